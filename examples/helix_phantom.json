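{
  "shape": [144, 64, 64],
  "resolution_mm": 0.3,
  "seed": 7,
  "noise": {"salt_fraction": 0.03},
  "roots": [
    {"curve": {"kind": "helix", "center_xy": [32.5, 32.5], "radius": 8.0,
               "z_start": 10.0, "z_end": 130.0, "turns": 2.0},
     "radius": 3, "intensity": 255}
  ]
}
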