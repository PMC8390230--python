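"""Synthetic root phantoms: tubular volumes with known ground truth.

Real inputs are segmented X-ray CT stacks in which roots appear as
bright, roughly tubular segments over a dark, speckled background (soil
minerals, air pockets and water show up as noise).  This module builds
volumes of that kind from parametric centerlines — straight lines,
helices, sinusoids and cubic Bezier curves — so tracing and trait
calculations can be validated against closed-form arc lengths and exact
centerline geometry without any external data.

Noise model: "salt" voxels set to 255 at a given fraction (speckle from
substrate voids) plus additive Gaussian intensity noise clipped to
[0, 255].  All randomness flows from the spec's seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .rsa_model import Polyline
from .volume_io import Volume, write_volume  # noqa: F401  (re-export)


# --------------------------------------------------------------------------
# parametric centerlines


class Curve:
    """A parametric 3D curve on t in [0, 1], in (x, y, z) voxel units."""

    def point(self, t: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def arc_length(self) -> float:
        """Arc length in voxels (dense numeric integration by default)."""
        t = np.linspace(0.0, 1.0, 8001)
        p = self.point(t)
        return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())

    @property
    def start(self) -> np.ndarray:
        return self.point(np.array([0.0]))[0]

    @property
    def end(self) -> np.ndarray:
        return self.point(np.array([1.0]))[0]

    def polyline(self, spacing: float = 0.25) -> Polyline:
        """Ground-truth polyline resampled at ``spacing`` voxels of arc."""
        t = np.linspace(0.0, 1.0, 8001)
        p = self.point(t)
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        keep = np.concatenate([[True], seg > 1e-12])
        arc, p = arc[keep], p[keep]
        targets = np.arange(0.0, arc[-1], spacing)
        targets = np.append(targets, arc[-1])
        pts = np.column_stack([np.interp(targets, arc, p[:, k]) for k in range(3)])
        dedup = np.ones(len(pts), dtype=bool)
        dedup[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
        return Polyline(pts[dedup])


@dataclass
class StraightCurve(Curve):
    start_xyz: tuple[float, float, float]
    end_xyz: tuple[float, float, float]

    def point(self, t):
        a = np.asarray(self.start_xyz, float)
        b = np.asarray(self.end_xyz, float)
        return a[None, :] + np.asarray(t, float)[:, None] * (b - a)[None, :]

    def arc_length(self) -> float:
        return float(
            np.linalg.norm(np.asarray(self.end_xyz) - np.asarray(self.start_xyz))
        )


@dataclass
class HelixCurve(Curve):
    """Circular helix descending from z_start to z_end around a vertical axis."""

    center_xy: tuple[float, float]
    radius: float
    z_start: float
    z_end: float
    turns: float
    phase_deg: float = 0.0

    def point(self, t):
        t = np.asarray(t, float)
        angle = math.radians(self.phase_deg) + 2.0 * math.pi * self.turns * t
        return np.column_stack(
            [
                self.center_xy[0] + self.radius * np.cos(angle),
                self.center_xy[1] + self.radius * np.sin(angle),
                self.z_start + (self.z_end - self.z_start) * t,
            ]
        )

    def arc_length(self) -> float:
        # closed form: sqrt((2 pi R turns)^2 + height^2)
        horizontal = 2.0 * math.pi * self.radius * self.turns
        return math.hypot(horizontal, self.z_end - self.z_start)


@dataclass
class SineCurve(Curve):
    """A vertical run with sinusoidal lateral displacement along x or y."""

    center_xy: tuple[float, float]
    z_start: float
    z_end: float
    amplitude: float
    periods: float
    phase_deg: float = 0.0
    axis: str = "x"

    def point(self, t):
        t = np.asarray(t, float)
        wobble = self.amplitude * np.sin(
            math.radians(self.phase_deg) + 2.0 * math.pi * self.periods * t
        )
        x = np.full_like(t, self.center_xy[0], dtype=float)
        y = np.full_like(t, self.center_xy[1], dtype=float)
        if self.axis == "x":
            x = x + wobble
        elif self.axis == "y":
            y = y + wobble
        else:
            raise ValueError("sine axis must be 'x' or 'y'")
        return np.column_stack([x, y, self.z_start + (self.z_end - self.z_start) * t])


@dataclass
class BezierCurve(Curve):
    """Cubic Bezier through four (x, y, z) control points."""

    control_points: list[tuple[float, float, float]]

    def point(self, t):
        cp = np.asarray(self.control_points, float)
        if cp.shape != (4, 3):
            raise ValueError("cubic bezier requires exactly 4 control points")
        t = np.asarray(t, float)[:, None]
        u = 1.0 - t
        return (
            u**3 * cp[0] + 3 * u**2 * t * cp[1] + 3 * u * t**2 * cp[2] + t**3 * cp[3]
        )


_CURVE_KINDS = {
    "straight": StraightCurve,
    "helix": HelixCurve,
    "sine": SineCurve,
    "bezier": BezierCurve,
}


def curve_from_dict(d: dict) -> Curve:
    """Build a curve from its JSON description ({"kind": ..., params...})."""
    d = dict(d)
    kind = d.pop("kind", None)
    if kind not in _CURVE_KINDS:
        raise ValueError(f"unknown curve kind {kind!r}; expected {sorted(_CURVE_KINDS)}")
    cls = _CURVE_KINDS[kind]
    try:
        return cls(**{k: (tuple(v) if isinstance(v, list) and k != "control_points" else v) for k, v in d.items()})
    except TypeError as exc:
        raise ValueError(f"bad parameters for {kind} curve: {exc}") from exc


# --------------------------------------------------------------------------
# phantom specification and rasterization


@dataclass
class RootSpec:
    """One phantom root: its centerline, tube radius and intensity."""

    curve: Curve
    radius: float = 3.0
    intensity: int = 255

    def __post_init__(self) -> None:
        if isinstance(self.curve, dict):
            self.curve = curve_from_dict(self.curve)
        if not self.radius > 0:
            raise ValueError("tube radius must be > 0 voxels")
        if not 1 <= self.intensity <= 255:
            raise ValueError("intensity must be an 8-bit value >= 1")


@dataclass
class PhantomSpec:
    """Full description of a synthetic volume.

    shape is (depth, height, width) in voxels; base_xyz is the seed
    position (defaults to the first root's start point); salt_fraction is
    the fraction of voxels set to 255, gaussian_sigma the std-dev of
    additive intensity noise (8-bit units).
    """

    shape: tuple[int, int, int]
    resolution_mm: float = 0.3
    roots: list[RootSpec] = field(default_factory=list)
    base_xyz: tuple[float, float, float] | None = None
    salt_fraction: float = 0.0
    gaussian_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(v) for v in self.shape)  # type: ignore[assignment]
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValueError("shape must be (depth, height, width) of positive ints")
        if not self.resolution_mm > 0:
            raise ValueError("resolution must be > 0 mm/voxel")
        if not 0.0 <= self.salt_fraction < 0.5:
            raise ValueError("salt_fraction must be in [0, 0.5)")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        self.roots = [
            r if isinstance(r, RootSpec) else RootSpec(**r) for r in self.roots
        ]

    @property
    def base(self) -> np.ndarray:
        if self.base_xyz is not None:
            return np.asarray(self.base_xyz, float)
        if not self.roots:
            raise ValueError("phantom has no roots and no explicit base")
        return self.roots[0].curve.start

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        doc = json.loads(text)
        noise = doc.pop("noise", {})
        return cls(
            shape=tuple(doc["shape"]),
            resolution_mm=doc.get("resolution_mm", 0.3),
            roots=[RootSpec(**r) for r in doc.get("roots", [])],
            base_xyz=tuple(doc["base"]) if "base" in doc else None,
            salt_fraction=noise.get("salt_fraction", 0.0),
            gaussian_sigma=noise.get("gaussian_sigma", 0.0),
            seed=doc.get("seed", 0),
        )

    @classmethod
    def from_json_file(cls, path) -> "PhantomSpec":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


@dataclass
class PhantomResult:
    """A rasterized phantom plus its ground truth."""

    volume: Volume
    polylines: list[Polyline]
    arc_lengths: list[float]
    angles: list[float]
    base_xyz: np.ndarray


def _growth_angle(start: np.ndarray, end: np.ndarray) -> float:
    horizontal = math.hypot(end[0] - start[0], end[1] - start[1])
    return math.atan2(abs(end[2] - start[2]), horizontal)


def rasterize(spec: PhantomSpec) -> PhantomResult:
    """Rasterize a phantom spec into a volume with ground truth attached.

    Every voxel whose centre lies within ``radius`` of a centerline
    (point-to-curve distance, curve sampled at 0.25-voxel arc steps) is
    set to the root's intensity; overlaps take the maximum.  Noise is
    applied afterwards with the spec's seed.
    """
    depth, height, width = spec.shape
    canvas = np.zeros(spec.shape, dtype=float)
    polylines, lengths, angles = [], [], []

    for i, root in enumerate(spec.roots):
        gt = root.curve.polyline(spacing=0.25)
        samples = gt.points
        lo = samples.min(axis=0) - root.radius
        hi = samples.max(axis=0) + root.radius
        if (lo < 0).any() or (hi > np.array([width, height, depth])).any():
            raise ValueError(f"phantom out of bounds: root {i}")

        x0, y0, z0 = np.floor(lo - 1).astype(int).clip(min=0)
        x1 = min(width, int(np.ceil(hi[0] + 1)))
        y1 = min(height, int(np.ceil(hi[1] + 1)))
        z1 = min(depth, int(np.ceil(hi[2] + 1)))
        zz, yy, xx = np.meshgrid(
            np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
        )
        centers = np.column_stack(
            [xx.ravel() + 0.5, yy.ravel() + 0.5, zz.ravel() + 0.5]
        )
        dist, _ = cKDTree(samples).query(centers)
        inside = dist <= root.radius
        block = canvas[z0:z1, y0:y1, x0:x1].ravel()
        block[inside] = np.maximum(block[inside], float(root.intensity))
        canvas[z0:z1, y0:y1, x0:x1] = block.reshape(z1 - z0, y1 - y0, x1 - x0)

        polylines.append(gt)
        lengths.append(root.curve.arc_length())
        angles.append(_growth_angle(root.curve.start, root.curve.end))

    rng = np.random.default_rng(spec.seed)
    if spec.gaussian_sigma > 0:
        canvas = canvas + rng.normal(0.0, spec.gaussian_sigma, size=spec.shape)
    if spec.salt_fraction > 0:
        canvas[rng.random(spec.shape) < spec.salt_fraction] = 255.0
    intensities = np.clip(np.round(canvas), 0, 255).astype(np.uint8)

    return PhantomResult(
        volume=Volume(intensities, spec.resolution_mm),
        polylines=polylines,
        arc_lengths=lengths,
        angles=angles,
        base_xyz=spec.base,
    )
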