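"""Interpolation of registered nodes into dense root polylines.

Three algorithms turn a root's registered nodes (base + relays) into a
polyline:

``straight``
    connects adjacent registered nodes; no nodes are added.
``spline``
    an interpolating cubic parametric spline (``scipy.interpolate.splprep``,
    smoothing factor 0, chord-length parameterization) through all nodes,
    sampled densely between them.
``cog``
    centre-of-gravity tracking: starting from the relay farthest from the
    base, the tracker repeatedly advances a fixed step whose *direction*
    is corrected by the intensity-weighted centre of gravity (COG) of the
    root voxels inside a forward-looking cone, consuming each registered
    node in base-ward order until the base is reached.  This hugs wavy
    roots that straight/spline interpolation cuts across, at the price of
    needing the segmented volume.

All three preserve the registered nodes verbatim among the output
vertices and are deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import interpolate as _si

from .rsa_model import Polyline, RSATree
from .volume_io import Volume

log = logging.getLogger(__name__)


@dataclass
class TrackingConfig:
    """Parameters of the COG tracker.

    step:
        voxels advanced per interpolated node (the COG correction
        interval); default 4.
    search_radius:
        radius in voxels of the forward COG window (cone length);
        default 8 (= 2 * step).
    cone_half_angle:
        angular half-width, in degrees, of the forward-looking cone
        toward the current target node; default 45.
    intensity_threshold:
        8-bit value at or above which a voxel counts as root; default 1
        (any non-zero voxel).
    max_steps:
        safety cap on tracker iterations; default 10 * volume diagonal
        / step, resolved at run time.
    arrival_radius:
        distance to the current target node that counts as "reached";
        default = step.
    """

    step: float = 4.0
    search_radius: float = 8.0
    cone_half_angle: float = 45.0
    intensity_threshold: int = 1
    max_steps: int | None = None
    arrival_radius: float | None = None

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1 voxel")
        if self.search_radius < self.step:
            raise ValueError("search_radius must be >= step")
        if not 0 < self.cone_half_angle <= 90:
            raise ValueError("cone_half_angle must be in (0, 90] degrees")
        if not 0 <= self.intensity_threshold <= 255:
            raise ValueError("intensity_threshold must be an 8-bit value")

    def resolved_arrival_radius(self) -> float:
        return self.step if self.arrival_radius is None else self.arrival_radius

    def resolved_max_steps(self, volume_shape) -> int:
        if self.max_steps is not None:
            return self.max_steps
        diagonal = float(np.linalg.norm(volume_shape))
        return max(1, int(math.ceil(10.0 * diagonal / self.step)))


def _as_nodes(base, relays) -> np.ndarray:
    base = np.asarray(base, dtype=float).reshape(3)
    relays = np.asarray(relays, dtype=float)
    if relays.ndim == 1:
        relays = relays.reshape(1, 3)
    if relays.ndim != 2 or relays.shape[1] != 3 or relays.shape[0] < 1:
        raise ValueError("at least one relay node of (x, y, z) is required")
    return np.vstack([base[None, :], relays])


def _collapse_duplicates(points: np.ndarray, warn: bool = True) -> np.ndarray:
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.any(points[1:] != points[:-1], axis=1)
    if warn and not keep.all():
        log.warning("collapsed %d duplicate consecutive node(s)", int((~keep).sum()))
    return points[keep]


def straight_interpolate(base, relays) -> Polyline:
    """Connect base and relay nodes with straight segments, base end first."""
    return Polyline(_collapse_duplicates(_as_nodes(base, relays)))


def spline_interpolate(base, relays, samples_per_span: int = 10) -> Polyline:
    """Interpolating cubic spline through base and relay nodes.

    Chord-length parameterized, smoothing factor 0 (the curve passes
    through every given node); ``samples_per_span`` vertices are emitted
    per inter-node span.  With only two distinct nodes the result
    degenerates to the straight polyline; with fewer than four the spline
    degree is lowered to (node count - 1).
    """
    if samples_per_span < 1:
        raise ValueError("samples_per_span must be >= 1")
    nodes = _collapse_duplicates(_as_nodes(base, relays))
    m = len(nodes)
    if m == 2:
        return straight_interpolate(nodes[0], nodes[1:])

    chord = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(chord)])
    u /= u[-1]
    k = min(3, m - 1)
    tck, _ = _si.splprep(nodes.T, u=u, s=0.0, k=k)

    params = []
    for i in range(m - 1):
        span = np.linspace(u[i], u[i + 1], samples_per_span, endpoint=False)
        params.append(span)
    params.append([u[-1]])
    params = np.concatenate(params)
    pts = np.asarray(_si.splev(params, tck)).T

    # registered nodes must appear verbatim: snap the span starts/end
    node_rows = np.arange(m - 1) * samples_per_span
    pts[node_rows] = nodes[:-1]
    pts[-1] = nodes[-1]
    return Polyline(_collapse_duplicates(pts, warn=False))


def _forward_cog(
    intensities: np.ndarray, apex: np.ndarray, axis: np.ndarray, cfg: TrackingConfig
) -> np.ndarray | None:
    """Intensity-weighted COG of root voxels in the forward cone, or None.

    The cone has its apex at the current position, points along ``axis``
    (toward the current target), half-angle ``cone_half_angle`` and is
    truncated at ``search_radius``.  Voxel centres (index + 0.5) are the
    sample points; weights are raw 8-bit intensities.
    """
    depth, height, width = intensities.shape
    r = cfg.search_radius
    x, y, z = apex
    x0, x1 = max(0, math.floor(x - r - 1)), min(width, math.ceil(x + r + 1))
    y0, y1 = max(0, math.floor(y - r - 1)), min(height, math.ceil(y + r + 1))
    z0, z1 = max(0, math.floor(z - r - 1)), min(depth, math.ceil(z + r + 1))
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return None
    sub = intensities[z0:z1, y0:y1, x0:x1]
    hit = sub >= cfg.intensity_threshold
    if not hit.any():
        return None

    cz = np.arange(z0, z1, dtype=float)[:, None, None] + 0.5 - z
    cy = np.arange(y0, y1, dtype=float)[None, :, None] + 0.5 - y
    cx = np.arange(x0, x1, dtype=float)[None, None, :] + 0.5 - x
    r2 = cz * cz + cy * cy + cx * cx
    proj = cx * axis[0] + cy * axis[1] + cz * axis[2]
    cos_half = math.cos(math.radians(cfg.cone_half_angle))
    mask = hit & (r2 <= r * r) & (r2 > 0) & (proj >= np.sqrt(r2) * cos_half)
    if not mask.any():
        return None

    w = sub[mask].astype(float)
    total = w.sum()
    gz, gy, gx = np.broadcast_arrays(cz, cy, cx)
    return apex + np.array(
        [(w * gx[mask]).sum(), (w * gy[mask]).sum(), (w * gz[mask]).sum()]
    ) / total


def cog_track(
    volume: Volume, base, relays, config: TrackingConfig | None = None
) -> Polyline:
    """Trace one root through the volume by COG tracking.

    Tracking starts at the relay farthest from the base (normally the root
    tip, the last registered relay) and walks base-ward through the
    remaining registered nodes.  Each iteration computes the
    intensity-weighted COG of root voxels in a forward cone (axis: the
    mean of the current travel direction and the direction to the target)
    and snaps the next interpolated node to it; when the cone contains no
    root voxel the tracker advances geometrically toward the target
    without adding a node, so in a fully empty volume the result is
    exactly the straight polyline.  A target within ``arrival_radius`` is
    consumed and its exact coordinate appended.  The returned polyline
    runs base -> tip and contains every registered node verbatim.
    """
    cfg = config or TrackingConfig()
    nodes = _collapse_duplicates(_as_nodes(base, relays))
    for node in nodes:
        if not volume.contains_point(node):
            raise ValueError(f"node {tuple(node)} lies outside the volume bounds")

    far = 1 + int(np.argmax(np.linalg.norm(nodes[1:] - nodes[0], axis=1)))
    if far != len(nodes) - 1:
        log.warning(
            "farthest relay (index %d) is not the last registered one; "
            "tracking still follows reverse registration order",
            far,
        )

    arrival = cfg.resolved_arrival_radius()
    max_steps = cfg.resolved_max_steps(volume.shape)
    intensities = volume.intensities

    points = [nodes[-1].copy()]
    cur = nodes[-1].copy()
    heading: np.ndarray | None = None  # unit direction of the last COG step
    steps = 0
    for target in nodes[-2::-1]:
        while np.linalg.norm(target - cur) > arrival:
            to_target = (target - cur) / np.linalg.norm(target - cur)
            # cone axis: mean of the travel direction and the direction to
            # the target — the travel term keeps the window on the local
            # root run (a cone aimed only at a distant target clips the
            # outer side of winding roots), the target term steers the
            # tracker so every registered node is reached
            if heading is None:
                axis = to_target
            else:
                axis = heading + to_target
                norm = np.linalg.norm(axis)
                axis = to_target if norm < 1e-12 else axis / norm
            cog = _forward_cog(intensities, cur, axis, cfg)
            if cog is None:
                # no root voxel ahead: pure geometric step, no COG node added
                cur = cur + cfg.step * to_target
                heading = None
            else:
                offset = cog - cur
                heading = offset / np.linalg.norm(offset)
                cur = cog
                points.append(cur.copy())
            steps += 1
            if steps > max_steps:
                raise RuntimeError(
                    f"tracking did not converge within {max_steps} steps"
                )
        points.append(target.copy())
        cur = target.copy()
        heading = None  # re-aim at the next base-ward node

    return Polyline(_collapse_duplicates(np.array(points[::-1]), warn=False))


def vectorize_root(
    tree: RSATree,
    root_id: int,
    method: str,
    volume: Volume | None = None,
    config: TrackingConfig | None = None,
    samples_per_span: int = 10,
) -> Polyline:
    """Vectorize one registered root and cache the polyline on its node.

    ``method`` is one of ``straight``, ``spline``, ``cog``; COG tracking
    requires a volume.  Re-running with identical inputs yields an
    identical polyline.
    """
    root = tree.get_root(root_id)
    base = tree.base.position
    if method == "straight":
        poly = straight_interpolate(base, root.relay_nodes)
    elif method == "spline":
        poly = spline_interpolate(base, root.relay_nodes, samples_per_span)
    elif method == "cog":
        if volume is None:
            raise ValueError("COG tracking requires a volume")
        poly = cog_track(volume, base, root.relay_nodes, config)
    else:
        raise ValueError(f"method must be straight, spline or cog; got {method!r}")
    root.interpolation = method
    root.polyline = poly
    return poly


def vectorize_all(
    tree: RSATree,
    method: str,
    volume: Volume | None = None,
    config: TrackingConfig | None = None,
    samples_per_span: int = 10,
) -> None:
    """Vectorize every root of the tree with one method (see vectorize_root)."""
    for root in tree.roots:
        vectorize_root(
            tree, root.id, method, volume=volume, config=config,
            samples_per_span=samples_per_span,
        )
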