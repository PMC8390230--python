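"""Single-root and RSA-level trait calculation and CSV export.

Given a vectorized root with interpolated nodes P_i(x_i, y_i, z_i),
i = 1..n (base end first), and voxel resolution r (mm/voxel):

* root growth angle (radians)::

      theta = atan( |z_n - z_1| / sqrt((x_n - x_1)^2 + (y_n - y_1)^2) )

  the angle between the horizontal plane and the chord connecting the
  two end nodes; a vertical root gives pi/2.

* root length (cm)::

      L = (r / 10) * sum_i sqrt(dx_i^2 + dy_i^2 + dz_i^2)

  the cumulative Euclidean distance over consecutive nodes.

At the RSA level, over N single roots: the mean growth angle
``theta_bar = (1/N) sum theta_I``, the total root length
``TL = sum L_I``, and the root distribution index

    RDI = (r / 10) * [ (1/N) sum_I (1/n'_I) sum_i z_(I,i)  -  z_b ]

the depth centroid of the vertical root distribution relative to the
base-node depth z_b, with each polyline first resampled at one-voxel
arc-length spacing (n'_I nodes) so every stretch of root contributes in
proportion to its length.  Deeper-rooting plants have larger RDI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .rsa_model import Polyline, RSATree

PER_ROOT_CSV = "root_traits.csv"
SUMMARY_CSV = "rsa_summary.csv"


@dataclass
class SingleRootTraits:
    """Growth angle theta (radians) and length L (cm) of one root."""

    root_id: int
    theta: float
    length_cm: float
    method: str | None = None


@dataclass
class RSATraits:
    """Whole-RSA traits: mean angle, total length, RDI, root count."""

    mean_theta: float
    total_length_cm: float
    rdi_cm: float
    n_roots: int


def root_growth_angle(polyline: Polyline) -> float:
    """Growth angle in radians from the polyline's two end vertices."""
    p1, pn = polyline.points[0], polyline.points[-1]
    horizontal = math.hypot(pn[0] - p1[0], pn[1] - p1[1])
    return math.atan2(abs(pn[2] - p1[2]), horizontal)


def root_length(polyline: Polyline, resolution_mm: float) -> float:
    """Root length L in cm: cumulative inter-node distance scaled by r/10."""
    if not resolution_mm > 0:
        raise ValueError("resolution must be > 0 mm/voxel")
    return resolution_mm / 10.0 * polyline.length_voxels()


def average_growth_angle(roots: list[SingleRootTraits]) -> float:
    """theta_bar, the arithmetic mean growth angle in radians."""
    if not roots:
        raise ValueError("no roots")
    return float(np.mean([r.theta for r in roots]))


def total_root_length(roots: list[SingleRootTraits]) -> float:
    """TL, the total root length in cm."""
    if not roots:
        raise ValueError("no roots")
    return float(np.sum([r.length_cm for r in roots]))


def resample_at_voxel_resolution(polyline: Polyline, spacing: float = 1.0) -> Polyline:
    """Linearly resample so consecutive vertices are <= ``spacing`` apart.

    Each original segment is subdivided evenly into ceil(length / spacing)
    pieces, so original vertices are retained, inserted vertices are
    collinear with their segment, and the total length is unchanged.
    Segments already shorter than ``spacing`` are left as they are.
    """
    if not spacing > 0:
        raise ValueError("spacing must be > 0 voxels")
    pts = polyline.points
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = float(np.linalg.norm(b - a))
        pieces = max(1, math.ceil(seg / spacing - 1e-12))
        for j in range(1, pieces):
            out.append(a + (b - a) * (j / pieces))
        out.append(b)
    return Polyline(np.array(out))


def rdi(polylines: list[Polyline], base_z: float, resolution_mm: float) -> float:
    """Root distribution index in cm over already-resampled polylines.

    Per-root mean vertex depth, averaged over roots, offset by the base
    node depth ``z_b`` and scaled voxels -> cm.  Roots above the base node
    contribute negative depth and are averaged as-is.
    """
    if not polylines:
        raise ValueError("no roots")
    if not resolution_mm > 0:
        raise ValueError("resolution must be > 0 mm/voxel")
    per_root = [float(np.mean(p.points[:, 2])) for p in polylines]
    return resolution_mm / 10.0 * (float(np.mean(per_root)) - float(base_z))


def compute_single_root_traits(tree: RSATree) -> list[SingleRootTraits]:
    """Per-root traits from the cached polylines of a vectorized tree."""
    out = []
    for root in tree.roots:
        if root.polyline is None:
            raise ValueError(f"vectorize before export: root {root.id}")
        out.append(
            SingleRootTraits(
                root_id=root.id,
                theta=root_growth_angle(root.polyline),
                length_cm=root_length(root.polyline, tree.resolution_mm),
                method=root.interpolation,
            )
        )
    return out


def compute_rsa_traits(tree: RSATree) -> RSATraits:
    """RSA-level traits; polylines are resampled internally for the RDI."""
    singles = compute_single_root_traits(tree)
    if not singles:
        raise ValueError("no roots")
    resampled = [resample_at_voxel_resolution(r.polyline) for r in tree.roots]  # type: ignore[arg-type]
    return RSATraits(
        mean_theta=average_growth_angle(singles),
        total_length_cm=total_root_length(singles),
        rdi_cm=rdi(resampled, tree.base.position[2], tree.resolution_mm),
        n_roots=tree.n_roots,
    )


def export_traits_csv(tree: RSATree, output_dir) -> tuple[Path, Path]:
    """Write the per-root and summary trait CSVs; returns their paths.

    Per-root columns: root_id, method, theta_deg, length_cm.  Summary
    columns: n_roots, mean_theta_deg, total_length_cm, rdi_cm.  Numbers
    are printed with 6 significant digits; an empty tree yields a summary
    row with n_roots = 0 and empty trait fields.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    per_root_path = output_dir / PER_ROOT_CSV
    summary_path = output_dir / SUMMARY_CSV

    singles = compute_single_root_traits(tree)
    per_root = pd.DataFrame(
        {
            "root_id": [s.root_id for s in singles],
            "method": [s.method or "" for s in singles],
            "theta_deg": [math.degrees(s.theta) for s in singles],
            "length_cm": [s.length_cm for s in singles],
        }
    )
    per_root.to_csv(per_root_path, index=False, float_format="%.6g")

    if singles:
        rsa = compute_rsa_traits(tree)
        summary = pd.DataFrame(
            {
                "n_roots": [rsa.n_roots],
                "mean_theta_deg": [math.degrees(rsa.mean_theta)],
                "total_length_cm": [rsa.total_length_cm],
                "rdi_cm": [rsa.rdi_cm],
            }
        )
    else:
        summary = pd.DataFrame(
            {"n_roots": [0], "mean_theta_deg": [""], "total_length_cm": [""], "rdi_cm": [""]}
        )
    summary.to_csv(summary_path, index=False, float_format="%.6g")
    return per_root_path, summary_path
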