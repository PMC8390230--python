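import numpy as np
import pytest
from scipy.spatial import cKDTree

from roottrace import (
    BaseNode,
    HelixCurve,
    PhantomSpec,
    Polyline,
    RootSpec,
    RSATree,
    StraightCurve,
    rasterize,
    resample_at_voxel_resolution,
)


@pytest.fixture(scope="session")
def straight_tube():
    """Noiseless vertical tube (radius 3) centered on a voxel-centre axis."""
    spec = PhantomSpec(
        shape=(64, 48, 48),
        resolution_mm=0.3,
        roots=[
            RootSpec(
                curve=StraightCurve((24.5, 24.5, 4.0), (24.5, 24.5, 60.0)),
                radius=3.0,
                intensity=255,
            )
        ],
    )
    return rasterize(spec)


@pytest.fixture(scope="session")
def helix_tube():
    """Noiseless helical tube (radius 3) with closed-form arc length."""
    spec = PhantomSpec(
        shape=(144, 64, 64),
        resolution_mm=0.3,
        roots=[
            RootSpec(
                curve=HelixCurve(
                    center_xy=(32.5, 32.5), radius=8.0,
                    z_start=10.0, z_end=130.0, turns=2.0,
                ),
                radius=3.0,
                intensity=255,
            )
        ],
    )
    return rasterize(spec)


def centerline_rms(polyline: Polyline, reference_points: np.ndarray) -> float:
    """RMS distance from a (densified) polyline to a reference centerline."""
    dense = resample_at_voxel_resolution(polyline, spacing=0.5)
    d, _ = cKDTree(reference_points).query(dense.points)
    return float(np.sqrt((d ** 2).mean()))


def random_polyline(rng: np.random.Generator, n_min: int = 2, n_max: int = 30) -> Polyline:
    """A random polyline with distinct consecutive vertices."""
    n = int(rng.integers(n_min, n_max + 1))
    pts = np.cumsum(rng.uniform(-5, 5, size=(n, 3)), axis=0) + rng.uniform(0, 50, 3)
    # nudge any coincident consecutive points apart
    for i in range(1, n):
        if np.allclose(pts[i], pts[i - 1]):
            pts[i] += 0.5
    return Polyline(pts)


def random_tree(rng: np.random.Generator, max_roots: int = 5) -> RSATree:
    """A random depth-2 tree; relays ordered so the farthest is last."""
    base = rng.uniform(5, 45, 3)
    tree = RSATree(
        BaseNode(base),
        resolution_mm=float(rng.uniform(0.1, 1.0)),
        annotations={"cultivar": "synthetic", "das": str(int(rng.integers(1, 60)))},
    )
    for _ in range(int(rng.integers(0, max_roots + 1))):
        k = int(rng.integers(1, 6))
        relays = base + rng.uniform(-30, 30, size=(k, 3))
        relays = relays[np.argsort(np.linalg.norm(relays - base, axis=1))]
        tree.add_root(relays)
    return tree
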