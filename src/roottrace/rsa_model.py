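"""Depth-2 tree model of a monocot root system and its JSON persistence.

A monocot root system architecture (RSA) is a set of single roots
(radicle and crown roots), each representable as one curve.  The model
is a tree of depth exactly 2:

* the **base node** (depth 0) marks where the seed was sown;
* each **root node** (depth 1) is one single root;
* its **relay nodes** (depth 2) are operator-registered points on that
  root that guide interpolation.

A vectorized root carries a cached :class:`Polyline` of interpolated
nodes.  The whole tree round-trips through a small JSON document
("root information", extension ``.rinfo``):

.. code-block:: json

    {"format": "rinfo", "version": 1, "resolution_mm": 0.3,
     "base": {"xyz": [x, y, z]},
     "roots": [{"id": 0, "interpolation": "cog",
                "relay_nodes": [[x, y, z], ...],
                "polyline": [[x, y, z], ...]}],
     "annotations": {"cultivar": "..."}}

Coordinates are stored in voxel units with ``resolution_mm`` alongside,
so physical traits are always recomputable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

RINFO_FORMAT = "rinfo"
RINFO_VERSION = 1

_METHODS = {"straight", "spline", "cog"}


class InvalidRinfoError(ValueError):
    """Raised when an rinfo document violates the schema."""


class Polyline:
    """An ordered run of interpolated nodes P_i(x_i, y_i, z_i) for one root.

    Points are continuous voxel coordinates ordered from the base-node end
    to the root tip.  At least two points; consecutive points distinct.
    """

    __slots__ = ("points",)

    def __init__(self, points) -> None:
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("polyline points must be an (n, 3) array of (x, y, z)")
        if pts.shape[0] < 2:
            raise ValueError("polyline requires at least 2 points")
        if np.any(np.all(pts[1:] == pts[:-1], axis=1)):
            raise ValueError("consecutive polyline points must be distinct")
        pts.setflags(write=False)
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Polyline):
            return NotImplemented
        return self.points.shape == other.points.shape and bool(
            np.all(self.points == other.points)
        )

    def __repr__(self) -> str:
        return f"Polyline({len(self)} points)"

    def length_voxels(self) -> float:
        """Cumulative Euclidean length over consecutive points, in voxels."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def as_lists(self) -> list[list[float]]:
        return [[float(v) for v in p] for p in self.points]


@dataclass
class BaseNode:
    """The seed position (x, y, z) in voxel units; its z is ``z_b``."""

    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError("base node position must be (x, y, z)")
        self.position = pos

    def __eq__(self, other) -> bool:
        if not isinstance(other, BaseNode):
            return NotImplemented
        return bool(np.all(self.position == other.position))


@dataclass
class RootNode:
    """One single root: its relay nodes and (optionally) a cached polyline."""

    id: int
    relay_nodes: np.ndarray
    interpolation: str | None = None
    polyline: Polyline | None = None

    def __post_init__(self) -> None:
        relays = np.asarray(self.relay_nodes, dtype=float)
        if relays.ndim != 2 or relays.shape[1] != 3 or relays.shape[0] < 1:
            raise ValueError("root requires at least one node")
        if len({tuple(p) for p in relays.tolist()}) != relays.shape[0]:
            raise ValueError("relay nodes must be distinct points")
        if self.interpolation is not None and self.interpolation not in _METHODS:
            raise ValueError(f"unknown interpolation method {self.interpolation!r}")
        self.relay_nodes = relays

    def __eq__(self, other) -> bool:
        if not isinstance(other, RootNode):
            return NotImplemented
        return (
            self.id == other.id
            and self.interpolation == other.interpolation
            and self.relay_nodes.shape == other.relay_nodes.shape
            and bool(np.all(self.relay_nodes == other.relay_nodes))
            and self.polyline == other.polyline
        )


@dataclass(eq=False)
class RSATree:
    """A whole RSA: one base node plus N single roots.

    Root ids are assigned at registration and never reused after deletion,
    so references in exports stay stable.  Structural equality ignores the
    internal id counter.
    """

    base: BaseNode
    roots: list[RootNode] = field(default_factory=list)
    annotations: dict[str, str] = field(default_factory=dict)
    resolution_mm: float = 1.0
    _next_id: int = 0

    def __post_init__(self) -> None:
        if not self.resolution_mm > 0:
            raise ValueError("resolution must be > 0 mm/voxel")
        if self.roots:
            self._next_id = max(self._next_id, max(r.id for r in self.roots) + 1)

    @property
    def n_roots(self) -> int:
        """N, the number of single roots."""
        return len(self.roots)

    def add_root(self, relay_nodes, interpolation: str | None = None) -> int:
        """Register one single root from its relay nodes; returns its id."""
        relays = np.asarray(relay_nodes, dtype=float)
        if relays.size == 0:
            raise ValueError("root requires at least one node")
        root = RootNode(self._next_id, relays, interpolation=interpolation)
        self.roots.append(root)
        self._next_id += 1
        return root.id

    def get_root(self, root_id: int) -> RootNode:
        for r in self.roots:
            if r.id == root_id:
                return r
        raise KeyError(f"no root with id {root_id}")

    def remove_root(self, root_id: int) -> None:
        root = self.get_root(root_id)
        self.roots.remove(root)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RSATree):
            return NotImplemented
        return (
            self.base == other.base
            and self.roots == other.roots
            and self.annotations == other.annotations
            and self.resolution_mm == other.resolution_mm
        )


# --------------------------------------------------------------------------
# rinfo serialization


def to_rinfo(tree: RSATree) -> str:
    """Serialize a tree to rinfo JSON text (UTF-8, ``.rinfo`` extension)."""
    doc = {
        "format": RINFO_FORMAT,
        "version": RINFO_VERSION,
        "resolution_mm": float(tree.resolution_mm),
        "base": {"xyz": [float(v) for v in tree.base.position]},
        "roots": [
            {
                "id": int(r.id),
                "interpolation": r.interpolation,
                "relay_nodes": [[float(v) for v in p] for p in r.relay_nodes],
                "polyline": None if r.polyline is None else r.polyline.as_lists(),
            }
            for r in tree.roots
        ],
        "annotations": dict(tree.annotations),
    }
    return json.dumps(doc, indent=1)


def _fail(path: str, why: str):
    raise InvalidRinfoError(f"invalid rinfo: {path} ({why})")


def _check_xyz(value, path: str) -> list[float]:
    if (
        not isinstance(value, (list, tuple))
        or len(value) != 3
        or not all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in value)
    ):
        _fail(path, "expected [x, y, z] numbers")
    return [float(v) for v in value]


def from_rinfo(text: str) -> RSATree:
    """Parse rinfo JSON text back into a structurally identical tree."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise InvalidRinfoError(f"invalid rinfo: <document> (not JSON: {exc})") from exc
    if not isinstance(doc, dict):
        _fail("<document>", "expected a JSON object")
    if doc.get("format") != RINFO_FORMAT:
        _fail("format", f"expected {RINFO_FORMAT!r}")
    if doc.get("version") != RINFO_VERSION:
        _fail("version", f"expected {RINFO_VERSION}")
    res = doc.get("resolution_mm")
    if not isinstance(res, (int, float)) or isinstance(res, bool) or not res > 0:
        _fail("resolution_mm", "expected a positive number")
    base = doc.get("base")
    if not isinstance(base, dict) or "xyz" not in base:
        _fail("base", "expected an object with 'xyz'")
    base_node = BaseNode(_check_xyz(base["xyz"], "base.xyz"))

    roots_doc = doc.get("roots")
    if not isinstance(roots_doc, list):
        _fail("roots", "expected a list")
    roots = []
    for i, rd in enumerate(roots_doc):
        where = f"roots[{i}]"
        if not isinstance(rd, dict):
            _fail(where, "expected an object")
        rid = rd.get("id")
        if not isinstance(rid, int) or isinstance(rid, bool):
            _fail(f"{where}.id", "expected an integer")
        interp = rd.get("interpolation")
        if interp is not None and interp not in _METHODS:
            _fail(f"{where}.interpolation", f"expected one of {sorted(_METHODS)} or null")
        relays_doc = rd.get("relay_nodes")
        if not isinstance(relays_doc, list) or len(relays_doc) < 1:
            _fail(f"{where}.relay_nodes", "expected a non-empty list")
        relays = [
            _check_xyz(p, f"{where}.relay_nodes[{j}]") for j, p in enumerate(relays_doc)
        ]
        poly_doc = rd.get("polyline")
        polyline = None
        if poly_doc is not None:
            if not isinstance(poly_doc, list) or len(poly_doc) < 2:
                _fail(f"{where}.polyline", "expected null or a list of >= 2 points")
            polyline = Polyline(
                [_check_xyz(p, f"{where}.polyline[{j}]") for j, p in enumerate(poly_doc)]
            )
        try:
            roots.append(
                RootNode(rid, relays, interpolation=interp, polyline=polyline)
            )
        except ValueError as exc:
            _fail(where, str(exc))

    ann = doc.get("annotations", {})
    if not isinstance(ann, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in ann.items()
    ):
        _fail("annotations", "expected an object of string -> string")

    return RSATree(
        base=base_node, roots=roots, annotations=dict(ann), resolution_mm=float(res)
    )


def save_rinfo(tree: RSATree, path) -> None:
    from pathlib import Path

    Path(path).write_text(to_rinfo(tree), encoding="utf-8")


def load_rinfo(path) -> RSATree:
    from pathlib import Path

    return from_rinfo(Path(path).read_text(encoding="utf-8"))
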