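"""Tetrahedral mesh data model and P1 element geometry.

The mesh is the substrate for everything downstream: harmonic field solves,
material-frame construction and the linear-elastic solver all operate on a
:class:`TetMesh` of linear (four-node) tetrahedra with per-element region tags
and named node/face sets.

Conventions
-----------
* coordinates in millimetres, 0-based indices;
* tets stored in positive orientation (signed volume > 0); readers and the
  constructor reorder by swapping the last two nodes where needed;
* region tags are small integers; the canonical anatomy mapping is in
  :data:`REGION_TAGS`;
* face sets store boundary triangles as sorted node triples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping

import numpy as np

#: canonical region-name <-> tag mapping used throughout the package
REGION_TAGS: Dict[str, int] = {
    "cortical": 1,
    "cancellous": 2,
    "implant": 3,
    "tooth": 4,
    "virtual": 9,
}

_TAG_NAMES = {v: k for k, v in REGION_TAGS.items()}

#: bone = load-carrying mandible tissue (excludes implant and virtual fill)
BONE_TAGS = frozenset({REGION_TAGS["cortical"], REGION_TAGS["cancellous"]})


class MeshError(ValueError):
    """Raised for malformed meshes or mesh files."""


class DegenerateElementError(MeshError):
    """Raised when an element has zero or negative volume."""


def region_tag(region: "int | str") -> int:
    """Resolve a region given either by name or by integer tag."""
    if isinstance(region, str):
        try:
            return REGION_TAGS[region]
        except KeyError:
            raise KeyError(
                f"unknown region name {region!r}; known: {sorted(REGION_TAGS)}"
            ) from None
    return int(region)


def canonical_faces(tets: np.ndarray) -> np.ndarray:
    """Sorted node triples of the four faces of each tet, shape (m, 4, 3).

    Local face ``a`` is the face opposite local node ``a``.
    """
    idx = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])
    faces = tets[:, idx]  # (m, 4, 3)
    return np.sort(faces, axis=2)


@dataclass
class TetMesh:
    """Linear tetrahedral mesh with region tags and named entity sets."""

    nodes: np.ndarray                                   # (n, 3) float, mm
    tets: np.ndarray                                    # (m, 4) int
    region: np.ndarray                                  # (m,) int
    node_sets: Dict[str, np.ndarray] = field(default_factory=dict)
    face_sets: Dict[str, np.ndarray] = field(default_factory=dict)  # (k, 3)
    elem_sets: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.region = np.ascontiguousarray(self.region, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshError("nodes must be an (n, 3) array")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshError("tets must be an (m, 4) array")
        if self.region.shape != (len(self.tets),):
            raise MeshError("region must carry exactly one tag per element")
        if len(self.tets) and (self.tets.min() < 0 or self.tets.max() >= len(self.nodes)):
            raise MeshError("tet connectivity references nonexistent nodes")
        self.node_sets = {k: np.asarray(v, dtype=np.int64) for k, v in self.node_sets.items()}
        self.face_sets = {
            k: np.sort(np.asarray(v, dtype=np.int64).reshape(-1, 3), axis=1)
            for k, v in self.face_sets.items()
        }
        self.elem_sets = {k: np.asarray(v, dtype=np.int64) for k, v in self.elem_sets.items()}

    # -- basic queries ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def elements_of(self, regions: "Iterable[int | str] | int | str") -> np.ndarray:
        """Indices of elements whose tag is in *regions*."""
        if isinstance(regions, (int, str)):
            regions = [regions]
        tags = {region_tag(r) for r in regions}
        return np.flatnonzero(np.isin(self.region, sorted(tags)))

    def centroids(self, elems: np.ndarray | None = None) -> np.ndarray:
        t = self.tets if elems is None else self.tets[elems]
        return self.nodes[t].mean(axis=1)

    def region_names(self) -> Dict[int, str]:
        return {int(t): _TAG_NAMES.get(int(t), f"region_{int(t)}")
                for t in np.unique(self.region)}

    # -- orientation ------------------------------------------------------
    def orient(self) -> "TetMesh":
        """Enforce positive signed volumes by swapping the last two nodes."""
        vol = signed_volumes(self.nodes, self.tets)
        flip = vol < 0
        if flip.any():
            self.tets[flip][:, [2, 3]]  # no-op guard for fancy indexing
            self.tets[np.ix_(np.flatnonzero(flip), [2, 3])] = (
                self.tets[np.ix_(np.flatnonzero(flip), [3, 2])]
            )
        return self

    def boundary_faces(self) -> np.ndarray:
        """Sorted node triples of faces used by exactly one tet, (k, 3)."""
        faces = canonical_faces(self.tets).reshape(-1, 3)
        uniq, counts = np.unique(faces, axis=0, return_counts=True)
        return uniq[counts == 1]


def signed_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volume of each tet, mm^3 (positive for canonical ordering)."""
    x = nodes[tets]
    e = x[:, 1:] - x[:, :1]                      # (m, 3, 3) edges from node 0
    return np.linalg.det(e) / 6.0


def element_geometry(mesh: TetMesh) -> "tuple[np.ndarray, np.ndarray]":
    """Volumes (m,) and P1 shape-function gradients (m, 4, 3), units mm^3 and 1/mm.

    Gradients satisfy the partition-of-unity identity sum_a grad N_a = 0 and are
    exact for linear fields.  Raises :class:`DegenerateElementError` on elements
    with non-positive volume.
    """
    x = mesh.nodes[mesh.tets]
    e = x[:, 1:] - x[:, :1]                      # rows are edge vectors
    det = np.linalg.det(e)
    vol = det / 6.0
    bad = np.flatnonzero(vol <= 0)
    if bad.size:
        raise DegenerateElementError(
            f"elements with non-positive volume: {bad[:20].tolist()}"
            + ("..." if bad.size > 20 else "")
        )
    inv = np.linalg.inv(e)                       # (m, 3, 3)
    # barycentric lambda_a (a=1..3) have grad = rows of e^{-T} = columns of inv
    g123 = np.transpose(inv, (0, 2, 1))          # (m, 3, 3): grad of N1..N3
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)   # (m, 4, 3)
    return vol, grads


@dataclass
class ValidationReport:
    n_nodes: int
    n_elements: int
    min_volume: float
    max_volume: float
    inverted_elements: List[int]
    unreferenced_nodes: List[int]
    bad_set_references: List[str]
    nonboundary_faces: List[str]

    @property
    def ok(self) -> bool:
        return not (self.inverted_elements or self.unreferenced_nodes
                    or self.bad_set_references or self.nonboundary_faces)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"nodes={self.n_nodes} elements={self.n_elements}",
            f"volume range [{self.min_volume:.6g}, {self.max_volume:.6g}] mm^3",
        ]
        if self.inverted_elements:
            lines.append(f"inverted elements: {self.inverted_elements}")
        if self.unreferenced_nodes:
            lines.append(f"unreferenced nodes: {self.unreferenced_nodes}")
        if self.bad_set_references:
            lines.append(f"bad set references: {self.bad_set_references}")
        if self.nonboundary_faces:
            lines.append(f"face-set triangles not on the boundary: {self.nonboundary_faces}")
        lines.append("OK" if self.ok else "INVALID")
        return "\n".join(lines)


def validate_mesh(mesh: TetMesh) -> ValidationReport:
    """Report invariant violations without modifying the mesh."""
    vol = signed_volumes(mesh.nodes, mesh.tets)
    inverted = np.flatnonzero(vol <= 0).tolist()
    referenced = np.zeros(mesh.n_nodes, dtype=bool)
    referenced[mesh.tets.ravel()] = True
    orphans = np.flatnonzero(~referenced).tolist()

    bad_refs: List[str] = []
    for name, idx in mesh.node_sets.items():
        if idx.size and (idx.min() < 0 or idx.max() >= mesh.n_nodes):
            bad_refs.append(f"node_set:{name}")
    for name, idx in mesh.elem_sets.items():
        if idx.size and (idx.min() < 0 or idx.max() >= mesh.n_elements):
            bad_refs.append(f"elem_set:{name}")

    nonboundary: List[str] = []
    if mesh.face_sets:
        faces = canonical_faces(mesh.tets).reshape(-1, 3)
        uniq, counts = np.unique(faces, axis=0, return_counts=True)
        once = {tuple(f) for f in uniq[counts == 1]}
        for name, tris in mesh.face_sets.items():
            if any(tuple(t) not in once for t in tris):
                nonboundary.append(name)

    return ValidationReport(
        n_nodes=mesh.n_nodes,
        n_elements=mesh.n_elements,
        min_volume=float(vol.min()) if len(vol) else float("nan"),
        max_volume=float(vol.max()) if len(vol) else float("nan"),
        inverted_elements=inverted,
        unreferenced_nodes=orphans,
        bad_set_references=bad_refs,
        nonboundary_faces=nonboundary,
    )
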