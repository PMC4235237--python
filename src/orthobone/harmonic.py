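"""Volumetric harmonic fields on tetrahedral meshes.

A harmonic scalar field solves Laplace's equation with prescribed boundary
values; its gradient is a smooth direction field that conforms to the domain
shape.  Two such fields drive orthotropic material assignment in curved bone:

* the *longitudinal* field, seeded at the two ends of the bone, whose gradient
  follows the curved long axis;
* the *radial* field, seeded 0 at the cortical-cancellous interface and 1 at
  the periosteal surface, whose gradient points outward through the shell.

Near an alveolar-ridge notch the longitudinal field bends around the cut-out
because its level sets conform to the boundary.  Including the *virtual*
fill elements in the longitudinal solve (and only there) lets the field flow
straight through the ridge; the virtual elements are ignored again when
material frames are assigned.

Discretization is the standard P1 stiffness form (per element
``V_e * grad(N_a) . grad(N_b)`` with unit conductivity); Dirichlet values are
imposed by elimination and therefore met exactly; the linear system is solved
by direct sparse factorization for determinism.  Nodes outside the included
regions carry NaN as the "undefined" sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .mesh import BONE_TAGS, REGION_TAGS, TetMesh, element_geometry, region_tag


class HarmonicError(ValueError):
    pass


class DisconnectedDomainError(HarmonicError):
    pass


@dataclass(frozen=True)
class DirichletSpec:
    """Named-set Dirichlet seeds: list of ``(node_set_name, value)`` pairs."""

    seeds: Tuple[Tuple[str, float], ...]

    def __init__(self, seeds: Iterable[Tuple[str, float]]):
        object.__setattr__(self, "seeds", tuple((str(n), float(v)) for n, v in seeds))
        if not self.seeds:
            raise HarmonicError("DirichletSpec needs at least one seed set")

    def resolve(self, mesh: TetMesh, restrict_to: np.ndarray | None = None):
        """Return (node indices, values); optionally intersect with a node subset.

        Seed sets must be disjoint after restriction (a node cannot carry two
        prescribed values).
        """
        idx_parts: List[np.ndarray] = []
        val_parts: List[np.ndarray] = []
        for name, value in self.seeds:
            if name not in mesh.node_sets:
                raise HarmonicError(
                    f"node set {name!r} not found; available: {sorted(mesh.node_sets)}")
            ids = mesh.node_sets[name]
            if restrict_to is not None:
                ids = np.intersect1d(ids, restrict_to)
            idx_parts.append(ids)
            val_parts.append(np.full(len(ids), value))
        idx = np.concatenate(idx_parts)
        vals = np.concatenate(val_parts)
        uniq, counts = np.unique(idx, return_counts=True)
        if (counts > 1).any():
            dup = uniq[counts > 1][:5]
            raise HarmonicError(f"seed sets overlap at nodes {dup.tolist()}")
        if not len(idx):
            raise HarmonicError("no seed nodes inside the solve domain")
        return idx, vals


def _stiffness(mesh: TetMesh, elems: np.ndarray) -> sp.csr_matrix:
    vol, grads = element_geometry(mesh)
    vol, grads = vol[elems], grads[elems]
    tets = mesh.tets[elems]
    # local 4x4 blocks: V * g_a . g_b
    local = np.einsum("e,eai,ebi->eab", vol, grads, grads)
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    K = sp.coo_matrix((local.ravel(), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes))
    return K.tocsr()


def _submesh_elements(mesh: TetMesh, include_regions) -> np.ndarray:
    if include_regions is None:
        return np.arange(mesh.n_elements)
    return mesh.elements_of(include_regions)


def _check_connected(mesh: TetMesh, elems: np.ndarray, nodes: np.ndarray) -> None:
    tets = mesh.tets[elems]
    # node adjacency through shared elements (edges of each tet suffice)
    pairs = []
    for a in range(4):
        for b in range(a + 1, 4):
            pairs.append(tets[:, [a, b]])
    e = np.concatenate(pairs, axis=0)
    n = mesh.n_nodes
    adj = sp.coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    adj = adj + adj.T
    ncomp, labels = csgraph.connected_components(adj.tocsr(), directed=False)
    present = np.unique(labels[nodes])
    if len(present) > 1:
        sizes = [int((labels[nodes] == c).sum()) for c in present]
        raise DisconnectedDomainError(
            f"solve domain has {len(present)} connected components of sizes {sizes}")


def solve_harmonic(
    mesh: TetMesh,
    spec: DirichletSpec,
    include_regions=None,
    method: str = "direct",
    cg_tol: float = 1e-10,
) -> np.ndarray:
    """Solve the discrete Laplace equation; returns one value per node.

    The result minimizes the discrete Dirichlet energy over P1 fields with the
    prescribed seed values (met exactly).  Nodes outside the included regions
    are NaN.  ``method`` is ``"direct"`` (default, sparse LU) or ``"cg"``.
    """
    elems = _submesh_elements(mesh, include_regions)
    if not len(elems):
        raise HarmonicError("no elements in the included regions")
    dom_nodes = np.unique(mesh.tets[elems])
    seed_idx, seed_vals = spec.resolve(mesh)
    outside = np.setdiff1d(seed_idx, dom_nodes)
    if outside.size:
        raise HarmonicError(
            f"{outside.size} seed nodes lie outside the solve domain "
            f"(e.g. node {int(outside[0])}); restrict the seed sets")
    _check_connected(mesh, elems, dom_nodes)

    K = _stiffness(mesh, elems)

    phi = np.full(mesh.n_nodes, np.nan)
    phi[seed_idx] = seed_vals
    is_fixed = np.zeros(mesh.n_nodes, dtype=bool)
    is_fixed[seed_idx] = True
    free = dom_nodes[~is_fixed[dom_nodes]]
    if len(free):
        Kff = K[free][:, free]
        rhs = -K[free][:, seed_idx] @ seed_vals
        if method == "cg":
            x, info = spla.cg(Kff, rhs, rtol=cg_tol, maxiter=10 * len(free))
            if info != 0:
                raise HarmonicError(f"CG did not converge (info={info})")
        else:
            x = spla.spsolve(Kff.tocsc(), rhs)
        if not np.all(np.isfinite(x)):
            raise HarmonicError("singular system: seeds do not determine the field")
        phi[free] = x
    return phi


def dirichlet_energy(mesh: TetMesh, phi: np.ndarray, include_regions=None) -> float:
    """Discrete Dirichlet energy 1/2 sum_e V_e |grad phi|_e^2 of a P1 field."""
    elems = _submesh_elements(mesh, include_regions)
    g = element_gradients(mesh, phi, include_regions)
    vol, _ = element_geometry(mesh)
    return float(0.5 * np.sum(vol[elems] * np.einsum("ei,ei->e", g[elems], g[elems])))


def element_gradients(mesh: TetMesh, phi: np.ndarray, include_regions=None) -> np.ndarray:
    """Constant per-element gradient of a P1 nodal field, shape (m, 3), 1/mm.

    Elements outside the included regions get NaN rows; an included element
    with an undefined (NaN) node value is an error.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (mesh.n_nodes,):
        raise HarmonicError(f"field has shape {phi.shape}, expected ({mesh.n_nodes},)")
    elems = _submesh_elements(mesh, include_regions)
    _, grads = element_geometry(mesh)
    vals = phi[mesh.tets[elems]]
    bad = np.flatnonzero(~np.isfinite(vals).all(axis=1))
    if bad.size:
        raise HarmonicError(
            f"undefined node values in included elements, e.g. element {int(elems[bad[0]])}")
    out = np.full((mesh.n_elements, 3), np.nan)
    out[elems] = np.einsum("ea,eai->ei", vals, grads[elems])
    return out


def default_longitudinal_spec() -> DirichletSpec:
    return DirichletSpec([("end_cap_A", 0.0), ("end_cap_B", 1.0)])


def default_radial_spec() -> DirichletSpec:
    return DirichletSpec([("inner_interface", 0.0), ("outer_surface", 1.0)])


def solve_field_pair(
    mesh: TetMesh,
    long_spec: DirichletSpec | None = None,
    rad_spec: DirichletSpec | None = None,
    use_virtual: bool = False,
    bone_regions: Sequence = ("cortical", "cancellous"),
) -> "tuple[np.ndarray, np.ndarray]":
    """Solve the longitudinal and radial harmonic fields; returns (phi_long, phi_rad).

    The longitudinal field is solved on bone plus the virtual fill when
    ``use_virtual`` is set (the ridge repair); the radial field is solved on
    bone only — radial seeding is a shell problem that the fill does not
    affect.  Seed sets are intersected with each solve domain, so shared sets
    (e.g. end caps that include virtual-fill nodes) can be used for both
    configurations.
    """
    long_spec = long_spec or default_longitudinal_spec()
    rad_spec = rad_spec or default_radial_spec()
    bone = [region_tag(r) for r in bone_regions]
    long_regions = list(bone)
    if use_virtual:
        if not len(mesh.elements_of("virtual")):
            raise HarmonicError("use_virtual=True but the mesh has no virtual elements")
        long_regions.append(REGION_TAGS["virtual"])

    phi_long = _solve_restricted(mesh, long_spec, long_regions)
    phi_rad = _solve_restricted(mesh, rad_spec, bone)
    return phi_long, phi_rad


def _solve_restricted(mesh: TetMesh, spec: DirichletSpec, regions) -> np.ndarray:
    elems = mesh.elements_of(regions)
    dom = np.unique(mesh.tets[elems])
    restricted = DirichletSpec([
        (name, value) for name, value in spec.seeds
    ])
    # intersect each seed set with the domain by building a temporary spec view
    idx, vals = restricted.resolve(mesh, restrict_to=dom)
    tmp_sets = {"__seeds__": idx}
    saved = mesh.node_sets
    try:
        mesh.node_sets = dict(saved, **tmp_sets)
        # group equal values back into per-value sets for solve_harmonic
        uniq = np.unique(vals)
        pairs = []
        for k, v in enumerate(uniq):
            name = f"__seed_{k}__"
            mesh.node_sets[name] = idx[vals == v]
            pairs.append((name, float(v)))
        return solve_harmonic(mesh, DirichletSpec(pairs), include_regions=regions)
    finally:
        mesh.node_sets = saved
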