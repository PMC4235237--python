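"""Tet4 linear elasticity with per-element (rotatable orthotropic) stiffness.

Constant-strain tetrahedra assembled as ``K_e = V_e B^T C B`` with C the
element stiffness in global axes (GPa).  Unit system: coordinates mm, moduli
GPa, so forces are kN internally; the public interface takes loads in N and
tractions in MPa, and reports stresses in MPa.

Perfect bonding between regions (e.g. implant and bone) is realized by the
shared-node mesh itself; restraints and loads are declarative, referencing
named node/face sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TetMesh, element_geometry

_N_TO_KN = 1e-3
_GPA_TO_MPA = 1e3
_AXIS = {"x": 0, "y": 1, "z": 2}


class SolverError(ValueError):
    pass


class RigidModeError(SolverError):
    """Raised when the restraints do not remove all rigid-body modes."""


@dataclass
class BCSpec:
    """Restraints and loads by named sets.

    ``fixed``: list of ``(node_set, axes)`` with axes a subset of "xyz"
    (displacement pinned to zero on those components).
    ``node_loads``: list of ``(node_set, total force [N] as 3-vector)``,
    divided equally over the set's nodes.
    ``tractions``: list of ``(face_set, traction [MPa] as 3-vector)``,
    integrated over triangle areas with equal thirds to the corner nodes.
    """

    fixed: List[Tuple[str, str]] = field(default_factory=list)
    node_loads: List[Tuple[str, Sequence[float]]] = field(default_factory=list)
    tractions: List[Tuple[str, Sequence[float]]] = field(default_factory=list)

    def fixed_dofs(self, mesh: TetMesh) -> np.ndarray:
        dofs = []
        for set_name, axes in self.fixed:
            if set_name not in mesh.node_sets:
                raise SolverError(f"node set {set_name!r} not in mesh; "
                                  f"available: {sorted(mesh.node_sets)}")
            ax = [_AXIS[a] for a in axes.lower()]
            if not ax:
                raise SolverError(f"empty axes spec for set {set_name!r}")
            for a in ax:
                dofs.append(3 * mesh.node_sets[set_name] + a)
        if not dofs:
            raise RigidModeError("no restraints specified")
        return np.unique(np.concatenate(dofs))

    def force_vector(self, mesh: TetMesh) -> np.ndarray:
        """Assembled load vector in kN, shape (3 n,)."""
        f = np.zeros(3 * mesh.n_nodes)
        for set_name, force in self.node_loads:
            if set_name not in mesh.node_sets:
                raise SolverError(f"node set {set_name!r} not in mesh")
            ids = mesh.node_sets[set_name]
            if not len(ids):
                raise SolverError(f"node set {set_name!r} is empty")
            per = np.asarray(force, dtype=float) * _N_TO_KN / len(ids)
            for a in range(3):
                f[3 * ids + a] += per[a]
        for set_name, trac in self.tractions:
            if set_name not in mesh.face_sets:
                raise SolverError(f"face set {set_name!r} not in mesh")
            tris = mesh.face_sets[set_name]
            t = np.asarray(trac, dtype=float) * _N_TO_KN   # MPa * mm^2 = N
            p = mesh.nodes[tris]
            areas = 0.5 * np.linalg.norm(
                np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
            contrib = areas[:, None] * t[None, :] / 3.0
            for corner in range(3):
                np.add.at(f, 3 * tris[:, corner, None] + np.arange(3), contrib)
        return f


def _b_matrices(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices, shape (m, 6, 12).

    Voigt order (11, 22, 33, 23, 13, 12) with engineering shears.
    """
    m = len(grads)
    B = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 1] = gz
        B[:, 3, c + 2] = gy
        B[:, 4, c + 0] = gz
        B[:, 4, c + 2] = gx
        B[:, 5, c + 0] = gy
        B[:, 5, c + 1] = gx
    return B


def assemble_stiffness(mesh: TetMesh, elem_stiffness: np.ndarray,
                       elems: np.ndarray | None = None) -> sp.csr_matrix:
    """Global stiffness (kN/mm) from per-element 6x6 C (GPa).

    ``elem_stiffness`` is (m, 6, 6) over all elements; rows for excluded
    elements may be NaN.  ``elems`` restricts assembly (e.g. to non-virtual
    elements).
    """
    if elems is None:
        elems = np.arange(mesh.n_elements)
    C = np.asarray(elem_stiffness, dtype=float)[elems]
    if not np.isfinite(C).all():
        bad = elems[~np.isfinite(C).reshape(len(C), -1).all(axis=1)]
        raise SolverError(f"stiffness undefined for elements {bad[:10].tolist()}")
    vol, grads = element_geometry(mesh)
    B = _b_matrices(grads[elems])
    Ke = np.einsum("e,eji,ejk,ekl->eil", vol[elems], B, C, B, optimize=True)
    tets = mesh.tets[elems]
    dof = (3 * tets[:, :, None] + np.arange(3)).reshape(len(elems), 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    return sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def solve_prescribed(
    mesh: TetMesh,
    elem_stiffness: np.ndarray,
    fixed_dofs: np.ndarray,
    fixed_values: np.ndarray | float = 0.0,
    force_kn: np.ndarray | None = None,
    elems: np.ndarray | None = None,
):
    """Low-level solve with arbitrary prescribed dof values.

    ``fixed_dofs`` are global dof indices (3*node + axis); ``fixed_values``
    the prescribed displacements (mm).  ``force_kn`` is an optional assembled
    load vector in kN.  Returns ``(u, K, f)`` with u of shape (n, 3).
    """
    if elems is None:
        elems = np.arange(mesh.n_elements)
    K = assemble_stiffness(mesh, elem_stiffness, elems)
    n = 3 * mesh.n_nodes
    f = np.zeros(n) if force_kn is None else np.asarray(force_kn, dtype=float)
    fixed = np.asarray(fixed_dofs, dtype=np.int64)
    vals = np.broadcast_to(np.asarray(fixed_values, dtype=float), fixed.shape)

    active_nodes = np.unique(mesh.tets[elems])
    active = (3 * active_nodes[:, None] + np.arange(3)).ravel()
    is_fixed = np.zeros(n, dtype=bool)
    is_fixed[fixed] = True
    free = active[~is_fixed[active]]

    u = np.zeros(n)
    u[fixed] = vals
    Kff = K[free][:, free].tocsc()
    rhs = f[free] - K[free][:, fixed] @ vals
    try:
        u_free = spla.spsolve(Kff, rhs)
    except Exception as exc:  # pragma: no cover - scipy usually returns nan instead
        raise RigidModeError(f"sparse solve failed: {exc}") from exc
    if not np.all(np.isfinite(u_free)):
        raise RigidModeError("singular stiffness: restraints leave rigid-body modes")
    res = np.linalg.norm(Kff @ u_free - rhs)
    scale = max(np.linalg.norm(rhs), 1e-300)
    if np.linalg.norm(rhs) > 0 and res / scale > 1e-8:
        # a direct factorization only misses the residual target when the
        # system is singular (or near-singular), i.e. restraints are missing
        raise RigidModeError(
            f"solver residual {res / scale:.2e} exceeds 1e-8: stiffness is "
            "singular or severely ill-conditioned (check restraints)")
    u[free] = u_free
    return u.reshape(-1, 3), K, f


def solve_elasticity(
    mesh: TetMesh,
    elem_stiffness: np.ndarray,
    bcs: BCSpec,
    elems: np.ndarray | None = None,
    return_reactions: bool = False,
):
    """Solve K u = f; returns nodal displacements (n, 3) in mm.

    Dirichlet restraints are zero-displacement on the named sets/axes; the
    relative residual on the free equations is checked to 1e-8.  With
    ``return_reactions`` also returns the reaction force array (n, 3) in N
    (non-zero only on restrained dofs).
    """
    f = bcs.force_vector(mesh)
    fixed = bcs.fixed_dofs(mesh)
    u, K, f = solve_prescribed(mesh, elem_stiffness, fixed, 0.0,
                               force_kn=f, elems=elems)
    if not return_reactions:
        return u
    r = K @ u.ravel() - f
    reactions = np.zeros_like(r)
    reactions[fixed] = r[fixed]
    return u, reactions.reshape(-1, 3) / _N_TO_KN


def recover_fields(
    mesh: TetMesh,
    u: np.ndarray,
    elem_stiffness: np.ndarray,
    elems: np.ndarray | None = None,
) -> "tuple[np.ndarray, np.ndarray]":
    """Element strain and stress tensors from a displacement field.

    Returns ``(strain, stress)`` as (m, 3, 3) symmetric tensors; strain is
    the symmetric displacement gradient (dimensionless), stress is C eps in
    MPa.  Rows of excluded elements are NaN.
    """
    if elems is None:
        elems = np.arange(mesh.n_elements)
    _, grads = element_geometry(mesh)
    ue = np.asarray(u, dtype=float)[mesh.tets[elems]]          # (k, 4, 3)
    H = np.einsum("eai,eaj->eij", ue, grads[elems])            # displacement gradient du_i/dx_j
    eps = 0.5 * (H + np.transpose(H, (0, 2, 1)))

    C = np.asarray(elem_stiffness, dtype=float)[elems]
    eps_v = np.stack([
        eps[:, 0, 0], eps[:, 1, 1], eps[:, 2, 2],
        2 * eps[:, 1, 2], 2 * eps[:, 0, 2], 2 * eps[:, 0, 1],
    ], axis=1)
    sig_v = np.einsum("eij,ej->ei", C, eps_v) * _GPA_TO_MPA
    sig = np.empty_like(eps)
    sig[:, 0, 0] = sig_v[:, 0]
    sig[:, 1, 1] = sig_v[:, 1]
    sig[:, 2, 2] = sig_v[:, 2]
    sig[:, 1, 2] = sig[:, 2, 1] = sig_v[:, 3]
    sig[:, 0, 2] = sig[:, 2, 0] = sig_v[:, 4]
    sig[:, 0, 1] = sig[:, 1, 0] = sig_v[:, 5]

    strain = np.full((mesh.n_elements, 3, 3), np.nan)
    stress = np.full((mesh.n_elements, 3, 3), np.nan)
    strain[elems] = eps
    stress[elems] = sig
    return strain, stress


def scalar_measures(tensors: np.ndarray, kind: str, nu_eff: float = 0.3) -> Dict[str, np.ndarray]:
    """Equivalent / first-principal / third-principal measures per element.

    Principals are eigenvalues sorted descending (first = tensile, third =
    compressive, signed).  Equivalent stress is the von Mises invariant
    sqrt(3 J2); equivalent strain carries the customary 1/(1+nu_eff)
    normalization (commercial-solver convention; for uniaxial stress in a
    material with nu = nu_eff it reports the axial strain).  NaN tensors
    propagate to NaN measures.
    """
    if kind not in ("stress", "strain"):
        raise ValueError("kind must be 'stress' or 'strain'")
    T = np.asarray(tensors, dtype=float)
    m = len(T)
    out_eq = np.full(m, np.nan)
    p1 = np.full(m, np.nan)
    p3 = np.full(m, np.nan)
    ok = np.isfinite(T).reshape(m, -1).all(axis=1)
    if ok.any():
        w = np.linalg.eigvalsh(T[ok])            # ascending
        p1[ok] = w[:, 2]
        p3[ok] = w[:, 0]
        d = np.sqrt(0.5 * ((w[:, 0] - w[:, 1]) ** 2
                           + (w[:, 1] - w[:, 2]) ** 2
                           + (w[:, 2] - w[:, 0]) ** 2))
        if kind == "strain":
            d = d / (1.0 + nu_eff)
        out_eq[ok] = d
    return {"equivalent": out_eq, "first_principal": p1, "third_principal": p3}
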