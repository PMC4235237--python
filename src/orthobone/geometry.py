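"""Deterministic synthetic test geometries.

The centrepiece is a mandible *proxy*: a circular-arc tube with a stiff
cortical shell and a soft cancellous core, a notch carved into the superior
surface standing in for the alveolar-ridge/teeth region (where an uncorrected
longitudinal harmonic field bends away from the true long axis), a block of
*virtual* elements exactly filling the notch flush with the unnotched outer
surface, and a vertical implant cylinder embedded at a "first molar" position.

The proxy is an idealized shape, not an anatomic mandible: the behaviours the
methodology is about — field bending at the ridge, its repair by virtual
elements, crestal stress concentration, apical strain concentration — are all
shape-generic and reproducible on an arc tube.

Meshing is template subdivision of a structured hexahedral grid (six Kuhn
tetrahedra per cell, conforming across cells), so meshes are exactly
reproducible; an optional jitter perturbs interior single-region nodes for
robustness testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict

import numpy as np

from .mesh import BONE_TAGS, MeshError, REGION_TAGS, TetMesh, signed_volumes

_CORT = REGION_TAGS["cortical"]
_CANC = REGION_TAGS["cancellous"]
_IMPL = REGION_TAGS["implant"]
_VIRT = REGION_TAGS["virtual"]


class GenerationError(MeshError):
    """Raised when geometry parameters cannot produce a valid mesh."""


# 6-tet Kuhn subdivision of a hexahedron: all tets share the main diagonal
# (0,0,0)-(1,1,1); identical orientation in every cell keeps the grid conforming.
_KUHN_PATHS = [
    (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
]


def _kuhn_tets(corner_ids: np.ndarray) -> np.ndarray:
    """Split hex cells into 6 tets each.

    ``corner_ids``: (ncell, 2, 2, 2) node ids indexed by local (di, dj, dk).
    """
    tets = []
    for axes in _KUHN_PATHS:
        loc = [(0, 0, 0)]
        cur = [0, 0, 0]
        for ax in axes:
            cur[ax] += 1
            loc.append(tuple(cur))
        tets.append(np.stack([corner_ids[:, a, b, c] for a, b, c in loc], axis=1))
    return np.concatenate(tets, axis=0).reshape(6, -1, 4).transpose(1, 0, 2).reshape(-1, 4)


# ----------------------------------------------------------------------
# box fixture
# ----------------------------------------------------------------------

def generate_box(nx: int, ny: int, nz: int,
                 lengths=(1.0, 1.0, 1.0), region: int = _CORT) -> TetMesh:
    """Structured box split into 6 tets per cell, with face sets for the six faces.

    Face/node sets are named ``x0, x1, y0, y1, z0, z1`` (lower/upper face along
    each axis).  Total volume is exactly ``lx*ly*lz``.
    """
    if min(nx, ny, nz) < 1:
        raise GenerationError("subdivisions must be >= 1")
    lx, ly, lz = lengths
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    corners = np.empty((len(I), 2, 2, 2), dtype=np.int64)
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                corners[:, di, dj, dk] = nid(I + di, J + dj, K + dk)
    tets = _kuhn_tets(corners)

    mesh = TetMesh(nodes, tets, np.full(len(tets), region, dtype=np.int64)).orient()

    bfaces = mesh.boundary_faces()
    fc = nodes[bfaces].mean(axis=1)
    tol = 1e-9 * max(lx, ly, lz, 1.0)
    planes = {
        "x0": np.abs(fc[:, 0]) < tol, "x1": np.abs(fc[:, 0] - lx) < tol,
        "y0": np.abs(fc[:, 1]) < tol, "y1": np.abs(fc[:, 1] - ly) < tol,
        "z0": np.abs(fc[:, 2]) < tol, "z1": np.abs(fc[:, 2] - lz) < tol,
    }
    for name, sel in planes.items():
        tris = bfaces[sel]
        mesh.face_sets[name] = tris
        mesh.node_sets[name] = np.unique(tris)
    return mesh


# ----------------------------------------------------------------------
# mandible proxy
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ProxyParams:
    """Parameters of the curved-tube mandible proxy (lengths in mm, angles in degrees).

    Defaults approximate a mandibular body: a 25 mm arc radius over 120 deg
    (arc length ~52 mm), a 10 mm outer tube radius (20 mm body height, molar
    region scale, leaving realistic apical clearance under a 10 mm implant)
    with a 2 mm cortical shell, a ridge notch cutting through the shell into
    the core, and an implant of the 10.0 x 4.8 mm fixture size embedded
    vertically at the "first molar" position.  ``jitter`` (fraction of edge length, default off) perturbs
    interior single-region nodes for robustness testing; ``seed`` feeds that
    perturbation only.
    """

    arc_radius: float = 25.0
    arc_angle_deg: float = 120.0
    outer_radius: float = 10.0
    cortical_thickness: float = 2.0
    notch_depth: float = 5.0
    notch_angle_deg: float = 35.0
    notch_center_frac: float = 0.3
    implant_length: float = 10.0
    implant_diameter: float = 4.8
    implant_frac: float = 0.7
    edge_length: float = 1.5
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.edge_length <= 0:
            raise GenerationError("edge_length must be positive")
        if not 0 < self.cortical_thickness < self.outer_radius:
            raise GenerationError("need 0 < cortical_thickness < outer_radius")
        if self.implant_diameter >= 2 * (self.outer_radius - self.cortical_thickness):
            raise GenerationError("implant diameter must fit inside the cancellous core")
        if self.notch_depth > self.outer_radius:
            raise GenerationError("notch_depth must not exceed outer_radius")
        if self.arc_radius <= self.outer_radius:
            raise GenerationError("arc_radius <= outer_radius: tube self-intersects")
        if not 0 <= self.jitter <= 0.25:
            raise GenerationError("jitter must be in [0, 0.25]")

    # -- arc helpers ------------------------------------------------------
    @property
    def arc_angle(self) -> float:
        return math.radians(self.arc_angle_deg)

    def alpha_range(self) -> "tuple[float, float]":
        h = self.arc_angle / 2
        return -h, h

    def notch_window(self) -> "tuple[float, float]":
        a0, a1 = self.alpha_range()
        c = a0 + self.notch_center_frac * (a1 - a0)
        h = math.radians(self.notch_angle_deg) / 2
        return c - h, c + h

    def implant_alpha(self) -> float:
        a0, a1 = self.alpha_range()
        return a0 + self.implant_frac * (a1 - a0)

    def implant_axis_point(self) -> np.ndarray:
        a = self.implant_alpha()
        return np.array([self.arc_radius * math.cos(a), self.arc_radius * math.sin(a), 0.0])

    def centerline_point(self, alpha: float) -> np.ndarray:
        return np.array([self.arc_radius * math.cos(alpha),
                         self.arc_radius * math.sin(alpha), 0.0])


def centerline_tangent(params: ProxyParams, point) -> np.ndarray:
    """Unit tangent of the circular centerline at the arc parameter nearest *point*.

    Serves as the analytic reference for the anatomic longitudinal direction
    when scoring material-frame quality.  Accepts a single point or an (k, 3)
    array and returns matching shape.
    """
    p = np.atleast_2d(np.asarray(point, dtype=float))
    alpha = np.arctan2(p[:, 1], p[:, 0])
    t = np.stack([-np.sin(alpha), np.cos(alpha), np.zeros_like(alpha)], axis=1)
    return t[0] if np.asarray(point).ndim == 1 else t


def generate_proxy(params: ProxyParams | None = None, **overrides) -> TetMesh:
    """Generate the mandible-proxy mesh.

    Regions: cortical(1) shell, cancellous(2) core, implant(3) cylinder,
    virtual(9) notch fill.  Node sets: ``end_cap_A``/``end_cap_B`` (tube ends),
    ``outer_surface`` (periosteal boundary of bone, end caps excluded),
    ``inner_interface`` (cortical-cancellous), ``implant_surface`` (bone-implant
    interface), ``crest_ring`` (cortical collar at the implant neck),
    ``implant_top`` (exposed implant platform).  Element sets: ``ridge_band``
    (bone under/around the notch), ``crest_band`` (cortical collar elements),
    ``apical_band`` (cancellous under the implant apex).
    """
    if params is None:
        params = ProxyParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)

    R, r_out = params.arc_radius, params.outer_radius
    h = params.edge_length
    a0, a1 = params.alpha_range()
    arc_len = R * (a1 - a0)
    n_u = max(4, int(round(arc_len / h)))
    n_c = max(4, int(round(2 * r_out / h)))
    alphas = np.linspace(a0, a1, n_u + 1)
    cross = np.linspace(-r_out, r_out, n_c + 1)

    # --- classify hex cells by parametric / global centroid
    ac = 0.5 * (alphas[:-1] + alphas[1:])
    cc = 0.5 * (cross[:-1] + cross[1:])
    A, XC, YC = np.meshgrid(ac, cc, cc, indexing="ij")  # (n_u, n_c, n_c)
    rho = np.hypot(XC, YC)
    inside = rho <= r_out

    tag = np.where(rho > r_out - params.cortical_thickness, _CORT, _CANC)

    nw0, nw1 = params.notch_window()
    in_notch = (A >= nw0) & (A <= nw1) & (YC > r_out - params.notch_depth) & inside
    tag = np.where(in_notch, _VIRT, tag)

    # implant: vertical cylinder in global coordinates
    gx = (R + XC) * np.cos(A)
    gy = (R + XC) * np.sin(A)
    gz = YC
    axis = params.implant_axis_point()
    r_imp = params.implant_diameter / 2
    z_bot = r_out - params.implant_length
    in_impl = (np.hypot(gx - axis[0], gy - axis[1]) <= r_imp) & (gz >= z_bot) & inside
    if (in_impl & in_notch).any():
        raise GenerationError("implant and notch regions overlap; move implant_frac "
                              "or notch_center_frac apart")
    tag = np.where(in_impl, _IMPL, tag)

    keep = np.argwhere(inside)
    if not len(keep):
        raise GenerationError("no cells inside the tube; check radii vs edge_length")

    # --- build nodes for kept cells
    def grid_id(i, j, k):
        return (i * (n_c + 1) + j) * (n_c + 1) + k

    I, J, K = keep.T
    corners = np.empty((len(I), 2, 2, 2), dtype=np.int64)
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                corners[:, di, dj, dk] = grid_id(I + di, J + dj, K + dk)
    used = np.unique(corners)
    remap = -np.ones((n_u + 1) * (n_c + 1) * (n_c + 1), dtype=np.int64)
    remap[used] = np.arange(len(used))
    corners = remap[corners]

    ui = used // ((n_c + 1) * (n_c + 1))
    rem = used % ((n_c + 1) * (n_c + 1))
    ji, ki = rem // (n_c + 1), rem % (n_c + 1)
    al = alphas[ui]
    xc, yc = cross[ji], cross[ki]
    nodes = np.stack([(R + xc) * np.cos(al), (R + xc) * np.sin(al), yc], axis=1)

    tets = _kuhn_tets(corners)
    region = np.repeat(tag[I, J, K], 6)

    mesh = TetMesh(nodes, tets, region).orient()

    # --- node sets
    node_region: Dict[int, np.ndarray] = {}
    for t in (_CORT, _CANC, _IMPL, _VIRT):
        sel = region == t
        node_region[t] = np.unique(tets[sel]) if sel.any() else np.array([], dtype=np.int64)
    bone_nodes = np.union1d(node_region[_CORT], node_region[_CANC])

    bnodes = np.unique(mesh.boundary_faces())
    is_boundary = np.zeros(mesh.n_nodes, dtype=bool)
    is_boundary[bnodes] = True

    cap_a = np.flatnonzero(ui == 0)
    cap_b = np.flatnonzero(ui == n_u)
    in_bone = np.zeros(mesh.n_nodes, dtype=bool); in_bone[bone_nodes] = True
    in_impl_n = np.zeros(mesh.n_nodes, dtype=bool); in_impl_n[node_region[_IMPL]] = True
    in_cap = np.zeros(mesh.n_nodes, dtype=bool); in_cap[cap_a] = True; in_cap[cap_b] = True

    inner_if = np.intersect1d(node_region[_CORT], node_region[_CANC])
    in_inner = np.zeros(mesh.n_nodes, dtype=bool); in_inner[inner_if] = True
    # a staircase node of a one-cell-thick shell can touch both surfaces;
    # the interface wins so the radial seed sets stay disjoint
    outer = np.flatnonzero(is_boundary & in_bone & ~in_cap & ~in_impl_n & ~in_inner)
    impl_surf = np.intersect1d(node_region[_IMPL], bone_nodes)
    crest = np.intersect1d(impl_surf, node_region[_CORT])
    impl_top = np.flatnonzero(is_boundary & in_impl_n & ~in_bone)
    if not (len(crest) and len(impl_top) and len(inner_if) and len(outer)):
        raise GenerationError("degenerate proxy: an interface node set came out empty; "
                              "refine edge_length or enlarge the geometry")

    mesh.node_sets.update(
        end_cap_A=cap_a, end_cap_B=cap_b, outer_surface=outer,
        inner_interface=inner_if, implant_surface=impl_surf,
        crest_ring=crest, implant_top=impl_top,
    )

    # --- element sets (defined from the same analytic geometry)
    cent = mesh.centroids()
    cent_alpha = np.arctan2(cent[:, 1], cent[:, 0])
    is_bone_e = np.isin(region, sorted(BONE_TAGS))
    ridge = is_bone_e & (cent_alpha >= nw0) & (cent_alpha <= nw1) \
        & (cent[:, 2] > r_out - 2 * params.notch_depth)
    in_crest = np.zeros(mesh.n_nodes, dtype=bool); in_crest[crest] = True
    crest_e = (region == _CORT) & in_crest[tets].any(axis=1)
    d_axis = np.hypot(cent[:, 0] - axis[0], cent[:, 1] - axis[1])
    apical = (region == _CANC) & (cent[:, 2] <= z_bot + 0.75 * h) & (d_axis <= r_imp + h)
    mesh.elem_sets.update(
        ridge_band=np.flatnonzero(ridge),
        crest_band=np.flatnonzero(crest_e),
        apical_band=np.flatnonzero(apical),
    )
    for name in ("ridge_band", "crest_band", "apical_band"):
        if not len(mesh.elem_sets[name]):
            raise GenerationError(f"element set {name} is empty; refine the mesh")

    # --- optional jitter (interior, single-region nodes only)
    if params.jitter > 0:
        rng = np.random.default_rng(params.seed)
        first_tag = np.full(mesh.n_nodes, -1, dtype=np.int64)
        mixed = np.zeros(mesh.n_nodes, dtype=bool)
        for e in range(mesh.n_elements):
            t = region[e]
            for nd in tets[e]:
                if first_tag[nd] == -1:
                    first_tag[nd] = t
                elif first_tag[nd] != t:
                    mixed[nd] = True
        movable = ~is_boundary & ~mixed & ~in_cap
        delta = rng.uniform(-1, 1, size=(int(movable.sum()), 3)) * params.jitter * h
        mesh.nodes[movable] += delta
        if (signed_volumes(mesh.nodes, mesh.tets) <= 0).any():
            raise GenerationError("jitter inverted elements; reduce jitter")

    return mesh
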