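"""Mesh I/O: VTK legacy ASCII unstructured grids and Gmsh 4.1 ASCII.

Both formats are line-oriented ASCII and are parsed directly; the writer emits
deterministic byte output for a fixed mesh so round-trips and regression
fixtures are stable.

Entity sets survive a VTK round trip through conventional data-array names:

* ``nodeset_<name>``   POINT_DATA 0/1 indicator,
* ``elemset_<name>``   CELL_DATA 0/1 indicator,
* ``faceset_<name>``   CELL_DATA integer bitmask of local faces (bit ``a`` set
  when the face opposite local node ``a`` belongs to the set).

Anything else under POINT_DATA / CELL_DATA is returned as a named field.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np

from .mesh import MeshError, TetMesh, canonical_faces

_VTK_TET = 10


class FormatError(MeshError):
    """Raised when a mesh file cannot be interpreted."""


# ----------------------------------------------------------------------
# public API
# ----------------------------------------------------------------------

def read_mesh(path, fmt: str | None = None) -> TetMesh:
    """Read a tetrahedral mesh from a VTK legacy or Gmsh 4.1 ASCII file.

    ``fmt`` is ``"vtk"`` or ``"gmsh"``; when omitted it is inferred from the
    file suffix (``.vtk`` / ``.msh``).
    """
    path = Path(path)
    if fmt is None:
        fmt = {"vtk": "vtk", "msh": "gmsh"}.get(path.suffix.lstrip("."), None)
        if fmt is None:
            raise FormatError(f"cannot infer format from suffix of {path.name}; pass fmt=")
    if fmt == "vtk":
        mesh, _, _ = _read_vtk(path)
        return mesh
    if fmt == "gmsh":
        return _read_gmsh(path)
    raise FormatError(f"unsupported format {fmt!r}; expected 'vtk' or 'gmsh'")


def read_vtk_with_fields(path) -> Tuple[TetMesh, Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Read a VTK file returning ``(mesh, node_fields, elem_fields)``."""
    return _read_vtk(Path(path))


def write_mesh(
    mesh: TetMesh,
    path,
    node_fields: Mapping[str, np.ndarray] | None = None,
    elem_fields: Mapping[str, np.ndarray] | None = None,
    fmt: str = "vtk",
) -> None:
    """Write the mesh (plus optional per-node / per-element data) as legacy VTK."""
    if fmt != "vtk":
        raise FormatError(f"only 'vtk' output is supported, got {fmt!r}")
    node_fields = dict(node_fields or {})
    elem_fields = dict(elem_fields or {})
    for name, arr in node_fields.items():
        if len(np.asarray(arr)) != mesh.n_nodes:
            raise MeshError(f"node field {name!r} has length {len(arr)}, expected {mesh.n_nodes}")
    for name, arr in elem_fields.items():
        if len(np.asarray(arr)) != mesh.n_elements:
            raise MeshError(f"element field {name!r} has length {len(arr)}, expected {mesh.n_elements}")

    lines = []
    lines.append("# vtk DataFile Version 3.0")
    lines.append("orthobone tetrahedral mesh")
    lines.append("ASCII")
    lines.append("DATASET UNSTRUCTURED_GRID")
    lines.append(f"POINTS {mesh.n_nodes} double")
    for p in mesh.nodes:
        lines.append(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}")
    m = mesh.n_elements
    lines.append(f"CELLS {m} {5 * m}")
    for t in mesh.tets:
        lines.append(f"4 {t[0]} {t[1]} {t[2]} {t[3]}")
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["10"] * m)

    # ---- cell data
    cell_arrays: Dict[str, np.ndarray] = {"region": mesh.region}
    for name, idx in mesh.elem_sets.items():
        ind = np.zeros(m, dtype=np.int64)
        ind[idx] = 1
        cell_arrays[f"elemset_{name}"] = ind
    for name, tris in mesh.face_sets.items():
        cell_arrays[f"faceset_{name}"] = _faceset_to_mask(mesh, tris)
    cell_arrays.update({k: np.asarray(v) for k, v in elem_fields.items()})
    lines.append(f"CELL_DATA {m}")
    for name, arr in cell_arrays.items():
        _emit_array(lines, name, np.asarray(arr))

    # ---- point data
    point_arrays: Dict[str, np.ndarray] = {}
    for name, idx in mesh.node_sets.items():
        ind = np.zeros(mesh.n_nodes, dtype=np.int64)
        ind[idx] = 1
        point_arrays[f"nodeset_{name}"] = ind
    point_arrays.update({k: np.asarray(v) for k, v in node_fields.items()})
    if point_arrays:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_arrays.items():
            _emit_array(lines, name, np.asarray(arr))

    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# VTK helpers
# ----------------------------------------------------------------------

def _faceset_to_mask(mesh: TetMesh, tris: np.ndarray) -> np.ndarray:
    faces = canonical_faces(mesh.tets)            # (m, 4, 3) sorted triples
    lookup = {}
    for e in range(len(faces)):
        for a in range(4):
            lookup.setdefault(tuple(faces[e, a]), []).append((e, a))
    mask = np.zeros(mesh.n_elements, dtype=np.int64)
    for t in tris:
        owners = lookup.get(tuple(t), [])
        if len(owners) != 1:
            raise MeshError(
                f"face-set triangle {tuple(int(v) for v in t)} is not a boundary face "
                f"(owned by {len(owners)} tets)"
            )
        e, a = owners[0]
        mask[e] |= 1 << a
    return mask


def _mask_to_faceset(tets: np.ndarray, mask: np.ndarray) -> np.ndarray:
    faces = canonical_faces(tets)
    tris = []
    for e in np.flatnonzero(mask):
        for a in range(4):
            if mask[e] & (1 << a):
                tris.append(faces[e, a])
    return np.array(tris, dtype=np.int64).reshape(-1, 3)


def _emit_array(lines, name, arr) -> None:
    if arr.ndim == 1:
        kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
        lines.append(f"SCALARS {name} {kind} 1")
        lines.append("LOOKUP_TABLE default")
        if kind == "int":
            lines.extend(str(int(v)) for v in arr)
        else:
            lines.extend(f"{float(v):.17g}" for v in arr)
    elif arr.ndim == 2 and arr.shape[1] == 3:
        lines.append(f"VECTORS {name} double")
        lines.extend(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in arr)
    else:
        raise MeshError(f"cannot emit array {name!r} of shape {arr.shape}")


def _read_vtk(path: Path):
    tokens = _Tokens(path)
    header = tokens.text
    if "DATASET" not in header:
        raise FormatError(f"{path.name}: not a legacy VTK file")
    dataset = re.search(r"DATASET\s+(\w+)", header).group(1)
    if dataset != "UNSTRUCTURED_GRID":
        raise FormatError(f"{path.name}: dataset {dataset} is not UNSTRUCTURED_GRID")

    tokens.seek_keyword("POINTS")
    n = tokens.next_int(); tokens.next()          # dtype token
    nodes = tokens.next_floats(3 * n).reshape(n, 3)

    tokens.seek_keyword("CELLS")
    m = tokens.next_int(); total = tokens.next_int()
    raw = tokens.next_ints(total)
    tokens.seek_keyword("CELL_TYPES")
    mt = tokens.next_int()
    if mt != m:
        raise FormatError(f"{path.name}: CELL_TYPES count {mt} != CELLS count {m}")
    ctypes = tokens.next_ints(m)
    bad = np.flatnonzero(ctypes != _VTK_TET)
    if bad.size:
        raise FormatError(
            f"{path.name}: unsupported cell type {int(ctypes[bad[0]])} at cell {int(bad[0])}; "
            "only tetrahedra (VTK type 10) are supported"
        )
    tets = np.empty((m, 4), dtype=np.int64)
    pos = 0
    for e in range(m):
        npts = raw[pos]
        if npts != 4:
            raise FormatError(f"{path.name}: cell {e} has {npts} points, expected 4")
        tets[e] = raw[pos + 1: pos + 5]
        pos += 5

    cell_arrays = tokens.read_attributes("CELL_DATA", m)
    point_arrays = tokens.read_attributes("POINT_DATA", n)

    if "region" not in cell_arrays:
        raise FormatError(
            f"{path.name}: no CELL_DATA array named 'region'; tag every element with an "
            "integer region id (cortical=1, cancellous=2, implant=3, tooth=4, virtual=9)"
        )
    region = cell_arrays.pop("region").astype(np.int64)

    node_sets, elem_sets, face_sets = {}, {}, {}
    elem_fields: Dict[str, np.ndarray] = {}
    node_fields: Dict[str, np.ndarray] = {}
    for name, arr in cell_arrays.items():
        if name.startswith("elemset_"):
            elem_sets[name[len("elemset_"):]] = np.flatnonzero(arr.astype(np.int64))
        elif name.startswith("faceset_"):
            face_sets[name[len("faceset_"):]] = _mask_to_faceset(tets, arr.astype(np.int64))
        else:
            elem_fields[name] = arr
    for name, arr in point_arrays.items():
        if name.startswith("nodeset_"):
            node_sets[name[len("nodeset_"):]] = np.flatnonzero(arr.astype(np.int64))
        else:
            node_fields[name] = arr

    mesh = TetMesh(nodes, tets, region, node_sets, face_sets, elem_sets).orient()
    return mesh, node_fields, elem_fields


class _Tokens:
    """Whitespace token stream over an ASCII VTK file."""

    def __init__(self, path: Path):
        self.text = path.read_text()
        self.toks = self.text.split()
        self.i = 0

    def next(self) -> str:
        if self.i >= len(self.toks):
            raise FormatError("unexpected end of file")
        t = self.toks[self.i]
        self.i += 1
        return t

    def next_int(self) -> int:
        return int(self.next())

    def next_ints(self, k: int) -> np.ndarray:
        out = np.array(self.toks[self.i: self.i + k], dtype=np.int64)
        if len(out) != k:
            raise FormatError("unexpected end of file in integer block")
        self.i += k
        return out

    def next_floats(self, k: int) -> np.ndarray:
        out = np.array(self.toks[self.i: self.i + k], dtype=float)
        if len(out) != k:
            raise FormatError("unexpected end of file in float block")
        self.i += k
        return out

    def seek_keyword(self, kw: str) -> None:
        while self.i < len(self.toks):
            if self.toks[self.i] == kw:
                self.i += 1
                return
            self.i += 1
        raise FormatError(f"keyword {kw} not found")

    def read_attributes(self, section: str, count: int) -> Dict[str, np.ndarray]:
        """Parse SCALARS/VECTORS arrays of one POINT_DATA/CELL_DATA section."""
        save = self.i
        self.i = 0
        try:
            self.seek_keyword(section)
        except FormatError:
            self.i = save
            return {}
        self.next_int()
        arrays: Dict[str, np.ndarray] = {}
        while self.i < len(self.toks):
            kw = self.toks[self.i]
            if kw in ("CELL_DATA", "POINT_DATA"):
                break
            if kw == "SCALARS":
                self.i += 1
                name = self.next(); dtype = self.next()
                ncomp = 1
                if self.i < len(self.toks) and self.toks[self.i].isdigit():
                    ncomp = self.next_int()
                if self.toks[self.i] == "LOOKUP_TABLE":
                    self.i += 2
                vals = self.next_floats(count * ncomp)
                arr = vals.reshape(count, ncomp) if ncomp > 1 else vals
                arrays[name] = arr.astype(np.int64) if dtype in ("int", "long", "short") else arr
            elif kw == "VECTORS":
                self.i += 1
                name = self.next(); self.next()
                arrays[name] = self.next_floats(3 * count).reshape(count, 3)
            else:
                self.i += 1
        self.i = save
        return arrays


# ----------------------------------------------------------------------
# Gmsh 4.1 ASCII
# ----------------------------------------------------------------------

def _read_gmsh(path: Path) -> TetMesh:
    text = path.read_text()
    sections = dict(re.findall(r"\$(\w+)\n(.*?)\n\$End\1", text, flags=re.S))
    if "MeshFormat" not in sections:
        raise FormatError(f"{path.name}: missing $MeshFormat; not a Gmsh file")
    version = sections["MeshFormat"].split()[0]
    if not version.startswith("4"):
        raise FormatError(f"{path.name}: Gmsh format {version} unsupported; need 4.x ASCII")
    if "Nodes" not in sections or "Elements" not in sections:
        raise FormatError(f"{path.name}: missing $Nodes/$Elements")

    phys_names: Dict[Tuple[int, int], str] = {}
    if "PhysicalNames" in sections:
        lines = sections["PhysicalNames"].strip().split("\n")
        for line in lines[1:]:
            dim, tag, name = line.split(maxsplit=2)
            phys_names[(int(dim), int(tag))] = name.strip().strip('"')

    # entity -> physical tag (first physical group of each entity)
    ent_phys: Dict[Tuple[int, int], int] = {}
    if "Entities" in sections:
        toks = sections["Entities"].split()
        it = iter(toks)
        npt, ncv, nsf, nvl = (int(next(it)) for _ in range(4))
        for _ in range(npt):
            tag = int(next(it)); [next(it) for _ in range(3)]
            nphys = int(next(it))
            phys = [int(next(it)) for _ in range(nphys)]
            if phys:
                ent_phys[(0, tag)] = phys[0]
        for dim, ndim in ((1, ncv), (2, nsf), (3, nvl)):
            for _ in range(ndim):
                tag = int(next(it)); [next(it) for _ in range(6)]
                nphys = int(next(it))
                phys = [int(next(it)) for _ in range(nphys)]
                nb = int(next(it)); [next(it) for _ in range(nb)]
                if phys:
                    ent_phys[(dim, tag)] = phys[0]

    # nodes
    toks = sections["Nodes"].split()
    it = iter(toks)
    nblocks = int(next(it)); ntotal = int(next(it)); next(it); next(it)
    coords = np.empty((ntotal, 3))
    tag_to_idx: Dict[int, int] = {}
    k = 0
    for _ in range(nblocks):
        next(it); next(it); next(it)
        nn = int(next(it))
        tags = [int(next(it)) for _ in range(nn)]
        for t in tags:
            tag_to_idx[t] = k + tags.index(t)  # placeholder, fixed below
        for j, t in enumerate(tags):
            tag_to_idx[t] = k + j
            coords[k + j] = (float(next(it)), float(next(it)), float(next(it)))
        k += nn
    coords = coords[:k]

    # elements
    toks = sections["Elements"].split()
    it = iter(toks)
    nblocks = int(next(it)); next(it); next(it); next(it)
    tets, regions = [], []
    face_sets: Dict[str, list] = {}
    for _ in range(nblocks):
        dim = int(next(it)); ent = int(next(it)); etype = int(next(it)); ne = int(next(it))
        nper = {1: 2, 2: 3, 3: 4, 4: 4, 15: 1}.get(etype)
        if nper is None:
            raise FormatError(f"{path.name}: unsupported Gmsh element type {etype}")
        phys = ent_phys.get((dim, ent))
        for _ in range(ne):
            next(it)  # element tag
            conn = [tag_to_idx[int(next(it))] for _ in range(nper)]
            if etype == 4:
                tets.append(conn)
                if phys is None:
                    raise FormatError(
                        f"{path.name}: tetrahedron in entity {ent} has no physical group; "
                        "tag volume regions with physical groups"
                    )
                regions.append(phys)
            elif etype == 2 and phys is not None:
                name = phys_names.get((2, phys), f"surface_{phys}")
                face_sets.setdefault(name, []).append(sorted(conn))
    if not tets:
        raise FormatError(f"{path.name}: no tetrahedra found")

    mesh = TetMesh(
        coords,
        np.array(tets, dtype=np.int64),
        np.array(regions, dtype=np.int64),
        face_sets={k: np.array(v, dtype=np.int64) for k, v in face_sets.items()},
    ).orient()
    return mesh
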