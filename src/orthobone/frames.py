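"""Per-element orthotropic material frames from harmonic-field gradients.

Each bone element gets a right-handed orthonormal triad (columns of a 3x3
matrix): e1 radial, e2 tangential/circumferential, e3 axial/longitudinal —
the axis convention under which the nine orthotropic constants are tabulated.

``build_frames`` is the per-element (field-driven) construction;
``zoned_frames`` is the simplified comparator that assigns one frame per zone
of the bone, emulating the few-local-systems modelling style that the
field-driven method improves upon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .mesh import BONE_TAGS, TetMesh

_DEG = np.pi / 180.0


class FrameError(ValueError):
    pass


@dataclass
class FrameField:
    """Per-element material triads.

    ``R`` has shape (m, 3, 3) with columns (e1, e2, e3); NaN for elements
    outside the frame domain (virtual fill, implant).  ``fallback`` flags
    elements whose frame was copied from a neighbour because their own
    gradients were degenerate.
    """

    R: np.ndarray
    defined: np.ndarray            # bool (m,)
    fallback: np.ndarray           # bool (m,)

    def e(self, k: int) -> np.ndarray:
        """k-th axis (1-based) per element, shape (m, 3)."""
        return self.R[:, :, k - 1]


def build_frames(
    grad_long: np.ndarray,
    grad_rad: np.ndarray,
    mesh: TetMesh,
    regions: Sequence = ("cortical", "cancellous"),
    reference: Callable[[np.ndarray], np.ndarray] | None = None,
    fallback: bool = True,
    min_angle_deg: float = 1.0,
) -> FrameField:
    """Gram-Schmidt frames: e3 along grad_long, e1 the radial residual, e2 = e3 x e1.

    An element is degenerate when its longitudinal gradient vanishes
    (|g| < 1e-12) or the two gradients are within ``min_angle_deg`` of
    parallel; degenerate elements inherit the frame of the nearest
    non-degenerate element (centroid distance) and are flagged, unless
    ``fallback`` is disabled, in which case they are an error.

    ``reference``: optional callable mapping centroids (k, 3) to unit axial
    directions; e3 signs are chosen so e3 . ref >= 0, making frames comparable
    across runs (the elastic response itself is insensitive to axis sign).
    """
    elems = mesh.elements_of(regions)
    m = mesh.n_elements
    R = np.full((m, 3, 3), np.nan)
    defined = np.zeros(m, dtype=bool)
    fb = np.zeros(m, dtype=bool)

    gl = np.asarray(grad_long, dtype=float)[elems]
    gr = np.asarray(grad_rad, dtype=float)[elems]
    if not (np.isfinite(gl).all() and np.isfinite(gr).all()):
        raise FrameError("gradients undefined on some bone elements")

    nl = np.linalg.norm(gl, axis=1)
    nr = np.linalg.norm(gr, axis=1)
    ok = (nl > 1e-12) & (nr > 1e-12)
    e3 = np.zeros_like(gl)
    e3[ok] = gl[ok] / nl[ok, None]
    # residual of the radial gradient orthogonal to e3
    proj = np.einsum("ei,ei->e", gr, e3)
    r_perp = gr - proj[:, None] * e3
    sin_angle = np.divide(np.linalg.norm(r_perp, axis=1), nr,
                          out=np.zeros_like(nr), where=nr > 0)
    ok &= sin_angle > np.sin(min_angle_deg * _DEG)

    if reference is not None:
        t = np.asarray(reference(mesh.centroids(elems)), dtype=float)
        sgn = np.where(np.einsum("ei,ei->e", e3, t) < 0, -1.0, 1.0)
        e3 *= sgn[:, None]
        r_perp_sign = r_perp  # e1 orientation kept from the radial field

    e1 = np.zeros_like(gl)
    e1[ok] = r_perp[ok] / np.linalg.norm(r_perp[ok], axis=1)[:, None]
    e2 = np.cross(e3, e1)

    good = elems[ok]
    R[good, :, 0] = e1[ok]
    R[good, :, 1] = e2[ok]
    R[good, :, 2] = e3[ok]
    defined[good] = True

    bad = elems[~ok]
    if bad.size:
        if not fallback:
            raise FrameError(
                f"{bad.size} degenerate elements (parallel or vanishing gradients), "
                f"e.g. {bad[:10].tolist()}")
        if not good.size:
            raise FrameError("all elements degenerate; cannot apply fallback")
        tree = cKDTree(mesh.centroids(good))
        _, nearest = tree.query(mesh.centroids(bad))
        R[bad] = R[good[nearest]]
        defined[bad] = True
        fb[bad] = True

    return FrameField(R=R, defined=defined, fallback=fb)


def zoned_frames(
    mesh: TetMesh,
    phi_long: np.ndarray,
    n_zones: int,
    frames: FrameField | None = None,
    zone_axes: np.ndarray | None = None,
    regions: Sequence = ("cortical", "cancellous"),
) -> FrameField:
    """Simplified comparator: one shared frame per longitudinal zone.

    Bone elements are binned into ``n_zones`` equal-width intervals of their
    mean longitudinal field value (a neutral, geometry-free analog of anatomic
    zoning).  Each zone's frame is the per-element frame of its representative
    element — the one closest to the zone's volume centroid — or the matching
    row of ``zone_axes`` (shape (n_zones, 3, 3)) when given.
    """
    if n_zones < 1:
        raise FrameError("n_zones must be >= 1")
    if zone_axes is None and frames is None:
        raise FrameError("provide per-element frames (or explicit zone_axes)")
    elems = mesh.elements_of(regions)
    vals = np.asarray(phi_long, dtype=float)[mesh.tets[elems]].mean(axis=1)
    if not np.isfinite(vals).all():
        raise FrameError("phi_long undefined on some bone elements")

    lo, hi = vals.min(), vals.max()
    edges = np.linspace(lo, hi, n_zones + 1)
    zone = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, n_zones - 1)

    m = mesh.n_elements
    R = np.full((m, 3, 3), np.nan)
    defined = np.zeros(m, dtype=bool)
    cent = mesh.centroids(elems)
    for z in range(n_zones):
        members = np.flatnonzero(zone == z)
        if not members.size:
            raise FrameError(
                f"zone {z} of {n_zones} is empty; use fewer zones for this mesh")
        if zone_axes is not None:
            Rz = np.asarray(zone_axes[z], dtype=float)
        else:
            c = cent[members].mean(axis=0)
            rep = members[np.argmin(np.linalg.norm(cent[members] - c, axis=1))]
            Rz = frames.R[elems[rep]]
        _check_orthonormal(Rz)
        R[elems[members]] = Rz
        defined[elems[members]] = True
    return FrameField(R=R, defined=defined, fallback=np.zeros(m, dtype=bool))


def _check_orthonormal(R: np.ndarray, tol: float = 1e-8) -> None:
    if not np.allclose(R.T @ R, np.eye(3), atol=tol) or np.linalg.det(R) < 0:
        raise FrameError("zone frame is not a right-handed orthonormal triad")


def frame_quality(
    frames: FrameField,
    mesh: TetMesh,
    reference: Callable[[np.ndarray], np.ndarray],
    elems: np.ndarray | None = None,
) -> "tuple[np.ndarray, Dict[str, float]]":
    """Angular deviation (degrees) of e3 from an analytic reference axis.

    Deviation is ``arccos(|e3 . t_ref|)`` in [0, 90] (sign-blind: an axis, not
    a direction).  Returns the per-element array (NaN where no frame is
    defined / outside ``elems``) and a mean/max summary over the scored set.
    """
    if elems is None:
        elems = np.flatnonzero(frames.defined)
    else:
        elems = np.asarray(elems)
        elems = elems[frames.defined[elems]]
    t = np.asarray(reference(mesh.centroids(elems)), dtype=float)
    t = t / np.linalg.norm(t, axis=1)[:, None]
    e3 = frames.R[elems, :, 2]
    cosang = np.clip(np.abs(np.einsum("ei,ei->e", e3, t)), 0.0, 1.0)
    dev = np.degrees(np.arccos(cosang))
    out = np.full(mesh.n_elements, np.nan)
    out[elems] = dev
    summary = {"mean": float(dev.mean()), "max": float(dev.max()),
               "n": int(len(dev))}
    return out, summary
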