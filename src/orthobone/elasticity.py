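"""Orthotropic elasticity: 6x6 compliance/stiffness, frame rotation, and
Voigt-Reuss-Hill effective isotropic moduli.

Voigt notation throughout: component order (11, 22, 33, 23, 13, 12) with
engineering (doubled) shear strains, so S44 pairs with G23, S55 with G13 and
S66 with G12 under the radial(1)/tangential(2)/axial(3) axis naming of the
bone constants.  Moduli in GPa, compliances in 1/GPa.

Poisson convention: S_ij = -nu_ij / E_i, i.e. nu_ij is the contraction in j
per unit extension in i under uniaxial stress along i (the dominant
engineering convention; it renders both tabulated bone rows thermodynamically
admissible and reproduces the published cortical effective modulus).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Union

import numpy as np

_VOIGT_PAIRS = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]


class AdmissibilityError(ValueError):
    """Raised when a constant set yields a non-positive-definite compliance."""


@dataclass(frozen=True)
class IsotropicConstants:
    """Isotropic material: Young's modulus E (GPa), Poisson ratio nu."""

    E: float
    nu: float

    def __post_init__(self):
        if self.E <= 0:
            raise AdmissibilityError(f"E must be positive, got {self.E}")
        if not -1.0 < self.nu < 0.5:
            raise AdmissibilityError(f"nu must be in (-1, 0.5), got {self.nu}")

    @property
    def G(self) -> float:
        return self.E / (2.0 * (1.0 + self.nu))

    def as_orthotropic(self) -> "OrthotropicConstants":
        return OrthotropicConstants(self.E, self.E, self.E,
                                    self.G, self.G, self.G,
                                    self.nu, self.nu, self.nu)

    def stiffness(self) -> np.ndarray:
        return stiffness_from_compliance(compliance_from_constants(self.as_orthotropic()))


@dataclass(frozen=True)
class OrthotropicConstants:
    """Nine engineering constants of an orthotropic solid (GPa, dimensionless).

    Axes: 1 radial, 2 tangential (circumferential), 3 axial (longitudinal).
    """

    E1: float
    E2: float
    E3: float
    G12: float
    G13: float
    G23: float
    nu12: float
    nu13: float
    nu23: float

    def __post_init__(self):
        for name in ("E1", "E2", "E3", "G12", "G13", "G23"):
            if getattr(self, name) <= 0:
                raise AdmissibilityError(f"{name} must be positive")


def compliance_from_constants(c: OrthotropicConstants) -> np.ndarray:
    """6x6 compliance S (1/GPa); raises if not positive definite."""
    S = np.zeros((6, 6))
    S[0, 0] = 1.0 / c.E1
    S[1, 1] = 1.0 / c.E2
    S[2, 2] = 1.0 / c.E3
    S[3, 3] = 1.0 / c.G23
    S[4, 4] = 1.0 / c.G13
    S[5, 5] = 1.0 / c.G12
    S[0, 1] = S[1, 0] = -c.nu12 / c.E1
    S[0, 2] = S[2, 0] = -c.nu13 / c.E1
    S[1, 2] = S[2, 1] = -c.nu23 / c.E2
    _check_pd(S)
    return S


def _check_pd(S: np.ndarray) -> None:
    for k in range(1, 7):
        if np.linalg.det(S[:k, :k]) <= 0:
            raise AdmissibilityError(
                f"compliance is not positive definite: leading {k}x{k} minor "
                "is non-positive (thermodynamically inadmissible constants)")


def stiffness_from_compliance(S: np.ndarray) -> np.ndarray:
    """Invert compliance to stiffness; verifies C @ S == I to 1e-10."""
    S = np.asarray(S, dtype=float)
    try:
        C = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise AdmissibilityError(f"singular compliance matrix: {exc}") from exc
    if not np.allclose(C @ S, np.eye(6), atol=1e-10):
        raise AdmissibilityError("compliance inversion failed the identity check")
    return 0.5 * (C + C.T)


def bond_stress_matrix(R: np.ndarray) -> np.ndarray:
    """6x6 Bond matrix M with sigma_voigt(R s R^T) = M sigma_voigt(s).

    Built constructively from the tensor transform so the component order and
    shear factors are correct by definition rather than by transcription.
    """
    R = np.asarray(R, dtype=float)
    M = np.empty((6, 6))
    for J, (p, q) in enumerate(_VOIGT_PAIRS):
        s = np.zeros((3, 3))
        s[p, q] = s[q, p] = 1.0
        t = R @ s @ R.T
        for I, (i, j) in enumerate(_VOIGT_PAIRS):
            M[I, J] = t[i, j]
    return M


def rotate_stiffness(C_local: np.ndarray, frame: np.ndarray) -> np.ndarray:
    """Stiffness in global axes for a material triad ``frame`` (columns = local axes).

    Uses the Bond congruence C_global = M C_local M^T, equivalent to the
    fourth-order rotation C'_ijkl = R_ip R_jq R_kr R_ls C_pqrs.
    """
    R = np.asarray(frame, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-8) \
            or np.linalg.det(R) < 0:
        raise ValueError("frame must be a right-handed orthonormal 3x3 triad")
    M = bond_stress_matrix(R)
    C = M @ np.asarray(C_local, dtype=float) @ M.T
    return 0.5 * (C + C.T)


def rotate_stiffness_batch(C_local: np.ndarray, frames: np.ndarray) -> np.ndarray:
    """Rotate one local stiffness by many frames, shape (k, 3, 3) -> (k, 6, 6)."""
    frames = np.asarray(frames, dtype=float)
    out = np.empty((len(frames), 6, 6))
    for i, R in enumerate(frames):
        out[i] = rotate_stiffness(C_local, R)
    return out


@dataclass(frozen=True)
class EffectiveIsotropic:
    """Voigt / Reuss bounds and Hill mean of the isotropized bulk and shear moduli."""

    K_V: float
    G_V: float
    K_R: float
    G_R: float

    @property
    def K_H(self) -> float:
        return 0.5 * (self.K_V + self.K_R)

    @property
    def G_H(self) -> float:
        return 0.5 * (self.G_V + self.G_R)

    @staticmethod
    def _to_E_nu(K: float, G: float) -> "tuple[float, float]":
        return 9 * K * G / (3 * K + G), (3 * K - 2 * G) / (2 * (3 * K + G))

    @property
    def E_V(self): return self._to_E_nu(self.K_V, self.G_V)[0]
    @property
    def nu_V(self): return self._to_E_nu(self.K_V, self.G_V)[1]
    @property
    def E_R(self): return self._to_E_nu(self.K_R, self.G_R)[0]
    @property
    def nu_R(self): return self._to_E_nu(self.K_R, self.G_R)[1]
    @property
    def E_H(self): return self._to_E_nu(self.K_H, self.G_H)[0]
    @property
    def nu_H(self): return self._to_E_nu(self.K_H, self.G_H)[1]

    def hill_constants(self) -> IsotropicConstants:
        return IsotropicConstants(self.E_H, self.nu_H)


def voigt_reuss_hill(c: Union[OrthotropicConstants, IsotropicConstants]) -> EffectiveIsotropic:
    """Effective isotropic moduli from anisotropic constants.

    Voigt bound: orientation average at uniform strain (stiffness average);
    Reuss bound: uniform stress (compliance average); Hill estimate: the
    arithmetic mean of the two bounds.  For an isotropic input the bounds
    coincide with the input exactly.
    """
    if isinstance(c, IsotropicConstants):
        c = c.as_orthotropic()
    S = compliance_from_constants(c)
    C = stiffness_from_compliance(S)
    K_V = (C[0, 0] + C[1, 1] + C[2, 2] + 2 * (C[0, 1] + C[0, 2] + C[1, 2])) / 9.0
    G_V = (C[0, 0] + C[1, 1] + C[2, 2] - C[0, 1] - C[0, 2] - C[1, 2]
           + 3 * (C[3, 3] + C[4, 4] + C[5, 5])) / 15.0
    K_R = 1.0 / (S[0, 0] + S[1, 1] + S[2, 2] + 2 * (S[0, 1] + S[0, 2] + S[1, 2]))
    G_R = 15.0 / (4 * (S[0, 0] + S[1, 1] + S[2, 2])
                  - 4 * (S[0, 1] + S[0, 2] + S[1, 2])
                  + 3 * (S[3, 3] + S[4, 4] + S[5, 5]))
    return EffectiveIsotropic(K_V=K_V, G_V=G_V, K_R=K_R, G_R=G_R)


def material_db() -> Dict[str, Union[IsotropicConstants, OrthotropicConstants]]:
    """Published material constants used by the mandible/implant models.

    Isotropic entries are literature values for the non-bone tissues and the
    implant components; ``bone_*_iso`` are the effective isotropic bone values
    as published alongside the orthotropic rows; ``bone_*_ortho`` are the nine
    orthotropic constants of mandibular compact and cancellous bone.
    """
    return {
        "enamel": IsotropicConstants(84.1, 0.33),
        "dentin": IsotropicConstants(18.6, 0.31),
        "cartilage": IsotropicConstants(0.8, 0.35),
        "titanium": IsotropicConstants(103.4, 0.35),
        "zirconia": IsotropicConstants(200.0, 0.31),
        "bone_cortical_iso": IsotropicConstants(16.42, 0.32),
        "bone_cancellous_iso": IsotropicConstants(0.482, 0.26),
        "bone_cortical_ortho": OrthotropicConstants(
            12.7, 17.9, 22.8, 5.0, 5.5, 7.4, 0.18, 0.31, 0.28),
        "bone_cancellous_ortho": OrthotropicConstants(
            0.511, 0.114, 0.907, 0.078, 0.434, 0.081, 0.22, 0.31, 0.30),
    }


def lookup_material(name: str):
    db = material_db()
    try:
        return db[name]
    except KeyError:
        raise KeyError(f"unknown material {name!r}; available: {sorted(db)}") from None
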