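"""Elasticity tensors: compliance assembly, rotation, Voigt-Reuss-Hill."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import orthobone as ob

from _helpers import random_rotation
from orthobone.elasticity import (
    AdmissibilityError, IsotropicConstants, OrthotropicConstants,
    bond_stress_matrix, compliance_from_constants, material_db,
    rotate_stiffness, stiffness_from_compliance, voigt_reuss_hill,
)

CORT = material_db()["bone_cortical_ortho"]
CANC = material_db()["bone_cancellous_ortho"]


def voigt_to_tensor4(C):
    """Expand a 6x6 Voigt stiffness to the full 3x3x3x3 tensor (oracle helper)."""
    pairs = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
    idx = np.empty((3, 3), dtype=int)
    for I, (i, j) in enumerate(pairs):
        idx[i, j] = idx[j, i] = I
    T = np.empty((3, 3, 3, 3))
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    T[i, j, k, l] = C[idx[i, j], idx[k, l]]
    return T


def tensor4_to_voigt(T):
    pairs = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
    C = np.empty((6, 6))
    for I, (i, j) in enumerate(pairs):
        for J, (k, l) in enumerate(pairs):
            C[I, J] = T[i, j, k, l]
    return C


def test_cortical_compliance_entries():
    S = compliance_from_constants(CORT)
    assert S[0, 0] == pytest.approx(1 / 12.7, rel=1e-12)
    assert S[1, 2] == pytest.approx(-0.28 / 17.9, rel=1e-12)
    assert S[3, 3] == pytest.approx(1 / 7.4, rel=1e-12)   # S44 pairs with G23
    assert S[5, 5] == pytest.approx(1 / 5.0, rel=1e-12)   # S66 pairs with G12
    assert np.allclose(S, S.T)


def test_isotropic_closed_form():
    iso = IsotropicConstants(10.0, 0.25)
    S = compliance_from_constants(iso.as_orthotropic())
    E, nu = 10.0, 0.25
    assert S[0, 0] == pytest.approx(1 / E)
    assert S[0, 1] == pytest.approx(-nu / E)
    assert S[3, 3] == pytest.approx(2 * (1 + nu) / E)
    C = stiffness_from_compliance(S)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    assert C[0, 0] == pytest.approx(lam + 2 * mu, rel=1e-10)
    assert C[0, 1] == pytest.approx(lam, rel=1e-10)
    assert C[3, 3] == pytest.approx(mu, rel=1e-10)


def test_inadmissible_constants_rejected():
    with pytest.raises(AdmissibilityError):
        compliance_from_constants(OrthotropicConstants(
            12.7, 17.9, 22.8, 5.0, 5.5, 7.4, 5.0, 0.31, 0.28))  # nu12 = 5
    with pytest.raises(AdmissibilityError):
        IsotropicConstants(-1.0, 0.3)
    with pytest.raises(AdmissibilityError):
        IsotropicConstants(1.0, 0.7)


def test_stiffness_inverse_oracle():
    for c in (CORT, CANC):
        S = compliance_from_constants(c)
        C = stiffness_from_compliance(S)
        assert np.allclose(C @ S, np.eye(6), atol=1e-10)


def test_rotation_identity_and_isotropy():
    C = stiffness_from_compliance(compliance_from_constants(CORT))
    assert np.allclose(rotate_stiffness(C, np.eye(3)), C, atol=1e-12)
    iso = IsotropicConstants(7.0, 0.3).stiffness()
    rng = np.random.default_rng(2)
    for _ in range(10):
        R = random_rotation(rng)
        assert np.allclose(rotate_stiffness(iso, R), iso, atol=1e-10)


def test_bond_rotation_matches_tensor_loop_oracle():
    """Bond congruence equals brute-force fourth-order rotation, 100 random frames."""
    C = stiffness_from_compliance(compliance_from_constants(CORT))
    T = voigt_to_tensor4(C)
    rng = np.random.default_rng(3)
    for _ in range(100):
        R = random_rotation(rng)
        via_bond = rotate_stiffness(C, R)
        Trot = np.einsum("ip,jq,kr,ls,pqrs->ijkl", R, R, R, R, T)
        via_tensor = tensor4_to_voigt(Trot)
        assert np.allclose(via_bond, via_tensor,
                           rtol=1e-9, atol=1e-9 * np.abs(C).max())


def test_rotation_preserves_kelvin_eigenvalues():
    C = stiffness_from_compliance(compliance_from_constants(CANC))
    # Kelvin normalization: factor 2 on the shear-shear block
    W = np.diag([1, 1, 1, np.sqrt(2), np.sqrt(2), np.sqrt(2)])
    rng = np.random.default_rng(4)
    ew0 = np.sort(np.linalg.eigvalsh(W @ C @ W))
    for _ in range(10):
        R = random_rotation(rng)
        Cr = rotate_stiffness(C, R)
        ew = np.sort(np.linalg.eigvalsh(W @ Cr @ W))
        assert np.allclose(ew, ew0, rtol=1e-9)


def test_rotate_then_inverse_rotation_round_trip():
    C = stiffness_from_compliance(compliance_from_constants(CORT))
    rng = np.random.default_rng(5)
    R = random_rotation(rng)
    back = rotate_stiffness(rotate_stiffness(C, R), R.T)
    assert np.allclose(back, C, atol=1e-10 * np.abs(C).max())


def test_nonorthonormal_frame_rejected():
    C = IsotropicConstants(1.0, 0.3).stiffness()
    with pytest.raises(ValueError):
        rotate_stiffness(C, np.eye(3) * 1.1)


def test_vrh_cortical_reproduces_published_effective_moduli():
    eff = voigt_reuss_hill(CORT)
    assert eff.E_H == pytest.approx(16.42, rel=0.02)
    assert eff.nu_H == pytest.approx(0.32, rel=0.02)


def test_vrh_isotropic_fixed_point():
    iso = IsotropicConstants(5.0, 0.2)
    eff = voigt_reuss_hill(iso)
    assert eff.K_V == pytest.approx(eff.K_R, rel=1e-12)
    assert eff.G_V == pytest.approx(eff.G_R, rel=1e-12)
    assert eff.E_H == pytest.approx(5.0, rel=1e-12)
    assert eff.nu_H == pytest.approx(0.2, rel=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    E=st.tuples(*[st.floats(0.1, 50)] * 3),
    G=st.tuples(*[st.floats(0.05, 20)] * 3),
    nu=st.tuples(*[st.floats(0.0, 0.45)] * 3),
)
def test_voigt_reuss_ordering_property(E, G, nu):
    """K_R <= K_H <= K_V and G_R <= G_H <= G_V for every admissible input."""
    try:
        eff = voigt_reuss_hill(OrthotropicConstants(*E, *G, *nu))
    except AdmissibilityError:
        return  # inadmissible random draw: out of the property's domain
    tol = 1e-9
    assert eff.K_R <= eff.K_H + tol * abs(eff.K_H) <= eff.K_V + 2 * tol * abs(eff.K_V)
    assert eff.G_R <= eff.G_H + tol * abs(eff.G_H) <= eff.G_V + 2 * tol * abs(eff.G_V)


def test_material_db_contents():
    db = material_db()
    assert db["enamel"] == IsotropicConstants(84.1, 0.33)
    assert db["titanium"] == IsotropicConstants(103.4, 0.35)
    assert db["zirconia"].E == 200.0 and db["dentin"].nu == 0.31
    assert db["bone_cancellous_ortho"].E2 == 0.114
    with pytest.raises(KeyError, match="available"):
        ob.lookup_material("adamantium")


def test_bond_matrix_is_orthogonal_in_kelvin_metric():
    rng = np.random.default_rng(6)
    W = np.diag([1, 1, 1, np.sqrt(2), np.sqrt(2), np.sqrt(2)])
    for _ in range(5):
        R = random_rotation(rng)
        M = bond_stress_matrix(R)
        Mk = W @ M @ np.linalg.inv(W)
        assert np.allclose(Mk @ Mk.T, np.eye(6), atol=1e-10)
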