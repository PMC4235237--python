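"""FE solver: patch tests, frame indifference, recovery, scalar measures."""

import numpy as np
import pytest

import orthobone as ob
from orthobone.elasticity import IsotropicConstants, material_db, rotate_stiffness
from orthobone.solver import (
    BCSpec, RigidModeError, recover_fields, scalar_measures, solve_elasticity,
    solve_prescribed,
)
from _helpers import random_rotation


def uniform_C(mesh, C6):
    return np.tile(C6, (mesh.n_elements, 1, 1))


def test_uniaxial_traction_patch_test():
    """Unit box, E=1 GPa nu=0, bottom fixed, top traction: tip displacement sigma*L/E."""
    mesh = ob.generate_box(2, 2, 2)
    C = uniform_C(mesh, IsotropicConstants(1.0, 0.0).stiffness())
    sigma = 0.05  # MPa
    bcs = BCSpec(fixed=[("z0", "xyz")], tractions=[("z1", (0.0, 0.0, sigma))])
    u = solve_elasticity(mesh, C, bcs)
    # sigma[MPa] * L[mm] / E[GPa] -> mm: 0.05e-3 GPa * 1 / 1
    assert np.allclose(u[mesh.node_sets["z1"], 2], sigma * 1e-3 * 1.0 / 1.0, rtol=1e-10)
    strain, stress = recover_fields(mesh, u, C)
    assert np.allclose(stress[:, 2, 2], sigma, rtol=1e-8)
    assert np.allclose(stress[:, 0, 0], 0.0, atol=1e-12)


@pytest.mark.parametrize("material", ["iso", "ortho_rotated"])
def test_constant_strain_patch_test(material):
    """Prescribing u = A x on the boundary reproduces the constant strain exactly."""
    mesh = ob.generate_box(2, 2, 2)
    rng = np.random.default_rng(9)
    if material == "iso":
        C6 = IsotropicConstants(3.0, 0.25).stiffness()
    else:
        ortho = material_db()["bone_cortical_ortho"]
        C_local = ob.stiffness_from_compliance(ob.compliance_from_constants(ortho))
        C6 = rotate_stiffness(C_local, random_rotation(rng))
    C = uniform_C(mesh, C6)
    A = rng.normal(scale=1e-3, size=(3, 3))
    eps = 0.5 * (A + A.T)
    boundary = np.unique(mesh.boundary_faces())
    dofs = (3 * boundary[:, None] + np.arange(3)).ravel()
    vals = (mesh.nodes[boundary] @ A.T).ravel()
    u, _, _ = solve_prescribed(mesh, C, dofs, vals)
    strain, stress = recover_fields(mesh, u, C)
    assert np.allclose(strain, eps[None], atol=1e-8 * np.abs(eps).max())
    # stress equals C eps everywhere (uniform)
    assert np.allclose(stress, stress[0][None], rtol=1e-8)


def test_frame_indifference_of_rotated_problem():
    """Rotating mesh, material and loads leaves displacement magnitudes unchanged."""
    mesh = ob.generate_box(2, 1, 1, lengths=(2.0, 1.0, 1.0))
    C6 = IsotropicConstants(2.0, 0.3).stiffness()
    bcs = BCSpec(fixed=[("x0", "xyz")], node_loads=[("x1", (0.0, 0.0, -10.0))])
    u_ref = solve_elasticity(mesh, uniform_C(mesh, C6), bcs)

    th = np.radians(30.0)
    R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    rot = ob.TetMesh(mesh.nodes @ R.T, mesh.tets.copy(), mesh.region.copy(),
                     node_sets={k: v.copy() for k, v in mesh.node_sets.items()},
                     face_sets={k: v.copy() for k, v in mesh.face_sets.items()})
    bcs_rot = BCSpec(fixed=[("x0", "xyz")], node_loads=[("x1", tuple(R @ [0, 0, -10.0]))])
    u_rot = solve_elasticity(rot, uniform_C(rot, C6), bcs_rot)
    assert np.allclose(np.linalg.norm(u_rot, axis=1),
                       np.linalg.norm(u_ref, axis=1), rtol=1e-9, atol=1e-15)
    assert np.allclose(u_rot, u_ref @ R.T, atol=1e-12)


def test_orthotropic_uniaxial_compliance_oracle():
    """Uniaxial stress along the material 3-axis: strains follow the compliance row."""
    mesh = ob.generate_box(1, 1, 1)
    ortho = material_db()["bone_cortical_ortho"]
    S = ob.compliance_from_constants(ortho)
    C = uniform_C(mesh, ob.stiffness_from_compliance(S))
    sigma = 1.0  # MPa along z = material axis 3
    # 3-2-1 restraints compatible with diagonal strain (no shear coupling here)
    n000 = int(np.flatnonzero((mesh.nodes == [0, 0, 0]).all(axis=1))[0])
    n100 = int(np.flatnonzero((mesh.nodes == [1, 0, 0]).all(axis=1))[0])
    mesh.node_sets["origin"] = np.array([n000])
    mesh.node_sets["xpt"] = np.array([n100])
    bcs = BCSpec(fixed=[("z0", "z"), ("origin", "xy"), ("xpt", "y")],
                 tractions=[("z1", (0.0, 0.0, sigma))])
    u = solve_elasticity(mesh, C, bcs)
    strain, stress = recover_fields(mesh, u, C)
    s_gpa = sigma * 1e-3
    assert np.allclose(strain[:, 2, 2], S[2, 2] * s_gpa, rtol=1e-8)
    assert np.allclose(strain[:, 0, 0], S[0, 2] * s_gpa, rtol=1e-8)
    assert np.allclose(strain[:, 1, 1], S[1, 2] * s_gpa, rtol=1e-8)
    assert np.allclose(stress[:, 2, 2], sigma, rtol=1e-8)


def test_rigid_motions_produce_zero_strain(box):
    C = uniform_C(box, IsotropicConstants(1.0, 0.3).stiffness())
    u_trans = np.tile([0.1, -0.2, 0.3], (box.n_nodes, 1))
    strain, stress = recover_fields(box, u_trans, C)
    assert np.allclose(strain, 0.0, atol=1e-14)
    # infinitesimal rotation: u = W x with W skew
    W = np.array([[0, -1e-4, 0], [1e-4, 0, 0], [0, 0, 0]])
    strain, _ = recover_fields(box, box.nodes @ W.T, C)
    assert np.allclose(strain, 0.0, atol=1e-16)


def test_global_equilibrium_of_reactions():
    mesh = ob.generate_box(2, 2, 2)
    C = uniform_C(mesh, IsotropicConstants(1.0, 0.3).stiffness())
    load = np.array([3.0, -2.0, -7.0])
    bcs = BCSpec(fixed=[("z0", "xyz")], node_loads=[("z1", tuple(load))])
    _, reactions = solve_elasticity(mesh, C, bcs, return_reactions=True)
    total_reaction = reactions.sum(axis=0)
    assert np.allclose(total_reaction, -load, rtol=1e-8, atol=1e-10)


def test_insufficient_restraints_raise():
    mesh = ob.generate_box(1, 1, 1)
    C = uniform_C(mesh, IsotropicConstants(1.0, 0.3).stiffness())
    with pytest.raises(RigidModeError):
        solve_elasticity(mesh, C, BCSpec(fixed=[("z0", "z")],
                                         node_loads=[("z1", (1.0, 0, 0))]))


def test_scalar_measures_trivials_and_oracle():
    p = 2.5
    hydro = np.tile(p * np.eye(3), (1, 1, 1))
    m = scalar_measures(hydro, "stress")
    assert m["equivalent"][0] == pytest.approx(0.0, abs=1e-12)
    assert m["first_principal"][0] == pytest.approx(p)
    assert m["third_principal"][0] == pytest.approx(p)

    uni = np.zeros((1, 3, 3)); uni[0, 0, 0] = 4.0
    m = scalar_measures(uni, "stress")
    assert m["equivalent"][0] == pytest.approx(4.0)
    assert m["first_principal"][0] == pytest.approx(4.0)
    assert m["third_principal"][0] == pytest.approx(0.0, abs=1e-12)

    rng = np.random.default_rng(10)
    T = rng.normal(size=(20, 3, 3))
    T = 0.5 * (T + np.transpose(T, (0, 2, 1)))
    m = scalar_measures(T, "stress")
    # deviatoric-invariant oracle: sqrt(3 J2) with J2 = 1/2 tr(dev^2)
    dev = T - np.trace(T, axis1=1, axis2=2)[:, None, None] / 3 * np.eye(3)
    j2 = 0.5 * np.einsum("eij,eij->e", dev, dev)
    assert np.allclose(m["equivalent"], np.sqrt(3 * j2), rtol=1e-10)
    # strain variant scales by 1/(1+nu_eff)
    ms = scalar_measures(T, "strain", nu_eff=0.3)
    assert np.allclose(ms["equivalent"], np.sqrt(3 * j2) / 1.3, rtol=1e-10)


def test_isotropic_limit_equivalence_on_small_proxy(small_proxy):
    """Rotated degenerate-isotropic orthotropy matches the isotropic pipeline."""
    mesh = small_proxy
    iso = IsotropicConstants(5.0, 0.3)
    C_iso = uniform_C(mesh, iso.stiffness())
    rng = np.random.default_rng(20)
    frames = np.stack([random_rotation(rng) for _ in range(mesh.n_elements)])
    C_rot = np.stack([rotate_stiffness(iso.stiffness(), R) for R in frames])
    bcs = BCSpec(fixed=[("end_cap_A", "xyz"), ("end_cap_B", "xyz")],
                 node_loads=[("implant_top", (0.0, 0.0, -50.0))])
    elems = mesh.elements_of(["cortical", "cancellous", "implant"])
    u_iso = solve_elasticity(mesh, C_iso, bcs, elems=elems)
    u_rot = solve_elasticity(mesh, C_rot, bcs, elems=elems)
    scale = np.abs(u_iso).max()
    assert np.allclose(u_rot, u_iso, atol=1e-9 * scale)
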