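"""Synthetic geometry: box combinatorics, proxy contract, centerline tangent."""

import numpy as np
import pytest

import orthobone as ob
from orthobone.geometry import GenerationError, centerline_tangent
from orthobone.mesh import REGION_TAGS, canonical_faces


def test_box_counts_and_volume():
    m = ob.generate_box(1, 1, 1)
    assert m.n_elements == 6
    assert ob.signed_volumes(m.nodes, m.tets).sum() == pytest.approx(1.0, rel=1e-12)
    m2 = ob.generate_box(2, 2, 2, lengths=(2.0, 3.0, 4.0))
    assert m2.n_elements == 48
    assert ob.signed_volumes(m2.nodes, m2.tets).sum() == pytest.approx(24.0, rel=1e-9)


@pytest.mark.parametrize("nx,ny,nz", [(1, 2, 3), (2, 2, 2)])
def test_box_face_set_triangle_counts(nx, ny, nz):
    m = ob.generate_box(nx, ny, nz)
    assert len(m.face_sets["x0"]) == 2 * ny * nz
    assert len(m.face_sets["y1"]) == 2 * nx * nz
    assert len(m.face_sets["z0"]) == 2 * nx * ny


def test_proxy_regions_present_and_deterministic(proxy, proxy_params):
    tags = set(np.unique(proxy.region))
    assert {REGION_TAGS[r] for r in ("cortical", "cancellous", "implant", "virtual")} <= tags
    again = ob.generate_proxy(proxy_params)
    assert np.array_equal(again.tets, proxy.tets)
    assert np.allclose(again.nodes, proxy.nodes)
    assert ob.validate_mesh(proxy).ok


def test_implant_extent_matches_fixture_length(proxy, proxy_params):
    elems = proxy.elements_of("implant")
    z = proxy.nodes[np.unique(proxy.tets[elems])][:, 2]
    extent = z.max() - z.min()
    assert abs(extent - proxy_params.implant_length) <= proxy_params.edge_length


def test_implant_diameter_within_tolerance(proxy, proxy_params):
    elems = proxy.elements_of("implant")
    pts = proxy.nodes[np.unique(proxy.tets[elems])]
    axis = proxy_params.implant_axis_point()
    r = np.hypot(pts[:, 0] - axis[0], pts[:, 1] - axis[1])
    assert r.max() <= proxy_params.implant_diameter / 2 + proxy_params.edge_length


def test_virtual_fill_is_flush_with_tube(proxy, proxy_params):
    """Union of bone and virtual elements forms a closed (watertight) tube."""
    keep = proxy.elements_of(["cortical", "cancellous", "virtual", "implant"])
    sub = ob.TetMesh(proxy.nodes, proxy.tets[keep], proxy.region[keep])
    bf = sub.boundary_faces()
    # watertight: every boundary edge is shared by exactly two boundary triangles
    edges = np.vstack([bf[:, [0, 1]], bf[:, [1, 2]], bf[:, [0, 2]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    assert (counts == 2).all()
    # flush fill: the outer boundary is independent of how deep the notch cuts
    # (the fill re-tags carved cells instead of removing them)
    shallow = ob.generate_proxy(proxy_params, notch_depth=3.0)
    bf2 = ob.TetMesh(shallow.nodes, shallow.tets, shallow.region).boundary_faces()
    assert {tuple(f) for f in sub.boundary_faces()} == {tuple(f) for f in bf2}
    # virtual nodes stay within one cell of the analytic tube surface
    v_nodes = np.unique(proxy.tets[proxy.elements_of("virtual")])
    rho = np.hypot(np.hypot(proxy.nodes[v_nodes, 0], proxy.nodes[v_nodes, 1])
                   - proxy_params.arc_radius, proxy.nodes[v_nodes, 2])
    assert rho.max() <= proxy_params.outer_radius + proxy_params.edge_length


def _compact(mesh, keep):
    tets = mesh.tets[keep]
    used = np.unique(tets)
    remap = np.full(mesh.n_nodes, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return ob.TetMesh(mesh.nodes[used], remap[tets], mesh.region[keep])


def test_removing_virtual_leaves_conforming_mesh(proxy):
    sub = _compact(proxy, proxy.elements_of(["cortical", "cancellous", "implant"]))
    assert ob.validate_mesh(sub).ok


def test_implant_laterally_bonded_to_bone(proxy):
    """Every implant face is either shared with bone/implant or on the outer boundary."""
    impl = proxy.elements_of("implant")
    faces_impl = canonical_faces(proxy.tets[impl]).reshape(-1, 3)
    all_faces = canonical_faces(proxy.tets).reshape(-1, 3)
    uniq, counts = np.unique(all_faces, axis=0, return_counts=True)
    boundary = {tuple(f) for f in uniq[counts == 1]}
    impl_nodes = set(np.unique(proxy.tets[impl]))
    bone_nodes = set(np.unique(proxy.tets[proxy.elements_of(["cortical", "cancellous"])]))
    for f in faces_impl:
        tf = tuple(f)
        if tf in boundary:
            continue  # exposed platform at the crest
        assert set(f) <= impl_nodes | bone_nodes


def test_centerline_tangent_properties(proxy_params):
    rng = np.random.default_rng(11)
    pts = rng.uniform(-1, 1, (50, 3)) * 5 + proxy_params.centerline_point(0.2)
    t = centerline_tangent(proxy_params, pts)
    assert np.allclose(np.linalg.norm(t, axis=1), 1.0, atol=1e-12)
    # tangent is perpendicular to the in-plane radial direction
    radial = np.stack([pts[:, 0], pts[:, 1], np.zeros(len(pts))], axis=1)
    radial /= np.linalg.norm(radial, axis=1)[:, None]
    assert np.allclose(np.einsum("ki,ki->k", t, radial), 0.0, atol=1e-12)
    # two antipodal arc parameters differ by the arc rotation
    a0, a1 = proxy_params.alpha_range()
    t0 = centerline_tangent(proxy_params, proxy_params.centerline_point(a0))
    t1 = centerline_tangent(proxy_params, proxy_params.centerline_point(a1))
    expected = np.cos(a1 - a0)
    assert float(t0 @ t1) == pytest.approx(expected, abs=1e-12)


def test_invalid_params_raise():
    with pytest.raises(GenerationError):
        ob.ProxyParams(cortical_thickness=8.0, outer_radius=7.0)
    with pytest.raises(GenerationError):
        ob.ProxyParams(implant_diameter=17.0)
    with pytest.raises(GenerationError):
        ob.ProxyParams(edge_length=-1.0)


def test_jitter_is_seeded_and_bounded():
    base = ob.generate_proxy(ob.ProxyParams(arc_angle_deg=90, edge_length=2.0))
    j1 = ob.generate_proxy(ob.ProxyParams(arc_angle_deg=90, edge_length=2.0,
                                          jitter=0.05, seed=5))
    j2 = ob.generate_proxy(ob.ProxyParams(arc_angle_deg=90, edge_length=2.0,
                                          jitter=0.05, seed=5))
    assert np.allclose(j1.nodes, j2.nodes)
    d = np.linalg.norm(j1.nodes - base.nodes, axis=1)
    assert d.max() <= 0.05 * 2.0 * np.sqrt(3) + 1e-12
    assert d.max() > 0
    assert ob.validate_mesh(j1).ok
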