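"""Laplacians, spectral embeddings, CPD registration, joint matching."""

import numpy as np
import pytest

import fetalmorph as fm
from fetalmorph.errors import ConnectivityError, RegistrationError
from fetalmorph.spectral import lumped_mass


def tetra_mesh(offset=0.0):
    v = np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]) + offset
    f = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
    return fm.SurfaceMesh(v, f)


def rotation(deg, axis=(0, 0, 1.0)):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    a = np.deg2rad(deg)
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K


def test_laplacian_row_sums_zero():
    for kind in ("cotangent", "combinatorial"):
        L = fm.mesh_laplacian(tetra_mesh(), kind=kind)
        assert L.shape == (4, 4)
        assert np.abs(np.asarray(L.sum(axis=1))).max() < 1e-10


def test_laplacian_is_psd(sphere10):
    L = fm.mesh_laplacian(sphere10)
    rng = np.random.default_rng(0)
    for _ in range(5):
        x = rng.normal(size=L.shape[0])
        assert x @ (L @ x) >= -1e-8


def test_disconnected_mesh_raises():
    a, b = tetra_mesh(), tetra_mesh(offset=10.0)
    joined = fm.SurfaceMesh(np.vstack([a.vertices, b.vertices]),
                            np.vstack([a.faces, b.faces + 4]))
    with pytest.raises(ConnectivityError):
        fm.mesh_laplacian(joined)


def test_zero_eigenvalue_multiplicity_counts_components():
    """One zero mode per connected component of the graph."""
    a, b = tetra_mesh(), tetra_mesh(offset=10.0)
    joined = fm.SurfaceMesh(np.vstack([a.vertices, b.vertices]),
                            np.vstack([a.faces, b.faces + 4]))
    from scipy.linalg import eigh
    L = fm.mesh_laplacian(joined, require_connected=False).toarray()
    M = lumped_mass(joined).toarray()
    vals = np.sort(eigh(L, M, eigvals_only=True))
    assert (np.abs(vals) < 1e-8).sum() == 2


def test_first_mode_constant(sphere10):
    emb = fm.spectral_embedding(sphere10, k=6)
    assert emb.eigenvalues[0] <= 1e-8
    v0 = emb.eigenvectors[:, 0]
    assert np.ptp(v0) / np.abs(v0).max() < 1e-6
    assert np.all(np.diff(emb.eigenvalues) >= -1e-10)


def test_icosphere_l1_triplet_degenerate(sphere10):
    emb = fm.spectral_embedding(sphere10, k=6)
    lam = emb.eigenvalues[1:4]  # l=1 triplet, analytic l(l+1)/R^2 = 0.02
    assert (lam.max() - lam.min()) / lam.min() < 0.05
    assert lam.mean() == pytest.approx(0.02, rel=0.05)


def test_spectrum_invariant_under_rigid_motion(sphere10):
    emb1 = fm.spectral_embedding(sphere10, k=8)
    moved = fm.SurfaceMesh(sphere10.vertices @ rotation(37, (1, 2, 3)).T + 5.0,
                           sphere10.faces)
    emb2 = fm.spectral_embedding(moved, k=8)
    nz = emb1.eigenvalues > 1e-10
    rel = np.abs(emb2.eigenvalues[nz] - emb1.eigenvalues[nz]) / emb1.eigenvalues[nz]
    assert rel.max() <= 1e-6


def test_first_nontrivial_mode_has_two_nodal_domains(default_spec):
    """Courant: the Fiedler mode splits the surface into two sign domains."""
    mesh = fm.phantom_surface(default_spec, subdivisions=3)
    emb = fm.spectral_embedding(mesh, k=5)
    sign = emb.eigenvectors[:, 1] >= 0
    import scipy.sparse as sp
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    n_domains = 0
    for value in (True, False):
        keep = sign[rows] == value
        keep &= sign[cols] == value
        adj = sp.coo_matrix((np.ones(keep.sum()), (rows[keep], cols[keep])),
                            shape=(mesh.n_vertices,) * 2)
        n, labels = sp.csgraph.connected_components(adj, directed=False)
        n_domains += len(np.unique(labels[sign == value]))
    assert n_domains == 2


# ---------------------------------------------------------------------------
# CPD
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def folded_cloud():
    mesh = fm.phantom_surface(fm.PhantomSpec(fold_amplitude=2.5, seed=3),
                              subdivisions=3)
    rng = np.random.default_rng(1)
    return mesh.vertices[rng.choice(mesh.n_vertices, 500, replace=False)]


def test_cpd_identity_is_exact(folded_cloud):
    tf = fm.cpd_rigid(folded_cloud, folded_cloud)
    assert np.abs(tf.rotation - np.eye(3)).max() < 1e-6
    assert np.abs(tf.translation).max() < 1e-6
    assert abs(tf.scale - 1.0) < 1e-6


def test_cpd_recovers_known_rotation(folded_cloud):
    R = rotation(30)
    target = folded_cloud @ R.T + np.array([5.0, -3.0, 2.0])
    tf = fm.cpd_rigid(folded_cloud, target)
    cos_err = (np.trace(tf.rotation @ R.T) - 1) / 2
    angle_err = np.degrees(np.arccos(np.clip(cos_err, -1, 1)))
    assert angle_err < 0.5


def test_cpd_alignment_under_noise(folded_cloud):
    rng = np.random.default_rng(2)
    bbox = np.linalg.norm(folded_cloud.max(0) - folded_cloud.min(0))
    sigma = 0.01 * bbox
    R = rotation(20, (0, 1, 1))
    target = folded_cloud @ R.T + rng.normal(0, sigma, folded_cloud.shape)
    tf = fm.cpd_rigid(folded_cloud, target)
    rmse = np.sqrt(((tf.apply(folded_cloud) - target) ** 2).sum(1).mean())
    assert rmse < 2 * sigma * np.sqrt(3)


def test_cpd_rejects_degenerate_geometry():
    plane = np.random.default_rng(0).normal(size=(50, 2))
    coplanar = np.column_stack([plane, np.zeros(50)])
    with pytest.raises(RegistrationError):
        fm.cpd_rigid(coplanar, coplanar)
    with pytest.raises(RegistrationError):
        fm.cpd_rigid(np.zeros((3, 3)), np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# Joint spectral matching and field transfer
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def pre_mesh():
    return fm.phantom_surface(fm.PhantomSpec(fold_amplitude=2.0, seed=11),
                              subdivisions=3)


def test_self_match_is_identity(pre_mesh):
    corr = fm.joint_spectral_match(pre_mesh, pre_mesh, k=20)
    assert np.array_equal(corr.target_vertex, np.arange(pre_mesh.n_vertices))


def test_rotated_self_match_is_identity(pre_mesh):
    moved = fm.SurfaceMesh(pre_mesh.vertices @ rotation(25).T + np.array([4., 2, -1]),
                           pre_mesh.faces)
    corr = fm.joint_spectral_match(pre_mesh, moved, k=20)
    assert np.mean(corr.target_vertex == np.arange(pre_mesh.n_vertices)) > 0.99


def test_phantom_pair_correspondence_error(phantom_pair):
    corr = fm.joint_spectral_match(phantom_pair.pre_mesh, phantom_pair.post_mesh)
    pre = phantom_pair.pre_mesh
    err = np.linalg.norm(pre.vertices[corr.target_vertex]
                         - pre.vertices[phantom_pair.correspondence_truth], axis=1)
    mean_edge = pre.edge_lengths().mean()
    assert err.mean() < 3 * mean_edge
    assert (err < 5.0).mean() >= 0.90


def test_constant_field_transfer_is_exact(phantom_pair):
    corr = fm.joint_spectral_match(phantom_pair.pre_mesh, phantom_pair.post_mesh)
    out = fm.transfer_field(corr, np.full(phantom_pair.post_mesh.n_vertices, 2.5))
    assert np.all(out == 2.5)


def test_transfer_range_subset_of_source(phantom_pair):
    corr = fm.joint_spectral_match(phantom_pair.pre_mesh, phantom_pair.post_mesh)
    rng = np.random.default_rng(0)
    f = rng.uniform(-1, 1, phantom_pair.post_mesh.n_vertices)
    out = fm.transfer_field(corr, f)
    assert out.min() >= f.min() - 1e-12 and out.max() <= f.max() + 1e-12


def test_identity_correspondence_preserves_field(pre_mesh):
    corr = fm.joint_spectral_match(pre_mesh, pre_mesh, k=20)
    f = np.linspace(0, 1, pre_mesh.n_vertices)
    assert np.array_equal(fm.transfer_field(corr, f), f)


def test_transfer_length_mismatch_raises(pre_mesh):
    corr = fm.joint_spectral_match(pre_mesh, pre_mesh, k=20)
    with pytest.raises(ValueError):
        fm.transfer_field(corr, np.zeros(10))


def test_delta_field_semantics():
    assert np.all(fm.delta_field(np.zeros(5), np.full(5, 0.5)) == 0.5)
    assert np.all(fm.delta_field(np.ones(4), np.ones(4)) == 0.0)
    with pytest.raises(ValueError):
        fm.delta_field(np.zeros(3), np.zeros(4))


def test_fold_increase_gives_positive_mean_delta_si(phantom_pair):
    pre, post = phantom_pair.pre_mesh, phantom_pair.post_mesh
    corr = fm.joint_spectral_match(pre, post)
    si_pre = fm.curvature_field(pre).curvedness
    si_post = fm.curvature_field(post).curvedness
    delta = fm.delta_field(si_pre, fm.transfer_field(corr, si_post))
    w = pre.vertex_areas()
    assert np.sum(w * delta) / w.sum() > 0  # folding increased
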