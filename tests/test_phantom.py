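"""Phantom generator: volume truth, determinism, growth, landmarks."""

import numpy as np
import pytest

import fetalmorph as fm
from fetalmorph.errors import ParameterError
from fetalmorph.phantom import FoldField, _truth_only


def ellipsoid_volume(a, b, c):
    return 4.0 / 3.0 * np.pi * a * b * c


def test_unfolded_phantom_matches_analytic_ellipsoid(smooth_spec):
    """fold_amplitude=0: WM region is a plain ellipsoid with known volume."""
    vol, truth = fm.generate_phantom(smooth_spec)
    analytic = ellipsoid_volume(*smooth_spec.semi_axes)
    measured = (fm.volume_from_labels(vol, "unmyelinated_wm")
                + fm.volume_from_labels(vol, "ventricles"))
    assert abs(measured - analytic) / analytic < 0.02
    assert abs((truth.wm_volume + truth.ventricle_volume) - analytic) / analytic < 1e-3


def test_ventricle_scale_zero_gives_no_ventricle():
    spec = fm.PhantomSpec(ventricle_scale=0.0, spacing=1.2)
    vol, truth = fm.generate_phantom(spec)
    assert fm.volume_from_labels(vol, "ventricles") == 0.0
    assert truth.ventricle_volume == 0.0


def test_same_seed_is_bitwise_deterministic():
    spec = fm.PhantomSpec(spacing=1.5, seed=4)
    v1, _ = fm.generate_phantom(spec)
    v2, _ = fm.generate_phantom(spec)
    assert np.array_equal(v1.data, v2.data)


def test_labels_are_disjoint(phantom_volume):
    vol, _ = phantom_volume
    codes = set(np.unique(vol.data).tolist())
    assert codes <= {0, 1, 2, 3}


@pytest.mark.parametrize("bad", [
    dict(fold_amplitude=-1.0),
    dict(fold_amplitude=15.0),               # >= min(semi)/2
    dict(ventricle_scale=0.95),              # not strictly inside
    dict(semi_axes=(0.0, 25.0, 20.0)),
])
def test_spec_invariants_enforced(bad):
    with pytest.raises(ParameterError):
        fm.PhantomSpec(**bad)


def test_volume_truth_recovered_across_random_specs():
    """Voxel volumetry at the 0.8 mm reconstruction spacing recovers the
    quadrature truth within 2% for every structure."""
    rng = np.random.default_rng(0)
    for _ in range(3):
        spec = fm.PhantomSpec(
            semi_axes=tuple(rng.uniform(24, 32) * np.array([1.0, 0.85, 0.7])),
            fold_amplitude=float(rng.uniform(0, 3)),
            ventricle_scale=float(rng.uniform(0.2, 0.4)),
            spacing=0.8, seed=int(rng.integers(100)))
        vol, truth = fm.generate_phantom(spec)
        for structure, expected in [("unmyelinated_wm", truth.wm_volume),
                                    ("ventricles", truth.ventricle_volume),
                                    ("cerebellum", truth.cerebellum_volume)]:
            measured = fm.volume_from_labels(vol, structure)
            assert abs(measured - expected) / expected < 0.02


def test_fold_field_is_seeded_and_normalized():
    f1 = FoldField(6, 3)
    f2 = FoldField(6, 3)
    u = np.random.default_rng(0).normal(size=(100, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    assert np.array_equal(f1(u), f2(u))
    assert np.abs(f1(u)).max() <= 1.0 + 1e-6


def test_zero_growth_pair_preserves_volumes():
    spec = fm.PhantomSpec(fold_amplitude=1.5, seed=2)
    pair = fm.generate_longitudinal_pair(spec, {}, 0.0, 2.0, voxelize=False)
    for attr in ("wm_volume", "ventricle_volume", "cerebellum_volume"):
        pre, post = getattr(pair.pre_truth, attr), getattr(pair.post_truth, attr)
        assert abs(post - pre) <= 0.01 * max(pre, 1.0)


def test_ventricular_growth_rate_is_honored():
    """648 mm^3/week for 2 weeks must add 1296 mm^3 of ventricle (within 5%,
    here quadrature-exact)."""
    spec = fm.PhantomSpec(seed=1)
    pair = fm.generate_longitudinal_pair(spec, {"ventricles": 648.0}, 0.0, 2.0,
                                         voxelize=False)
    dv = pair.post_truth.ventricle_volume - pair.pre_truth.ventricle_volume
    assert abs(dv - 1296.0) / 1296.0 < 0.05
    assert abs(pair.rates["ventricles"] - 648.0) / 648.0 < 0.05


def test_fold_increase_raises_mean_curvedness(phantom_pair):
    pre_c = fm.curvature_field(phantom_pair.pre_mesh).summary(phantom_pair.pre_mesh)
    post_c = fm.curvature_field(phantom_pair.post_mesh).summary(phantom_pair.post_mesh)
    assert post_c["mean_curvedness"] > pre_c["mean_curvedness"]


def test_pair_shares_parameterization(phantom_pair):
    assert phantom_pair.pre_mesh.n_vertices == phantom_pair.post_mesh.n_vertices
    assert np.array_equal(phantom_pair.pre_mesh.faces, phantom_pair.post_mesh.faces)
    assert np.array_equal(phantom_pair.correspondence_truth,
                          np.arange(phantom_pair.pre_mesh.n_vertices))


def test_growth_violating_invariants_raises():
    spec = fm.PhantomSpec(seed=0)
    with pytest.raises(ParameterError):
        fm.generate_longitudinal_pair(spec, {"cerebellum": -2000.0}, 0.0, 2.0,
                                      voxelize=False)
    with pytest.raises(ParameterError):
        fm.generate_longitudinal_pair(spec, {}, 0.0, -1.0, voxelize=False)


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def test_landmarks_tcd_mirror_symmetric(default_spec):
    lm = fm.phantom_landmarks(default_spec)
    left, right = lm["tcd_left"], lm["tcd_right"]
    assert np.allclose(left * np.array([-1, 1, 1]), right)


def test_landmark_tcd_equals_cerebellar_width():
    spec = fm.PhantomSpec(cerebellum_semi_axes=(12.0, 7.0, 6.0))
    lm = fm.phantom_landmarks(spec)
    assert abs(np.linalg.norm(lm["tcd_left"] - lm["tcd_right"]) - 24.0) <= spec.spacing


def test_landmarks_inside_labeled_structures(phantom_volume):
    vol, truth = phantom_volume
    inv = np.linalg.inv(vol.affine)
    for name in ("tcd_left", "tcd_right", "cereb_lowest"):
        p = truth.landmarks[name]
        idx = np.round(inv[:3, :3] @ p + inv[:3, 3]).astype(int)
        neighborhood = vol.data[idx[0] - 1:idx[0] + 2, idx[1] - 1:idx[1] + 2,
                                idx[2] - 1:idx[2] + 2]
        assert (neighborhood == vol.code("cerebellum")).any()


def test_no_ventricle_means_no_vw_landmarks():
    spec = fm.PhantomSpec(ventricle_scale=0.0)
    lm = fm.phantom_landmarks(spec)
    assert "vw_medial" not in lm and "vw_lateral" not in lm


def test_truth_only_matches_voxelized_truth(default_spec, phantom_volume):
    _, truth = phantom_volume
    fast = _truth_only(default_spec)
    assert np.isclose(fast.wm_volume, truth.wm_volume)
    assert np.isclose(fast.wm_surface_area, truth.wm_surface_area)
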