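"""MKDA maps, permutation thresholds, bootstrap balancing, overlap."""

import numpy as np
import pytest

from contextrl.mkda import DEFAULT_RADIUS_MM, FociStudy, bootstrap_contrast, \
    density_map, indicator_map, make_synthetic_mask, overlap_fraction, \
    permutation_threshold, read_foci_csv, study_weights, thresholded_map, \
    write_foci_csv
from contextrl.synth import SyntheticFociSpec, simulate_foci


@pytest.fixture(scope="module")
def grid_mask():
    return make_synthetic_mask(shape=(20, 20, 20), voxel_size=2.0)


def _study(foci, n=25, cat="reward_mixed", sid="s0"):
    return FociStudy(sid, cat, np.atleast_2d(foci), n)


def test_sphere_voxel_count_matches_brute_force(grid_mask):
    mask, grid = grid_mask
    full = np.ones_like(mask)   # isolate the kernel geometry
    ind = indicator_map(_study([0.0, 0.0, 0.0]), grid, full, 10.0)
    # foci are assigned to the nearest voxel; measure from its mm center
    center_mm = grid.vox_to_mm(grid.mm_to_vox([0.0, 0.0, 0.0]))[0]
    ijk = np.indices(grid.shape).reshape(3, -1).T
    mm = grid.vox_to_mm(ijk)
    brute = (np.sum((mm - center_mm) ** 2, axis=1) <= 100.0 + 1e-9).sum()
    assert ind.sum() == brute


def test_tiny_radius_marks_only_focus_voxel(grid_mask):
    mask, grid = grid_mask
    ind = indicator_map(_study([0.0, 0.0, 0.0]), grid, mask, 0.5)
    assert ind.sum() == 1
    assert ind[tuple(grid.mm_to_vox([0.0, 0.0, 0.0])[0])]


def test_distant_foci_give_disjoint_union(grid_mask):
    mask, grid = grid_mask
    full = np.ones_like(mask)
    single = indicator_map(_study([0.0, 0.0, 0.0]), grid, full, 6.0).sum()
    both = indicator_map(_study([[-12.0, 0, 0], [12.0, 0, 0]]), grid, full, 6.0)
    assert both.sum() == 2 * single


def test_out_of_mask_focus_clipped_with_warning(grid_mask, caplog):
    mask, grid = grid_mask
    import logging

    with caplog.at_level(logging.WARNING, logger="contextrl.mkda"):
        ind = indicator_map(_study([30.0, 30.0, 30.0]), grid, mask, 4.0)
    assert ind.sum() > 0
    assert "clipped" in caplog.text


def test_density_weighted_means(grid_mask):
    mask, grid = grid_mask
    on = _study([0.0, 0.0, 0.0], sid="a")
    off = _study([14.0, 0.0, 0.0], sid="b")
    center = tuple(grid.mm_to_vox([0.0, 0.0, 0.0])[0])
    dm = density_map([on, off], grid, mask, 5.0, weights="uniform")
    assert dm.values[center] == pytest.approx(0.5)
    dm1 = density_map([on], grid, mask, 5.0)
    np.testing.assert_array_equal(
        dm1.values, indicator_map(on, grid, mask, 5.0).astype(float))
    dm31 = density_map([on, off], grid, mask, 5.0, weights=[3.0, 1.0])
    assert dm31.values[center] == pytest.approx(0.75)
    assert dm.values.min() >= 0 and dm.values.max() <= 1
    assert not dm.values[~mask].any()


def test_density_monotone_in_radius(grid_mask):
    mask, grid = grid_mask
    studies = simulate_foci(SyntheticFociSpec(
        n_studies={"reward_mixed": 4, "reward_only": 3},
        foci_per_study_mean=4), grid, mask, seed=5)
    small = density_map(studies, grid, mask, 6.0).values
    large = density_map(studies, grid, mask, 10.0).values
    assert (large >= small - 1e-12).all()


def test_weights_default_sqrt_n():
    s1 = _study([0, 0, 0], n=16, sid="a")
    s2 = _study([0, 0, 0], n=4, sid="b")
    w = study_weights([s1, s2])
    np.testing.assert_allclose(w, [4 / 6, 2 / 6])
    with pytest.raises(ValueError):
        study_weights([s1], scheme=[0.0])


def test_single_permutation_threshold_is_that_max(grid_mask):
    mask, grid = grid_mask
    studies = [_study([0.0, 0.0, 0.0], sid=f"s{i}") for i in range(3)]
    rng = np.random.default_rng(9)
    crit = permutation_threshold(studies, grid, mask, 8.0, n_perm=1, seed=9)
    assert 0 < crit <= 1.0


def test_permutation_threshold_exact_under_study_relabeling(grid_mask):
    """With uniform weights and equal foci counts the permutation
    distribution is exchangeable in the study labels."""
    mask, grid = grid_mask
    studies = [_study([[0, 0, 0], [8, 0, 0]], n=10 + i, sid=f"s{i}")
               for i in range(4)]
    a = permutation_threshold(studies, grid, mask, 8.0, weights="uniform",
                              n_perm=50, seed=3)
    b = permutation_threshold(studies[::-1], grid, mask, 8.0, weights="uniform",
                              n_perm=50, seed=3)
    assert a == b


def test_planted_cluster_survives_threshold_background_does_not(grid_mask):
    mask, grid = grid_mask
    spec = SyntheticFociSpec(n_studies={"reward_mixed": 10},
                             foci_per_study_mean=3, cluster_sd_mm=0.0,
                             cluster_center=(0.0, 0.0, 0.0))
    studies = simulate_foci(spec, grid, mask, seed=11)
    dm, sig = thresholded_map(studies, grid, mask, 8.0, n_perm=99, seed=2)
    center = tuple(grid.mm_to_vox([0.0, 0.0, 0.0])[0])
    assert sig[center]
    assert sig.sum() < 0.2 * mask.sum()


def test_zero_spread_cluster_has_unit_density(grid_mask):
    mask, grid = grid_mask
    spec = SyntheticFociSpec(
        n_studies={"reward_mixed": 5, "reward_only": 4},
        cluster_categories=("reward_mixed", "reward_only"),
        cluster_sd_mm=0.0, cluster_center=(0.0, 0.0, 0.0),
        foci_per_study_mean=3)
    studies = simulate_foci(spec, grid, mask, seed=2)
    dm = density_map(studies, grid, mask, 10.0)
    center = tuple(grid.mm_to_vox([0.0, 0.0, 0.0])[0])
    assert dm.values[center] == pytest.approx(1.0)


def test_simulate_foci_category_counts(grid_mask):
    mask, grid = grid_mask
    studies = simulate_foci(SyntheticFociSpec(), grid, mask, seed=0)
    cats = [s.category for s in studies]
    assert cats.count("reward_mixed") == 16 and cats.count("reward_only") == 9
    for s in studies:
        vox = grid.mm_to_vox(s.foci)
        assert mask[vox[:, 0], vox[:, 1], vox[:, 2]].all()


def test_bootstrap_reduces_to_single_contrast(grid_mask):
    mask, grid = grid_mask
    spec = SyntheticFociSpec(n_studies={"reward_mixed": 5, "reward_only": 4},
                             foci_per_study_mean=3, cluster_sd_mm=2.0,
                             cluster_center=(0.0, 0.0, 0.0))
    studies = simulate_foci(spec, grid, mask, seed=4)
    mixed = [s for s in studies if s.category == "reward_mixed"]
    only = [s for s in studies if s.category == "reward_only"]
    final, freq = bootstrap_contrast(mixed, only, grid, mask, 8.0,
                                     n_boot=1, subset_size=len(mixed),
                                     consistency=1.0, n_perm=49, seed=8)
    rng = np.random.default_rng(8)
    idx = rng.choice(len(mixed), size=len(mixed), replace=False)
    _, sig_m = thresholded_map([mixed[i] for i in idx], grid, mask, 8.0,
                               n_perm=49, seed=rng)
    _, sig_o = thresholded_map(only, grid, mask, 8.0, n_perm=49, seed=rng)
    np.testing.assert_array_equal(final, sig_m & ~sig_o)
    np.testing.assert_array_equal(freq, (sig_m & ~sig_o).astype(float))


def test_bootstrap_finds_cluster_planted_only_in_mixed(grid_mask):
    mask, grid = grid_mask
    hits = 0
    for rep in range(3):
        spec = SyntheticFociSpec(
            n_studies={"reward_mixed": 8, "reward_only": 6},
            foci_per_study_mean=3, cluster_sd_mm=0.0,
            cluster_center=(0.0, 0.0, 0.0))
        studies = simulate_foci(spec, grid, mask, seed=20 + rep)
        mixed = [s for s in studies if s.category == "reward_mixed"]
        only = [s for s in studies if s.category == "reward_only"]
        final, _ = bootstrap_contrast(mixed, only, grid, mask, 8.0,
                                      n_boot=8, subset_size=6,
                                      consistency=0.5, n_perm=99,
                                      seed=rep)
        center = tuple(grid.mm_to_vox([0.0, 0.0, 0.0])[0])
        hits += bool(final[center])
    assert hits >= 2


def test_bootstrap_validates_arguments(grid_mask):
    mask, grid = grid_mask
    s = [_study([0, 0, 0])]
    with pytest.raises(ValueError, match="consistency"):
        bootstrap_contrast(s, s, grid, mask, consistency=0.0)
    with pytest.raises(ValueError, match="subset_size"):
        bootstrap_contrast(s, s, grid, mask, subset_size=5)


def test_overlap_fraction_cases(grid_mask):
    mask, _ = grid_mask
    a = np.zeros((20, 20, 20), dtype=bool)
    a[5:7, 5:7, 5:7] = True   # 8 voxels... build exact 10-voxel map
    a[:] = False
    idx = np.argwhere(np.ones_like(a))[:10]
    a[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    b = np.zeros_like(a)
    b[idx[:4, 0], idx[:4, 1], idx[:4, 2]] = True
    region = np.ones_like(a)
    assert overlap_fraction(a, a, region) == 100.0
    assert overlap_fraction(a, ~a, region) == 0.0
    assert overlap_fraction(a, b, region) == pytest.approx(40.0)
    with pytest.raises(ValueError, match="grid mismatch"):
        overlap_fraction(a, b[:10], region)


def test_foci_csv_roundtrip(grid_mask, tmp_path):
    mask, grid = grid_mask
    studies = simulate_foci(SyntheticFociSpec(
        n_studies={"reward_mixed": 3, "reward_only": 2},
        foci_per_study_mean=4), grid, mask, seed=1)
    path = tmp_path / "foci.csv"
    write_foci_csv(studies, path)
    back = read_foci_csv(path)
    assert len(back) == len(studies)
    for s, t in zip(studies, back):
        np.testing.assert_allclose(s.foci, t.foci)
        assert s.n_participants == t.n_participants
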