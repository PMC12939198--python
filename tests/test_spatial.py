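"""Spatial statistics: brute-force oracle equivalence and documented edge cases."""

import numpy as np
import pandas as pd
import pytest

from trmspatial import (
    ConfigurationError,
    density_and_fraction,
    gcross,
    infiltration_profile,
    interaction_count,
    mean_nearest_distance,
    sample_qc,
)

from conftest import make_point_table


def brute_nn(ref, tgt):
    d = np.sqrt(((ref[:, None, :] - tgt[None, :, :]) ** 2).sum(-1))
    return d.min(axis=1)


def test_three_four_five_triangle():
    cells = make_point_table([[0, 0]], [[3, 4]])
    assert mean_nearest_distance(cells, "naive_trm") == pytest.approx(5.0)


def test_coincident_targets_saturate_gcross():
    pts = np.array([[10.0, 10.0], [50.0, 80.0], [200.0, 30.0]])
    cells = make_point_table(pts, pts)
    curve = gcross(cells, "naive_trm")
    assert np.all(curve.g_hat == 1.0)
    assert curve.score == pytest.approx(1.0)
    assert mean_nearest_distance(cells, "naive_trm") == 0.0


def test_targets_beyond_rmax_give_zero_curve():
    cells = make_point_table([[0, 0], [10, 0]], [[500, 500]])
    curve = gcross(cells, "naive_trm", r_max_um=30)
    assert np.all(curve.g_hat == 0.0)
    assert curve.score == 0.0
    counts, mean = interaction_count(cells, "naive_trm", radius_um=10)
    assert np.all(counts == 0) and mean == 0.0


def test_empty_target_phenotype_flags_and_scores_zero():
    cells = make_point_table([[0, 0]], [])
    curve = gcross(cells, "naive_trm")
    assert curve.empty_target and curve.score == 0.0
    assert np.isnan(mean_nearest_distance(cells, "naive_trm"))


def test_no_tumor_cells_is_an_error():
    cells = make_point_table([], [[1, 1]])
    with pytest.raises(ValueError):
        interaction_count(cells, "naive_trm")
    with pytest.raises(ValueError):
        gcross(cells, "naive_trm")


def test_interaction_radius_is_inclusive():
    cells = make_point_table([[0, 0]], [[10.0, 0.0], [0.0, 0.0]])
    counts, mean = interaction_count(cells, "naive_trm", radius_um=10)
    assert counts[0] == 2  # coincident and exactly-at-radius both count


@pytest.mark.parametrize("seed", range(5))
def test_statistics_match_all_pairs_brute_force(seed):
    rng = np.random.default_rng(seed)
    ref = rng.uniform(0, 300, size=(40, 2))
    tgt = rng.uniform(0, 300, size=(60, 2))
    cells = make_point_table(ref, tgt)
    d = brute_nn(ref, tgt)
    assert mean_nearest_distance(cells, "naive_trm") == pytest.approx(d.mean(), abs=1e-9)
    counts, _ = interaction_count(cells, "naive_trm", radius_um=10)
    dd = np.sqrt(((ref[:, None, :] - tgt[None, :, :]) ** 2).sum(-1))
    np.testing.assert_array_equal(counts, (dd <= 10).sum(axis=1))
    curve = gcross(cells, "naive_trm", r_max_um=30, n_r=61)
    expected = (d[None, :] <= curve.r_grid[:, None]).mean(axis=1)
    np.testing.assert_allclose(curve.g_hat, expected, atol=1e-12)
    assert curve.auc == pytest.approx(np.trapezoid(expected, curve.r_grid), abs=1e-9)


def test_gcross_monotone_and_rigid_motion_invariant():
    rng = np.random.default_rng(3)
    ref = rng.uniform(0, 500, size=(30, 2))
    tgt = rng.uniform(0, 500, size=(50, 2))
    curve = gcross(make_point_table(ref, tgt), "naive_trm")
    assert np.all(np.diff(curve.g_hat) >= 0)
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = gcross(make_point_table(ref @ rot.T + 50, tgt @ rot.T + 50), "naive_trm")
    assert moved.score == pytest.approx(curve.score, abs=1e-12)


def test_border_correction_restricts_reference_cells():
    ref = np.array([[5.0, 5.0], [500.0, 500.0]])  # one near edge, one interior
    tgt = np.array([[510.0, 500.0]])
    cells = make_point_table(ref, tgt)
    corrected = gcross(cells, "naive_trm", r_max_um=30, border_correction=True,
                       window=(0, 0, 1000, 1000))
    assert corrected.n_reference == 1
    assert corrected.g_hat[-1] == 1.0


# --- infiltration profile -------------------------------------------------

def _with_boundary(cells, distances):
    out = cells.copy()
    out["boundary_distance_um"] = distances
    return out


def test_band_profile_all_in_first_band():
    cells = _with_boundary(make_point_table([[0, 0]], [[1, 1], [2, 2]]), [0.0, 5.0, 5.0])
    profile, empty = infiltration_profile(cells, "naive_trm")
    assert not empty
    assert profile[0] == 1.0 and profile[1:].sum() == 0.0


def test_band_profile_matches_hand_binning_and_sums_to_one():
    rng = np.random.default_rng(1)
    d = rng.uniform(-20, 140, size=30)
    cells = _with_boundary(make_point_table([[0, 0]], np.zeros((30, 2))), [0.0, *d])
    profile, empty = infiltration_profile(cells, "naive_trm", 10.0, 100.0)
    in_zone = d[(d > 0) & (d <= 100)]
    hand = np.array([((in_zone > 10 * k) & (in_zone <= 10 * (k + 1))).sum() for k in range(10)])
    np.testing.assert_allclose(profile, hand / len(in_zone), atol=1e-12)
    assert profile.sum() == pytest.approx(1.0)
    # band edges are right-closed: 10.0 falls in band 1
    p2, _ = infiltration_profile(
        _with_boundary(make_point_table([[0, 0]], [[1, 1]]), [0.0, 10.0]), "naive_trm"
    )
    assert p2[0] == 1.0


def test_band_profile_empty_zone_and_bad_width():
    cells = _with_boundary(make_point_table([[0, 0]], [[1, 1]]), [0.0, 500.0])
    profile, empty = infiltration_profile(cells, "naive_trm")
    assert empty and profile.sum() == 0.0
    with pytest.raises(ConfigurationError):
        infiltration_profile(cells, "naive_trm", band_width_um=7.0, max_dist_um=100.0)


# --- densities, fractions, sample QC -------------------------------------

def _compartmented(cells, compartments):
    out = cells.copy()
    out["compartment"] = compartments
    out["CD8_pos"] = out["phenotype"].isin(["naive_trm", "exhausted_trm", "pd1_cd8", "cd8"])
    return out


def test_density_arithmetic():
    cells = _compartmented(
        make_point_table([[0, 0]] * 10, np.zeros((50, 2))), ["intra_tumor"] * 60
    )
    df = density_and_fraction(cells, {"intra_tumor": 0.5}, "naive_trm")
    assert df["density_per_mm2"].iloc[0] == pytest.approx(100.0)
    assert df["fraction_of_cd8"].iloc[0] == pytest.approx(1.0)


def test_fraction_of_cd8_is_one_for_cd8_aggregate_and_nan_when_absent():
    cells = _compartmented(make_point_table([[0, 0]], np.zeros((5, 2))), ["intra_tumor"] * 6)
    df = density_and_fraction(cells, {"intra_tumor": 1.0}, "cd8_any")
    assert df["fraction_of_cd8"].iloc[0] == pytest.approx(1.0)
    tumor_only = _compartmented(make_point_table([[0, 0]], []), ["intra_tumor"])
    df2 = density_and_fraction(tumor_only, {"intra_tumor": 1.0}, "naive_trm")
    assert np.isnan(df2["fraction_of_cd8"].iloc[0])


def test_zero_area_rejected():
    cells = _compartmented(make_point_table([[0, 0]], []), ["intra_tumor"])
    with pytest.raises(ConfigurationError):
        density_and_fraction(cells, {"intra_tumor": 0.0}, "naive_trm")


def test_counting_matches_generator_truth(gated_sample, small_config):
    cells = gated_sample.copy()
    cells["compartment"] = "whole"
    df = density_and_fraction(cells, {"whole": 1.0}, "naive_trm")
    assert df["count"].iloc[0] == (cells["true_label"] == "naive_trm").sum()


@pytest.mark.parametrize("n,expected", [(1499, False), (1500, True)])
def test_sample_qc_inclusive_lower_bound(n, expected):
    cells = make_point_table(np.zeros((n, 2)), [])
    cells["compartment"] = "intra_tumor"
    cells["CD8_pos"] = False
    assert sample_qc(cells, min_combined=1500) is expected


def test_sample_qc_empty_sample_fails():
    cells = make_point_table([], [])
    assert sample_qc(cells) is False


def test_sample_qc_counts_only_tumor_tissue():
    cells = make_point_table(np.zeros((10, 2)), np.zeros((10, 2)))
    cells["CD8_pos"] = cells["phenotype"] != "tumor"
    cells["compartment"] = ["intra_tumor"] * 10 + ["stroma"] * 10
    assert sample_qc(cells, min_combined=11) is False
    assert sample_qc(cells, min_combined=10) is True
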