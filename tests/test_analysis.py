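"""Response analysis: significance detection, reliability classes,
fractions, overlap, Gamma fits, similarity and variability statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import olfstoch as o
from olfstoch.analysis import (
    RELIABLE,
    SILENT,
    UNRELIABLE,
    overlap_score,
    shuffle_expectation,
)
from olfstoch.tensor import ResponseTensor

from conftest import make_mask


def _single_trial_tensor(baseline, response_value):
    """One cell, one odor, one trial: given baseline frames, then a
    response window at the given constant value."""
    frames = np.concatenate([baseline, np.full(5, response_value)])
    return ResponseTensor(
        values=frames[None, None, None, :],
        frame_duration=0.5,
        odor_onset_frame=len(baseline),
    )


@pytest.mark.parametrize(
    "resp, expect", [(2.34, True), (2.32, False)]
)
def test_detection_threshold_boundary(resp, expect):
    """Baseline with mean 0 and sd 1: the 2.33-SD rule fires just above
    2.33 and not just below."""
    rng = np.random.default_rng(0)
    base = rng.standard_normal(2000)
    base = (base - base.mean()) / base.std(ddof=1)  # exact mean 0, sd 1
    tensor = _single_trial_tensor(base, resp)
    # classification needs >=2 trials; duplicate the trial
    v = np.repeat(tensor.values, 2, axis=2)
    t2 = ResponseTensor(v, 0.5, tensor.odor_onset_frame)
    mask = o.detect_significant(t2)
    assert mask.responded[0, 0, 0] == expect


def test_zero_variance_baseline_flagged():
    values = np.zeros((2, 1, 2, 10))
    values[1, :, :, :5] = np.random.default_rng(1).normal(0, 0.1, (1, 2, 5))
    values[:, :, :, 5:] = 5.0
    tensor = ResponseTensor(values, 0.5, 5)
    mask = o.detect_significant(tensor)
    assert 0 in mask.excluded_cells
    assert not mask.responded[0].any()
    assert mask.responded[1].all()


def test_overlapping_windows_rejected(fly_tensor):
    with pytest.raises(ValueError):
        o.detect_significant(
            fly_tensor, baseline_window=np.arange(0, 10),
            response_window=np.arange(5, 15),
        )


@pytest.mark.parametrize(
    "n_resp, label",
    [(4, RELIABLE), (3, UNRELIABLE), (1, UNRELIABLE), (0, SILENT)],
)
def test_classification_rule_boundaries(n_resp, label):
    """Reliable means more than half of 6 trials; exactly half is
    unreliable; zero responses is silent."""
    responded = np.zeros((1, 1, 6), dtype=bool)
    responded[0, 0, :n_resp] = True
    table = o.classify_cells(make_mask(responded))
    assert table.label.iloc[0] == label
    assert table.p_response.iloc[0] == n_resp / 6


def test_expected_response_is_mean_indicator_times_size():
    responded = np.zeros((1, 1, 4), dtype=bool)
    responded[0, 0, :2] = True
    sizes = np.array([[[2.0, 4.0, 9.0, 9.0]]])  # non-responding sizes ignored
    table = o.classify_cells(make_mask(responded, sizes))
    assert table.expected_response.iloc[0] == pytest.approx((2 + 4) / 4)


def test_toy_schematic_population_fractions(toy_schematic_mask):
    """Five-cell schematic: 1 unreliable cell per trial (20%), 3 of 5
    unreliable across trials (60%), 1.5 reliable cells per trial."""
    table = o.classify_cells(toy_schematic_mask)
    fr = o.population_fractions(table, toy_schematic_mask)
    per_trial = fr["per_trial"]
    assert per_trial.frac_unreliable.mean() == pytest.approx(0.20)
    assert fr["per_odor"].frac_unreliable.iloc[0] == pytest.approx(0.60)
    assert per_trial.frac_reliable.mean() * 5 == pytest.approx(1.5)
    assert fr["per_odor"].frac_reliable.iloc[0] == pytest.approx(0.40)


def test_all_silent_tensor_zero_fractions():
    mask = make_mask(np.zeros((4, 2, 6), dtype=bool))
    table = o.classify_cells(mask)
    fr = o.population_fractions(table, mask)
    assert (fr["per_trial"][["frac_reliable", "frac_unreliable"]] == 0).all().all()
    assert (fr["per_odor"][["frac_reliable", "frac_unreliable"]] == 0).all().all()


def test_partition_and_recurrence_invariants(fly_mask_table):
    """Classes partition cells per odor; reliable recur (per-odor close to
    per-trial) while unreliable accumulate (per-odor above per-trial)."""
    mask, table = fly_mask_table
    counts = table.groupby("odor").label.value_counts().unstack(fill_value=0)
    assert (counts.sum(axis=1) == mask.n_cells).all()
    fr = o.population_fractions(table, mask)
    rel_pt = fr["per_trial"].frac_reliable.mean()
    un_pt = fr["per_trial"].frac_unreliable.mean()
    rel_po = fr["per_odor"].frac_reliable.mean()
    un_po = fr["per_odor"].frac_unreliable.mean()
    assert un_po >= un_pt
    assert rel_pt <= rel_po <= 2 * rel_pt


@pytest.mark.parametrize(
    "ka, kb, expected",
    [(4, 2, 8 / 36), (1, 3, 1 / 12), (0, 5, 0.0)],
)
def test_overlap_worked_examples(ka, kb, expected):
    assert overlap_score(ka, kb, 6) == pytest.approx(expected)


def test_pairwise_overlap_matrix_properties(fly_mask_table):
    _, table = fly_mask_table
    res = o.pairwise_overlap(table)
    per_cell = res["per_cell"]
    p = table.pivot(index="cell", columns="odor", values="p_response").to_numpy()
    assert np.allclose(per_cell, per_cell.transpose(0, 2, 1))
    assert per_cell.min() >= 0 and per_cell.max() <= 1
    # overlap is bounded by the smaller response probability
    bound = np.minimum(p[:, :, None], p[:, None, :])
    assert np.all(per_cell <= bound + 1e-12)
    # self-overlap is the squared probability
    assert np.allclose(np.diagonal(per_cell, axis1=1, axis2=2), p**2)


@given(
    pa=st.floats(0, 1), pb=st.floats(0, 1)
)
@settings(max_examples=50, deadline=None)
def test_overlap_bound_equality_condition(pa, pb):
    ov = pa * pb
    assert ov <= min(pa, pb) + 1e-12
    if max(pa, pb) == 1.0:
        assert ov == pytest.approx(min(pa, pb))


def test_fit_gamma_recovery_and_consistency():
    rng = np.random.default_rng(10)
    errs = []
    for n in (10**3, 10**4, 10**5):
        fit = o.fit_gamma(rng.gamma(0.64, 0.42, n))
        errs.append(abs(fit.shape / 0.64 - 1))
    assert errs[-1] < 0.05
    assert errs[-1] < errs[0] + 0.01  # error shrinks with n


def test_fit_gamma_exponential_is_shape_one():
    rng = np.random.default_rng(11)
    fit = o.fit_gamma(rng.exponential(1.0, 10**5))
    assert fit.shape == pytest.approx(1.0, rel=0.05)


def test_fit_gamma_rejects_bad_input():
    with pytest.raises(ValueError):
        o.fit_gamma(np.ones(100))
    with pytest.raises(ValueError):
        o.fit_gamma(np.array([1.0, 2.0, -1.0] * 10))
    with pytest.raises(ValueError):
        o.fit_gamma(np.arange(1, 6, dtype=float))


def test_cumulative_frequency_curve():
    df = o.cumulative_frequency([3, 1, 1, 2])
    assert list(df.value) == [1, 2, 3]
    assert list(df.cumulative_frequency) == [0.5, 0.75, 1.0]


def test_odor_similarity_identical_and_independent():
    rng = np.random.default_rng(12)
    sizes = rng.gamma(1, 1, size=(50, 2, 6))
    responded = np.ones((50, 2, 6), dtype=bool)
    sizes[:, 1] = sizes[:, 0]  # odor 1 duplicates odor 0
    mask = make_mask(responded, sizes)
    sim = o.odor_similarity(mask)
    assert sim.avg_vector_corr.iloc[0] == pytest.approx(1.0)
    assert sim.label.iloc[0] == "similar"

    sizes_ind = rng.gamma(1, 1, size=(500, 2, 6))
    sim_ind = o.odor_similarity(make_mask(np.ones_like(sizes_ind, bool), sizes_ind))
    assert abs(sim_ind.avg_vector_corr.iloc[0]) < 0.15


def test_trial_pair_mean_below_average_vector_corr():
    """Averaging trials before correlating removes trial noise, so the
    averaged-vector correlation exceeds the mean of trial-pair
    correlations on correlated pairs."""
    cfg = o.fly_config(n_cells=400)
    pair = o.generate_correlated_pair(cfg, 0.6, seed=13)
    sim = o.odor_similarity(o.detect_significant(pair))
    assert sim.trial_pair_corr.iloc[0] <= sim.avg_vector_corr.iloc[0]


def test_class_restricted_similarity_reduces_to_unrestricted():
    """When every cell is responsive the responsive-class restriction keeps
    all cells, so the measure equals the trial-averaged-vector correlation."""
    rng = np.random.default_rng(21)
    responded = np.ones((60, 3, 6), dtype=bool)
    sizes = rng.gamma(1, 1, size=(60, 3, 6))
    mask = make_mask(responded, sizes)
    table = o.classify_cells(mask)
    full = o.odor_similarity(mask)
    restricted = o.class_restricted_similarity(mask, table, "responsive")
    for _, row in full.iterrows():
        sub = restricted[
            (restricted.odor_a == row.odor_i) & (restricted.odor_b == row.odor_j)
        ]
        assert sub["correlation"].iloc[0] == pytest.approx(row.avg_vector_corr)


def test_reliable_restriction_preserves_similarity_better():
    cfg = o.fly_config(n_cells=1000)
    pair = o.generate_correlated_pair(cfg, 0.6, seed=14)
    mask = o.detect_significant(pair)
    table = o.classify_cells(mask)
    rel = o.class_restricted_similarity(mask, table, RELIABLE)
    unrel = o.class_restricted_similarity(mask, table, UNRELIABLE)
    assert rel["correlation"].mean() > unrel["correlation"].mean()

    dis = o.generate_correlated_pair(cfg, 0.0, seed=14)
    mask_d = o.detect_significant(dis)
    table_d = o.classify_cells(mask_d)
    rel_d = o.class_restricted_similarity(mask_d, table_d, RELIABLE)
    unrel_d = o.class_restricted_similarity(mask_d, table_d, UNRELIABLE)
    assert abs(rel_d["correlation"].mean()) < 0.25
    assert abs(unrel_d["correlation"].mean()) < 0.25


def test_percentile_similarity_identical_and_disjoint():
    rng = np.random.default_rng(15)
    sizes = rng.gamma(1, 1, size=(40, 2, 6)) + 0.1
    sizes[:, 1] = sizes[:, 0]
    mask = make_mask(np.ones((40, 2, 6), bool), sizes)
    table = o.classify_cells(mask)
    ps = o.percentile_similarity(mask, table)
    assert np.allclose(ps.cosine, 1.0)

    # disjoint responsive sets: first half responds only to odor 0
    responded = np.zeros((40, 2, 6), bool)
    responded[:20, 0] = True
    responded[20:, 1] = True
    mask_d = make_mask(responded, np.where(responded, 1.0, 0.0))
    table_d = o.classify_cells(mask_d)
    ps_d = o.percentile_similarity(mask_d, table_d)
    assert np.allclose(ps_d.cosine, 0.0)


def test_percentile_similarity_top_band_most_similar():
    cfg = o.fly_config(n_cells=1000)
    pair = o.generate_correlated_pair(cfg, 0.6, seed=16)
    mask = o.detect_significant(pair)
    table = o.classify_cells(mask)
    bands = o.percentile_similarity(mask, table, bands=True)
    top = bands[bands.band_lo == 0].cosine.iloc[0]
    bottom = bands[bands.band_lo == 75].cosine.iloc[0]
    assert top >= bottom


def test_selectivity_bias_examples():
    # perfectly shared membership over the whole population
    responded = np.zeros((10, 2, 6), dtype=bool)
    responded[:, :, 0] = True  # every cell level 1 for both odors
    table = o.classify_cells(make_mask(responded))
    res = o.selectivity_bias(table, (0, 1), 1)
    assert res["ratio"] == pytest.approx(1.0)

    # zero observed co-count
    responded = np.zeros((10, 2, 6), dtype=bool)
    responded[:4, 0, 0] = True
    responded[4:9, 1, 0] = True
    table = o.classify_cells(make_mask(responded))
    res = o.selectivity_bias(table, (0, 1), 1)
    assert res["observed"] == 0 and res["ratio"] == 0.0

    with pytest.raises(ValueError):
        o.selectivity_bias(table, (0, 1), 5)


def test_selectivity_bias_small_case_and_shuffle_oracle():
    """N=10 cells, 4 at level 1 for A, 5 for B, all 4 shared: the bias is
    4/(4*5/10) = 2; the analytic expectation matches a shuffle."""
    responded = np.zeros((10, 2, 6), dtype=bool)
    responded[:4, 0, 0] = True
    responded[:4, 1, 0] = True
    responded[4, 1, 1] = True
    table = o.classify_cells(make_mask(responded))
    res = o.selectivity_bias(table, (0, 1), 1)
    assert res["ratio"] == pytest.approx(2.0)
    mc = shuffle_expectation(10, 4, 5, n_shuffles=10_000, seed=0)
    # hypergeometric mean 2.0, sd ~0.8 -> SE of the MC mean ~0.008
    assert mc == pytest.approx(res["expected"], abs=3 * 0.01)


def test_variability_stats_hand_computed():
    responded = np.zeros((2, 1, 6), dtype=bool)
    responded[0, 0, :2] = True   # responses {1, 3}
    responded[1, 0, :3] = True   # constant responses
    sizes = np.zeros((2, 1, 6))
    sizes[0, 0, :2] = [1.0, 3.0]
    sizes[1, 0, :3] = 2.0
    df = o.variability_stats(make_mask(responded, sizes))
    row0 = df[df.cell == 0].iloc[0]
    assert row0.cv == pytest.approx(np.sqrt(2) / 2)
    assert row0.fano == pytest.approx(1.0)
    row1 = df[df.cell == 1].iloc[0]
    assert row1.cv == 0.0 and row1.fano == 0.0


def test_variability_poisson_fano_near_one():
    rng = np.random.default_rng(17)
    counts = rng.poisson(5.0, size=(200, 1, 20)).astype(float)
    mask = make_mask(np.ones_like(counts, bool), counts)
    df = o.variability_stats(mask)
    assert df.fano.mean() == pytest.approx(1.0, abs=0.1)


def test_split_half_frequency():
    responded = np.zeros((3, 1, 6), dtype=bool)
    responded[0, 0, 0] = True          # once early, never again -> 0
    responded[1, 0, [1, 3, 4, 5]] = True  # once early, always late -> 1
    responded[2, 0, :3] = True         # three early responses: excluded
    res = o.split_half_frequency(make_mask(responded))
    df = res["table"].set_index("cell")
    assert df.loc[0].second_half_frequency == 0.0
    assert df.loc[1].second_half_frequency == 1.0
    assert 2 not in df.index
    assert res["null_frequency"] == pytest.approx(1 / 3)


def test_split_half_homogeneous_population_matches_null():
    cfg = o.fly_config(n_cells=4000, n_odors=1, fixed_reliability=1 / 3,
                       coupling="none", response_gamma=(5.0, 0.2))
    tensor = o.generate_responses(cfg, seed=18)
    mask = o.detect_significant(tensor)
    res = o.split_half_frequency(mask)
    assert res["table"].second_half_frequency.mean() == pytest.approx(1 / 3, abs=0.02)


def test_split_half_fly_preset_not_concentrated_at_null():
    """A reliability continuum produces a broad mixture of second-half
    frequencies, unlike a homogeneous population."""
    cfg = o.fly_config(n_cells=4000, n_odors=1)
    tensor = o.generate_responses(cfg, seed=19)
    res = o.split_half_frequency(o.detect_significant(tensor))
    freqs = res["table"].second_half_frequency
    assert freqs.std() > 0.15
    assert (freqs == 0).mean() > 0.2  # many one-off responders stay silent


def test_threshold_sensitivity_monotone(fly_tensor):
    df = o.threshold_sensitivity(fly_tensor, [1.64, 2.33, 3.1])
    counts = df.n_responsive_cell_trials.to_numpy()
    assert counts[0] > counts[1] > counts[2]
    base = o.detect_significant(fly_tensor)
    assert df.n_responsive_cell_trials.iloc[1] == base.responded.sum()
    huge = o.threshold_sensitivity(fly_tensor, [1e4])
    assert huge.n_responsive_cell_trials.iloc[0] == 0
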