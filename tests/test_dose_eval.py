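"""DVH metrics, normalization, homogeneity, Wilcoxon test and cohort tables."""

import datetime as dt
import itertools

import numpy as np
import pytest
from scipy import stats

from rtautoplan.dose_eval import (
    CohortComparison,
    TimingLog,
    compare_cohorts,
    compute_dvh,
    dose_at_volume,
    homogeneity_index,
    normalize_prescription,
    resample_dose,
    volume_at_dose,
    wilcoxon_signed_rank,
)
from rtautoplan.templates import ClinicalGoal, MetricSpec
from rtautoplan.volumetric import DoseGrid, SpatialGrid, StructureMask


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def dose_at_volume_oracle(samples, count):
    """Greatest d with at least `count` samples >= d, by direct enumeration."""
    for d in sorted(samples, reverse=True):
        if sum(1 for s in samples if s >= d - 1e-12) >= count - 1e-9:
            return d
    return min(samples)


def wilcoxon_oracle(diffs):
    """Two-sided exact p by brute-force enumeration over all sign vectors."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    center = ranks.sum() / 2.0
    dev = abs(w_obs - center)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - center) >= dev - 1e-9:
            count += 1
    return w_obs, count / 2**n


def small_case(doses, spacing=(1, 1, 1)):
    """One-voxel-per-sample dose/mask pair on a tiny grid."""
    n = len(doses)
    grid = SpatialGrid(origin=(0, 0, 0), spacing=spacing, dims=(n, 1, 1))
    mask = StructureMask(grid, np.ones(grid.shape_zyx, bool), "s")
    dose = DoseGrid(grid, np.asarray(doses, float).reshape(grid.shape_zyx))
    return dose, mask


# ---------------------------------------------------------------------------
# DVH and metrics
# ---------------------------------------------------------------------------

def test_dvh_uniform_dose_step():
    dose, mask = small_case([30.0] * 50)
    dvh = compute_dvh(dose, mask)
    assert dvh.fraction_at_least(30.0) == 1.0
    assert dvh.fraction_at_least(30.01) == 0.0
    assert dvh.fraction_at_least(0.0) == 1.0


def test_dvh_counting_fraction():
    dose, mask = small_case(list(range(1, 101)))
    dvh = compute_dvh(dose, mask)
    assert dvh.fraction_at_least(50.5) == pytest.approx(0.50)


def test_dvh_empty_mask_names_structure():
    grid = SpatialGrid(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(4, 4, 4))
    mask = StructureMask(grid, np.zeros(grid.shape_zyx, bool), "Cochlea")
    dose = DoseGrid(grid, np.zeros(grid.shape_zyx))
    with pytest.raises(ValueError, match="Cochlea"):
        compute_dvh(dose, mask)


def test_dvh_additive_over_disjoint_union():
    grid = SpatialGrid(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(10, 1, 1))
    vals = np.arange(10.0).reshape(grid.shape_zyx)
    dose = DoseGrid(grid, vals)
    occ_a = np.zeros(grid.shape_zyx, bool)
    occ_a[:, :, :5] = True
    occ_b = ~occ_a
    a = compute_dvh(dose, StructureMask(grid, occ_a, "a"))
    b = compute_dvh(dose, StructureMask(grid, occ_b, "b"))
    u = compute_dvh(dose, StructureMask(grid, occ_a | occ_b, "u"))
    np.testing.assert_array_equal(
        np.sort(np.concatenate([a.samples, b.samples])), u.samples
    )


def test_d95_pure_order_statistic():
    dose, mask = small_case(list(range(1, 101)))
    dvh = compute_dvh(dose, mask)
    assert dose_at_volume(dvh, MetricSpec("D_percent", 95)) == pytest.approx(6.0)
    assert dose_at_volume(dvh, MetricSpec("D_percent", 2)) == pytest.approx(99.0)
    assert dose_at_volume(dvh, MetricSpec("D_percent", 100)) == pytest.approx(1.0)


def test_dose_at_volume_uniform():
    dose, mask = small_case([30.0] * 20)
    dvh = compute_dvh(dose, mask)
    for pct in (2, 50, 98):
        assert dose_at_volume(dvh, MetricSpec("D_percent", pct)) == 30.0


def test_dcc_total_volume_is_minimum():
    dose, mask = small_case(list(range(1, 101)))
    dvh = compute_dvh(dose, mask)
    assert dose_at_volume(dvh, MetricSpec("D_cc", dvh.volume_cc)) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="exceeds"):
        dose_at_volume(dvh, MetricSpec("D_cc", dvh.volume_cc * 2))


def test_volume_at_dose_counting():
    dose, mask = small_case(list(range(1, 101)))
    dvh = compute_dvh(dose, mask)
    assert volume_at_dose(dvh, 0.0) == 100.0
    assert volume_at_dose(dvh, 25.0) == pytest.approx(76.0)


def test_metrics_match_enumeration_oracle_random():
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(5, 60))
        doses = rng.uniform(0, 40, n).round(3).tolist()
        dose, mask = small_case(doses)
        dvh = compute_dvh(dose, mask)
        for pct in (2, 5, 50, 95, 98, 100):
            count = n * pct / 100.0
            expected = dose_at_volume_oracle(doses, count)
            assert dose_at_volume(dvh, MetricSpec("D_percent", pct)) == pytest.approx(expected)
        for d in (0.0, 10.0, 25.0):
            expected = 100.0 * sum(1 for s in doses if s >= d) / n
            assert volume_at_dose(dvh, d) == pytest.approx(expected)


def test_near_inverse_property():
    rng = np.random.default_rng(12)
    doses = rng.uniform(0, 40, 73).tolist()
    dose, mask = small_case(doses)
    dvh = compute_dvh(dose, mask)
    for pct in np.linspace(0.5, 100, 40):
        d = dose_at_volume(dvh, MetricSpec("D_percent", pct))
        assert volume_at_dose(dvh, d) >= pct - 1e-9


# ---------------------------------------------------------------------------
# homogeneity index and normalization
# ---------------------------------------------------------------------------

def test_hi_uniform_zero():
    dose, mask = small_case([30.0] * 40)
    assert homogeneity_index(compute_dvh(dose, mask), 30.0) == 0.0


def test_hi_order_statistics_formula():
    dose, mask = small_case(list(range(1, 101)))
    dvh = compute_dvh(dose, mask)
    # D5% = 96, D95% = 6 -> 100 * (96 - 6) / 50 = 180
    assert homogeneity_index(dvh, 50.0) == pytest.approx(180.0)


def test_hi_scales_linearly_with_dose():
    rng = np.random.default_rng(13)
    doses = rng.uniform(20, 40, 64)
    d1, m = small_case(doses.tolist())
    d2, _ = small_case((3.0 * doses).tolist())
    hi1 = homogeneity_index(compute_dvh(d1, m), 30.0)
    hi2 = homogeneity_index(compute_dvh(d2, m), 30.0)
    assert hi2 == pytest.approx(3.0 * hi1)


def test_normalize_scale_from_order_statistics():
    dose, mask = small_case(list(range(1, 101)))
    scaled, scale = normalize_prescription(dose, mask, 30.0)
    assert scale == pytest.approx(5.0)  # D95 = 6 -> 30/6
    dvh = compute_dvh(scaled, mask)
    assert dose_at_volume(dvh, MetricSpec("D_percent", 95)) == pytest.approx(30.0)


def test_normalize_identity_when_already_at_rx():
    dose, mask = small_case([30.0] * 30)
    _, scale = normalize_prescription(dose, mask, 30.0)
    assert scale == pytest.approx(1.0)


def test_normalize_idempotent():
    rng = np.random.default_rng(14)
    dose, mask = small_case(rng.uniform(10, 40, 200).tolist())
    once, _ = normalize_prescription(dose, mask, 30.0)
    _, scale2 = normalize_prescription(once, mask, 30.0)
    assert scale2 == pytest.approx(1.0, abs=1e-9)


def test_normalize_guarantees_target_coverage():
    rng = np.random.default_rng(15)
    for _ in range(10):
        doses = rng.uniform(5, 45, int(rng.integers(50, 500))).tolist()
        dose, mask = small_case(doses)
        scaled, _ = normalize_prescription(dose, mask, 30.0)
        dvh = compute_dvh(scaled, mask)
        assert volume_at_dose(dvh, 30.0) >= 95.0


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def test_resample_linear_field_exact():
    src = SpatialGrid(origin=(0, 0, 0), spacing=(2, 2, 2), dims=(10, 10, 10))
    x = src.axis_coords(0)[None, None, :]
    vals = np.broadcast_to(0.5 * x + 3.0, src.shape_zyx).copy()
    dose = DoseGrid(src, vals)
    dst = SpatialGrid(origin=(2, 2, 2), spacing=(1, 1, 1), dims=(12, 12, 12))
    out = resample_dose(dose, dst)
    xd = dst.axis_coords(0)[None, None, :]
    expected = np.broadcast_to(0.5 * xd + 3.0, dst.shape_zyx)
    np.testing.assert_allclose(out.values, expected, atol=1e-9)


def test_resample_same_grid_is_noop():
    dose, mask = small_case([1.0, 2.0, 3.0])
    assert resample_dose(dose, mask.grid) is dose


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def test_wilcoxon_all_zero_differences():
    res = wilcoxon_signed_rank([(1.0, 1.0)] * 8)
    assert res.p == 1.0 and res.w == 0.0
    assert res.note


def test_wilcoxon_five_positive_no_ties():
    pairs = [(float(i + 2), 1.0) for i in range(5)]
    res = wilcoxon_signed_rank(pairs)
    assert res.method == "exact"
    assert res.p == pytest.approx(0.0625)
    assert res.w == 15.0


def test_wilcoxon_antisymmetry():
    rng = np.random.default_rng(16)
    a = rng.normal(0, 1, 9)
    b = rng.normal(0.4, 1, 9)
    pairs = list(zip(a, b))
    fwd = wilcoxon_signed_rank(pairs)
    rev = wilcoxon_signed_rank([(y, x) for x, y in pairs])
    n = fwd.n_effective
    assert rev.w == pytest.approx(n * (n + 1) / 2 - fwd.w)
    assert rev.p == pytest.approx(fwd.p)


def test_wilcoxon_matches_enumeration_oracle():
    rng = np.random.default_rng(17)
    for n in (4, 6, 8, 10, 12):
        for _ in range(5):
            # rounded data so ties and zeros occur
            a = rng.integers(0, 6, n).astype(float)
            b = rng.integers(0, 6, n).astype(float)
            diffs = a - b
            if np.all(diffs == 0):
                continue
            w_oracle, p_oracle = wilcoxon_oracle(diffs)
            res = wilcoxon_signed_rank(list(zip(a, b)))
            assert res.w == pytest.approx(w_oracle)
            assert res.p == pytest.approx(p_oracle)


def test_wilcoxon_matches_scipy_exact_without_ties():
    rng = np.random.default_rng(18)
    for n in (8, 15, 20):
        a = rng.normal(0, 1, n)
        b = rng.normal(0.3, 1, n)
        res = wilcoxon_signed_rank(list(zip(a, b)))
        ref = stats.wilcoxon(a, b, alternative="two-sided", method="exact")
        assert res.p == pytest.approx(ref.pvalue)


def test_wilcoxon_normal_approximation_large_n():
    rng = np.random.default_rng(19)
    a = rng.normal(0, 1, 40)
    b = rng.normal(0.5, 1, 40)
    res = wilcoxon_signed_rank(list(zip(a, b)))
    assert res.method == "normal"
    ref = stats.wilcoxon(a, b, alternative="two-sided", method="approx", correction=True)
    assert res.p == pytest.approx(ref.pvalue, rel=1e-6)


def test_wilcoxon_pratt_zero_handling():
    pairs = [(1.0, 1.0), (3.0, 1.0), (4.0, 1.0), (0.5, 1.0)]
    wilcox = wilcoxon_signed_rank(pairs, zero_method="wilcox")
    pratt = wilcoxon_signed_rank(pairs, zero_method="pratt")
    # pratt ranks the zero too, shifting the nonzero ranks upward
    assert pratt.w > wilcox.w


def test_wilcoxon_input_bounds():
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([])
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([(1.0, 2.0)] * 51)


# ---------------------------------------------------------------------------
# cohort comparison
# ---------------------------------------------------------------------------

def test_compare_identical_cohorts():
    comp = compare_cohorts("D2%", [34.0, 33.5, 34.2], [34.0, 33.5, 34.2])
    assert comp.mean_difference == 0.0
    assert comp.p_value == 1.0
    assert not comp.significant


def test_compare_constant_shift_significant():
    a = [30.0 + i * 0.1 for i in range(10)]
    b = [v - 1.0 for v in a]
    comp = compare_cohorts("D2%", a, b)
    assert comp.p_value == pytest.approx(2.0 / 1024.0)
    assert comp.significant
    assert comp.mean_difference == pytest.approx(1.0)


def test_compare_length_mismatch():
    with pytest.raises(ValueError, match="equal length"):
        compare_cohorts("x", [1.0, 2.0], [1.0])


def test_summary_row_layout():
    comp = compare_cohorts("HI", [4.4, 4.5, 4.3], [4.2, 4.3, 4.2])
    row = comp.summary_row()
    assert set(row) == {
        "metric", "a_mean", "a_sd", "b_mean", "b_sd", "difference", "p", "significant",
    }
    assert row["metric"] == "HI"


# ---------------------------------------------------------------------------
# timing
# ---------------------------------------------------------------------------

def test_timing_log_durations():
    t0 = dt.datetime(2024, 1, 1, 9, 0, 0)
    log = TimingLog(
        application_start=t0,
        plan_trigger=t0 + dt.timedelta(seconds=117),
        planning_start=t0 + dt.timedelta(seconds=120),
        planning_end=t0 + dt.timedelta(seconds=120 + 842),
    )
    assert log.tte_seconds == 117
    assert log.tpt_seconds == 842
    # trigger-to-end decomposes into the wait plus the planning time
    total = (log.planning_end - log.plan_trigger).total_seconds()
    assert total == log.tpt_seconds + (log.planning_start - log.plan_trigger).total_seconds()


def test_timing_log_rejects_non_monotone():
    t0 = dt.datetime(2024, 1, 1, 9, 0, 0)
    with pytest.raises(ValueError):
        TimingLog(
            application_start=t0,
            plan_trigger=t0 - dt.timedelta(seconds=1),
            planning_start=t0,
            planning_end=t0,
        )
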