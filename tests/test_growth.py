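"""Doubling time, inhibition profile, ATRA score, groups and tertiles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atrasens import (
    GrowthAssay,
    GrowthSimParams,
    NonGrowthError,
    NormalizationError,
    ValidationError,
    assign_sensitivity_groups,
    assign_tertiles,
    atra_score,
    estimate_doubling_time,
    growth_inhibition_profile,
    hill_inhibition,
    simulate_growth_assay,
)


def _assay(rows, line="X"):
    return GrowthAssay(line, pd.DataFrame(
        rows, columns=["concentration_uM", "day", "replicate", "od"]))


class TestDoublingTime:
    def test_exact_exponential(self):
        assay = _assay([(0, 0, 0, 0.1), (0, 1, 0, 0.2), (0, 2, 0, 0.4),
                        (0.1, 0, 0, 0.1), (0.1, 2, 0, 0.1)])
        gp = estimate_doubling_time(assay)
        assert gp.td_days == pytest.approx(1.0, abs=1e-12)
        assert gp.fit_r2 == pytest.approx(1.0, abs=1e-12)
        assert gp.n_points == 3

    def test_constant_od_is_non_growth(self):
        assay = _assay([(0, 0, 0, 0.3), (0, 3, 0, 0.3), (0, 6, 0, 0.3),
                        (1.0, 0, 0, 0.3), (1.0, 3, 0, 0.3)])
        with pytest.raises(NonGrowthError):
            estimate_doubling_time(assay)

    def test_noisy_recovery_median_error_under_5pct(self):
        errors = []
        for seed in range(100):
            assay = simulate_growth_assay(
                GrowthSimParams(td_days=1.5, cv=0.05, seed=seed),
                concentrations=(0.0, 1.0), days=(0.0, 3.0, 6.0, 9.0),
                n_replicates=3)
            td = estimate_doubling_time(assay).td_days
            errors.append(abs(td - 1.5) / 1.5)
        assert np.median(errors) < 0.05


class TestInhibitionProfile:
    def test_identical_to_vehicle_gives_zero(self):
        assay = simulate_growth_assay(GrowthSimParams(imax=0.0, cv=0.0))
        prof = growth_inhibition_profile(assay)
        assert all(v == 0.0 for v in prof.values())

    def test_flat_under_drug_gives_one(self):
        assay = _assay([(0, 3, 0, 0.2), (0, 6, 0, 0.8),
                        (1.0, 3, 0, 0.2), (1.0, 6, 0, 0.2),
                        (10.0, 3, 0, 0.2), (10.0, 6, 0, 0.2)])
        prof = growth_inhibition_profile(assay)
        assert prof[1.0] == 1.0 and prof[10.0] == 1.0

    def test_fractional_rate_recovered_exactly(self):
        # drug multiplies the growth rate by 0.4 -> inhibition 0.6
        td = 1.5
        rows = []
        for c, factor in ((0.0, 1.0), (1.0, 0.4)):
            for day in (3.0, 6.0):
                rows.append((c, day, 0, 0.1 * 2 ** (day * factor / td)))
        prof = growth_inhibition_profile(_assay(rows))
        assert prof[1.0] == pytest.approx(0.6, abs=1e-12)

    def test_non_growing_vehicle_is_normalization_error(self):
        assay = _assay([(0, 3, 0, 0.4), (0, 6, 0, 0.4),
                        (1.0, 3, 0, 0.4), (1.0, 6, 0, 0.2)])
        with pytest.raises(NormalizationError):
            growth_inhibition_profile(assay)


class TestAtraScore:
    def test_extremes(self):
        zero = simulate_growth_assay(GrowthSimParams(imax=0.0, cv=0.0))
        assert atra_score(zero).score == 0.0
        full = simulate_growth_assay(
            GrowthSimParams(imax=1.0, ec50_um=1e-12, hill=1.0, cv=0.0))
        assert atra_score(full).score == pytest.approx(1.0, abs=1e-9)

    def test_hill_closed_form_matches_numeric_trapezoid(self, clean_assay):
        doses = np.array([0.001, 0.01, 0.1, 1.0, 10.0])
        x = np.log10(doses)
        y = hill_inhibition(doses, 0.8, 0.1, 1.0)
        expected = np.trapezoid(y, x) / (x[-1] - x[0])
        assert atra_score(clean_assay).score == pytest.approx(expected,
                                                              abs=1e-12)

    def test_absorbance_unit_invariance(self, clean_assay):
        scaled = GrowthAssay(clean_assay.cell_line,
                             clean_assay.data.assign(
                                 od=clean_assay.data["od"] * 7.3))
        assert atra_score(scaled).score == pytest.approx(
            atra_score(clean_assay).score, abs=1e-12)

    def test_monotone_in_imax(self):
        scores = []
        for imax in (0.2, 0.5, 0.9):
            assay = simulate_growth_assay(GrowthSimParams(imax=imax, cv=0.0))
            scores.append(atra_score(assay).score)
        assert scores == sorted(scores)

    def test_single_nonzero_dose_falls_back_with_warning(self, caplog):
        assay = simulate_growth_assay(GrowthSimParams(cv=0.0),
                                      concentrations=(0.0, 0.1))
        with caplog.at_level("WARNING", logger="atrasens"):
            res = atra_score(assay)
        assert res.score == pytest.approx(res.inhibition[0.1], abs=1e-12)
        assert any("single nonzero dose" in r.message for r in caplog.records)

    def test_replicate_count_invariance(self):
        one = simulate_growth_assay(GrowthSimParams(cv=0.0), n_replicates=1)
        five = simulate_growth_assay(GrowthSimParams(cv=0.0), n_replicates=5)
        assert atra_score(one).score == pytest.approx(
            atra_score(five).score, abs=1e-12)


def brute_force_partition(values, k):
    """Minimal within-block SSE over all contiguous k-partitions (oracle)."""
    n = len(values)
    best, best_bounds = math.inf, None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        sse = 0.0
        for i, j in zip(bounds, bounds[1:]):
            block = values[i:j]
            sse += sum((v - sum(block) / len(block)) ** 2 for v in block)
        if sse < best - 1e-15:
            best, best_bounds = sse, bounds
    return best, best_bounds


class TestGroups:
    def test_reference_partition(self):
        scores = dict(zip("abcdefgh",
                          [0.95, 0.9, 0.6, 0.55, 0.3, 0.25, 0.02, 0.0]))
        labels = assign_sensitivity_groups(scores)
        assert {k for k, v in labels.items() if v == "A"} == {"a", "b"}
        assert {k for k, v in labels.items() if v == "B"} == {"c", "d"}
        assert {k for k, v in labels.items() if v == "C"} == {"e", "f"}
        assert {k for k, v in labels.items() if v == "D"} == {"g", "h"}

    def test_k1_all_a(self):
        labels = assign_sensitivity_groups({"x": 1.0, "y": 2.0}, k=1)
        assert set(labels.values()) == {"A"}

    def test_order_invariance(self):
        scores = {f"l{i}": s for i, s in
                  enumerate([0.9, 0.1, 0.5, 0.45, 0.85, 0.05, 0.6, 0.2])}
        shuffled = dict(sorted(scores.items(), key=lambda kv: kv[1]))
        assert assign_sensitivity_groups(scores) == \
            assign_sensitivity_groups(shuffled)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(4, 13))
            values = sorted(rng.uniform(0, 1, size=n).round(4))
            scores = {f"l{i}": v for i, v in enumerate(values)}
            labels = assign_sensitivity_groups(scores)
            # recover block SSE from the labeling
            sse = 0.0
            for g in "ABCD":
                block = [scores[l] for l, lab in labels.items() if lab == g]
                assert block, "every group must be nonempty"
                mu = sum(block) / len(block)
                sse += sum((v - mu) ** 2 for v in block)
            best, _ = brute_force_partition(values, 4)
            assert sse == pytest.approx(best, abs=1e-9)

    def test_too_few_distinct_scores_rejected(self):
        with pytest.raises(ValidationError):
            assign_sensitivity_groups({"a": 1.0, "b": 1.0, "c": 1.0})


class TestTertiles:
    def test_42_lines_split_14_14_14(self):
        rng = np.random.default_rng(1)
        scores = {f"l{i}": float(s)
                  for i, s in enumerate(rng.uniform(0, 1, 42))}
        tertiles = assign_tertiles(scores)
        counts = pd.Series(tertiles).value_counts()
        assert counts["T1"] == counts["T2"] == counts["T3"] == 14

    def test_three_lines(self):
        assert assign_tertiles({"a": 3, "b": 2, "c": 1}) == \
            {"a": "T1", "b": "T2", "c": "T3"}

    def test_tie_policy_follows_input_order(self):
        tertiles = assign_tertiles({f"l{i}": 1.0 for i in range(6)})
        assert [tertiles[f"l{i}"] for i in range(6)] == \
            ["T1", "T1", "T2", "T2", "T3", "T3"]

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=3, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_sizes_differ_by_at_most_one(self, values):
        scores = {f"l{i}": v for i, v in enumerate(values)}
        counts = pd.Series(assign_tertiles(scores)).value_counts()
        assert counts.max() - counts.min() <= 1
        # T1 holds the highest scores
        t1_min = min(v for l, v in scores.items()
                     if assign_tertiles(scores)[l] == "T1")
        t3_max = max(v for l, v in scores.items()
                     if assign_tertiles(scores)[l] == "T3")
        assert t1_min >= t3_max - 1e-12
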