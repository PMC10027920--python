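"""Unit and property tests for the repertoire statistics battery.

Brute-force oracles here recompute every statistic from first principles on
plain Python data structures, independent of the implementation path.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from immunopair.errors import DataError, ParameterError
from immunopair.repstats import (
    expansion_summary,
    group_compare,
    sharing_summary,
    vj_usage,
    vj_usage_correlation,
)

from conftest import make_cdr3, make_repertoire, random_repertoire


# ---------------------------------------------------------------------- oracles

def brute_bin_fraction(freqs, t, mode="mass"):
    above = [f for f in freqs if f > t]
    return sum(above) if mode == "mass" else len(above) / len(freqs)


def brute_top_n(freqs_by_key, n):
    order = sorted(freqs_by_key.items(), key=lambda kv: (-kv[1], kv[0]))
    return sum(f for _, f in order[:n])


def rank_then_pearson(x, y):
    """Spearman via average ranks + plain Pearson."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


# ----------------------------------------------------------------- expansion

class TestExpansionSummary:
    def test_worked_example_bins(self, worked_repertoire):
        e = expansion_summary(worked_repertoire, (0.001, 0.005, 0.01), top_n=10)
        assert e.bin_fractions[0.001] == pytest.approx(0.295, abs=1e-12)
        assert e.bin_fractions[0.005] == pytest.approx(0.295, abs=1e-12)
        assert e.bin_fractions[0.01] == pytest.approx(0.28, abs=1e-12)

    def test_worked_example_top2(self, worked_repertoire):
        e = expansion_summary(worked_repertoire, (0.001,), top_n=2)
        assert e.top_n_proportion == pytest.approx(0.28, abs=1e-12)

    def test_uniform_repertoire_all_above(self):
        rep = make_repertoire([1] * 10)
        e = expansion_summary(rep, (0.01,), top_n=1)
        assert e.bin_fractions[0.01] == pytest.approx(1.0)

    def test_count_mode(self, worked_repertoire):
        e = expansion_summary(worked_repertoire, (0.005,), top_n=1, bin_mode="count")
        # clonotypes with 200, 80, 9 and 6 reads all exceed 0.5%
        assert e.bin_fractions[0.005] == pytest.approx(4 / 709)

    def test_clone_and_clonotype_counts(self):
        from immunopair.repertoire import ClonotypeRecord, Repertoire

        rep = Repertoire(
            "s",
            [
                ClonotypeRecord("CASSF", "TRBV1", "", "TRBJ1", 3),
                ClonotypeRecord("CASSF", "TRBV2", "", "TRBJ1", 1),
            ],
        )
        e = expansion_summary(rep, (0.001,), top_n=1)
        assert (e.n_clonotypes, e.n_clones) == (1, 2)

    @pytest.mark.parametrize("thresholds", [(0.0, 0.5), (0.5, 1.0), (0.5, 0.2)])
    def test_bad_thresholds(self, thresholds, worked_repertoire):
        with pytest.raises(ParameterError):
            expansion_summary(worked_repertoire, thresholds, top_n=1)

    @given(st.integers(0, 2**31))
    @settings(max_examples=40, deadline=None)
    def test_bins_monotone_and_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rep = random_repertoire(rng)
        thr = (0.001, 0.01, 0.1, 0.5)
        e = expansion_summary(rep, thr, top_n=5)
        freqs = list(rep.clonotype_frequencies().values())
        vals = [e.bin_fractions[t] for t in thr]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        for t in thr:
            assert e.bin_fractions[t] == pytest.approx(brute_bin_fraction(freqs, t))

    @given(st.integers(0, 2**31))
    @settings(max_examples=25, deadline=None)
    def test_top_n_monotone_reaches_one(self, seed):
        rng = np.random.default_rng(seed)
        rep = random_repertoire(rng)
        n_keys = len(rep.clonotype_frequencies())
        props = [
            expansion_summary(rep, (0.5,), top_n=n).top_n_proportion
            for n in range(1, n_keys + 1)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(props, props[1:]))
        assert props[-1] == pytest.approx(1.0)


# ------------------------------------------------------------------- sharing

class TestSharingSummary:
    def test_set_arithmetic_example(self):
        a = make_repertoire({"CAAAF": 1, "CEEEF": 1, "CCCCF": 1}, sample_id="A")
        b = make_repertoire({"CEEEF": 1, "CCCCF": 1, "CDDDF": 1}, sample_id="B")
        s = sharing_summary(a, b)
        assert s.n_shared == 2
        assert s.fraction_a == pytest.approx(2 / 3)
        assert s.fraction_b == pytest.approx(2 / 3)
        assert s.jaccard == pytest.approx(0.5)

    def test_identical_repertoires(self):
        a = make_repertoire({"CAAAF": 5, "CEEEF": 3, "CCCCF": 1}, sample_id="A")
        b = make_repertoire({"CAAAF": 5, "CEEEF": 3, "CCCCF": 1}, sample_id="B")
        s = sharing_summary(a, b)
        assert s.jaccard == 1.0
        assert s.rho == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        a = make_repertoire({"CAAAF": 3, "CEEEF": 2, "CCCCF": 1, "CPPPF": 4}, sample_id="A")
        b = make_repertoire({"CAAAF": 1, "CEEEF": 2, "CCCCF": 3, "CQQQF": 4}, sample_id="B")
        s = sharing_summary(a, b)
        assert s.n_shared == 3
        assert s.rho == pytest.approx(-1.0)

    def test_small_overlap_rho_undefined_not_zero(self):
        a = make_repertoire({"CAAAF": 1, "CEEEF": 1}, sample_id="A")
        b = make_repertoire({"CAAAF": 1, "CDDDF": 1}, sample_id="B")
        s = sharing_summary(a, b)
        assert s.n_shared == 1
        assert not s.rho_defined
        assert s.rho is None

    def test_union_zeros_mode_uses_union(self):
        a = make_repertoire({"CAAAF": 3, "CEEEF": 1}, sample_id="A")
        b = make_repertoire({"CAAAF": 1, "CDDDF": 3}, sample_id="B")
        s = sharing_summary(a, b, corr_mode="union-zeros")
        assert s.n_shared_used == 3

    @given(st.integers(0, 2**31))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_under_swap(self, seed):
        rng = np.random.default_rng(seed)
        a = random_repertoire(rng, sample_id="A")
        b = random_repertoire(rng, sample_id="B")
        s1 = sharing_summary(a, b)
        s2 = sharing_summary(b, a)
        assert s1.n_shared == s2.n_shared
        assert s1.jaccard == pytest.approx(s2.jaccard)
        assert s1.fraction_a == pytest.approx(s2.fraction_b)

    @given(st.integers(0, 2**31))
    @settings(max_examples=30, deadline=None)
    def test_spearman_matches_rank_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shared = [make_cdr3(i) for i in range(int(rng.integers(3, 11)))]
        a = make_repertoire(
            {**{k: int(rng.integers(1, 50)) for k in shared}, "CRRRF": 1}, sample_id="A"
        )
        b = make_repertoire(
            {**{k: int(rng.integers(1, 50)) for k in shared}, "CWWWF": 1}, sample_id="B"
        )
        s = sharing_summary(a, b)
        fa = a.clonotype_frequencies()
        fb = b.clonotype_frequencies()
        x = [fa[k] for k in sorted(shared)]
        y = [fb[k] for k in sorted(shared)]
        expected = rank_then_pearson(x, y)
        if np.isfinite(expected):
            assert s.rho == pytest.approx(expected, abs=1e-12)


# ------------------------------------------------------------------ V-J usage

class TestVJUsage:
    def test_single_combination(self):
        rep = make_repertoire([2, 3], v_call="TRBV1*01", j_call="TRBJ1*02")
        u = vj_usage(rep)
        assert u.usage.loc["TRBV1", "TRBJ1"] == pytest.approx(1.0)

    def test_two_combinations_mass(self):
        from immunopair.repertoire import ClonotypeRecord, Repertoire

        rep = Repertoire(
            "s",
            [
                ClonotypeRecord("CAAAF", "TRBV1", "", "TRBJ1", 3),
                ClonotypeRecord("CEEEF", "TRBV2", "", "TRBJ1", 1),
            ],
        )
        u = vj_usage(rep)
        assert u.usage.loc["TRBV1", "TRBJ1"] == pytest.approx(0.75)
        assert u.usage.loc["TRBV2", "TRBJ1"] == pytest.approx(0.25)

    def test_clonotype_weighting(self):
        from immunopair.repertoire import ClonotypeRecord, Repertoire

        rep = Repertoire(
            "s",
            [
                ClonotypeRecord("CAAAF", "TRBV1", "", "TRBJ1", 99),
                ClonotypeRecord("CEEEF", "TRBV2", "", "TRBJ1", 1),
            ],
        )
        u = vj_usage(rep, weight="clonotype")
        assert u.usage.loc["TRBV1", "TRBJ1"] == pytest.approx(0.5)

    @given(st.integers(0, 2**31))
    @settings(max_examples=30, deadline=None)
    def test_total_mass_one(self, seed):
        rng = np.random.default_rng(seed)
        rep = random_repertoire(rng)
        u = vj_usage(rep)
        assert u.usage.to_numpy().sum() == pytest.approx(1.0, abs=1e-9)
        assert (u.usage.to_numpy() >= 0).all()


class TestVJUsageCorrelation:
    def _usages(self, mats):
        reps = []
        for sid, combos in mats.items():
            from immunopair.repertoire import ClonotypeRecord, Repertoire

            recs = [
                ClonotypeRecord(make_cdr3(i), v, "", j, c)
                for i, ((v, j), c) in enumerate(combos.items())
            ]
            reps.append(Repertoire(sid, recs))
        return [vj_usage(r) for r in reps]

    def test_identical_matrices_rho_one(self):
        combos = {("TRBV1", "TRBJ1"): 5, ("TRBV2", "TRBJ1"): 3, ("TRBV3", "TRBJ2"): 1}
        usages = self._usages({"A": combos, "B": dict(combos)})
        corr = vj_usage_correlation(usages, "A", min_avg_usage=0.0)
        assert corr.rho.loc["A", "B"] == pytest.approx(1.0)

    def test_zero_filter_retains_all(self):
        usages = self._usages(
            {
                "A": {("TRBV1", "TRBJ1"): 5, ("TRBV2", "TRBJ2"): 1},
                "B": {("TRBV1", "TRBJ1"): 1, ("TRBV3", "TRBJ1"): 2},
            }
        )
        corr = vj_usage_correlation(usages, "A", min_avg_usage=0.0)
        assert len(corr.retained) == 3

    def test_constructed_19_combination_filter(self):
        # reference sample: 19 combinations above 1%, one well below
        big = {(f"TRBV{i}", "TRBJ1"): 100 for i in range(1, 20)}
        ref = dict(big)
        ref[("TRBV99", "TRBJ9")] = 1  # 1/1901 < 1%
        other = {(f"TRBV{i}", "TRBJ1"): i for i in range(1, 20)}
        usages = self._usages({"HEART": ref, "EAT": other})
        corr = vj_usage_correlation(usages, "HEART", min_avg_usage=0.01)
        assert len(corr.retained) == 19

    def test_empty_filter_errors(self):
        usages = self._usages(
            {
                "A": {("TRBV1", "TRBJ1"): 1, ("TRBV2", "TRBJ1"): 1},
                "B": {("TRBV1", "TRBJ1"): 1, ("TRBV2", "TRBJ1"): 1},
            }
        )
        with pytest.raises(DataError):
            vj_usage_correlation(usages, "A", min_avg_usage=0.99)

    def test_needs_two_matrices(self):
        usages = self._usages({"A": {("TRBV1", "TRBJ1"): 1, ("TRBV2", "TRBJ1"): 1}})
        with pytest.raises(ParameterError):
            vj_usage_correlation(usages, "A")


# --------------------------------------------------------------- group tests

class TestGroupCompare:
    def test_identical_groups_ttest(self):
        stat, p = group_compare({"a": [1, 2, 3], "b": [1, 2, 3]}, test="ttest")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_mannwhitney_exact_enumeration_example(self):
        # U = 0; among C(6,3)=20 equally likely rank splits only the two
        # extremes are as extreme, so two-sided p = 2/20 = 0.1
        stat, p = group_compare({"a": [1, 2, 3], "b": [10, 20, 30]}, test="mannwhitney")
        assert stat in (0.0, 9.0)
        assert p == pytest.approx(0.1)

    def test_wilcoxon_degenerate_flagged(self):
        stat, p = group_compare(
            {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, test="wilcoxon_paired"
        )
        assert p == pytest.approx(1.0)

    def test_wilcoxon_requires_equal_lengths(self):
        with pytest.raises(DataError):
            group_compare({"a": [1, 2, 3], "b": [1, 2]}, test="wilcoxon_paired")

    def test_small_group_rejected(self):
        with pytest.raises(DataError):
            group_compare({"a": [1], "b": [1, 2]}, test="mannwhitney")

    def test_two_groups_required(self):
        with pytest.raises(ParameterError):
            group_compare({"a": [1, 2]}, test="ttest")

    def test_mannwhitney_ties_fall_back_to_asymptotic(self):
        stat, p = group_compare(
            {"a": [1, 1, 2, 2], "b": [1, 2, 2, 3]}, test="mannwhitney"
        )
        assert 0 <= p <= 1
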