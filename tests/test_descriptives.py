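"""Paired tests, exact nonparametrics against enumeration oracles, HOMA-IR."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

import epiaccel as ea
from epiaccel.descriptives import (
    _wilcoxon_exact_p,
    is_normal,
    spearman,
    wilcoxon_signed_rank,
)
from epiaccel.errors import DegenerateTestError, ValidationError


def wilcoxon_enumeration_oracle(d):
    """Literal enumeration over all 2^n sign assignments of |d| ranks."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    n = len(ranks)
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestHomaIr:
    def test_unit_construction(self):
        assert ea.homa_ir(22.5, 18.016) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_value(self):
        # 10 * (90 / 18.016) / 22.5 evaluated independently
        assert ea.homa_ir(10.0, 90.0) == pytest.approx(2.2202486678507993, rel=1e-12)

    def test_vanishes_with_insulin(self):
        assert ea.homa_ir(1e-4, 90.0) < 1e-4

    @pytest.mark.parametrize("ins,glu", [(0.0, 90.0), (5.0, -1.0)])
    def test_non_positive_inputs_rejected(self, ins, glu):
        with pytest.raises(ValidationError):
            ea.homa_ir(ins, glu)


class TestPairedT:
    def test_matches_textbook_formula_and_scipy(self):
        rng = np.random.default_rng(1)
        x0 = rng.normal(10, 2, 10)
        x6 = x0 + rng.normal(1, 1.5, 10)
        res = ea.paired_t_test(x0, x6)
        d = x6 - x0
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p = 2 * stats.t.sf(abs(t), df=len(d) - 1)
        assert res.statistic == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)
        sp = stats.ttest_rel(x6, x0)
        assert res.statistic == pytest.approx(sp.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(sp.pvalue, rel=1e-10)

    def test_location_shift_is_recovered_exactly(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        shift = rng.normal(0.5, 0.3, 12)
        res = ea.paired_t_test(x, x + shift)
        assert res.estimate == np.mean(shift)

    def test_identical_vectors_are_degenerate(self):
        x = np.arange(8.0)
        with pytest.raises(DegenerateTestError):
            ea.paired_t_test(x, x)

    def test_p_shrinks_as_jitter_vanishes(self):
        x = np.zeros(6)
        p_prev = 1.0
        for jitter in (0.5, 0.05, 0.005):
            d = np.ones(6) + jitter * np.array([1, -1, 1, -1, 1, -1])
            p = ea.paired_t_test(x, x + d).p_value
            assert p < p_prev
            p_prev = p
        assert p_prev < 1e-6


class TestWilcoxon:
    def test_all_positive_differences_reach_the_extreme_tail(self):
        x0 = np.zeros(8)
        x6 = np.arange(1.0, 9.0)
        res = wilcoxon_signed_rank(x0, x6, mode="exact")
        assert res.statistic == 36.0  # maximal W+ = 8*9/2
        assert res.p_value == pytest.approx(2.0 / 2**8, abs=1e-15)

    def test_symmetric_differences_are_central(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        res = wilcoxon_signed_rank(np.zeros(6), d, mode="exact")
        assert res.p_value > 0.8

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_p_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        d = np.round(rng.normal(0.3, 1.0, n), 1)  # rounding induces ties/zeros
        if np.all(d == 0):
            d[0] = 0.5
        res = wilcoxon_signed_rank(np.zeros(n), d, mode="exact")
        assert res.p_value == pytest.approx(wilcoxon_enumeration_oracle(d), abs=1e-12)

    def test_all_zero_differences_are_degenerate(self):
        with pytest.raises(DegenerateTestError):
            wilcoxon_signed_rank(np.ones(5), np.ones(5))

    def test_approximate_mode_matches_normal_theory(self):
        rng = np.random.default_rng(9)
        d = rng.normal(0.5, 1.0, 30)
        res = wilcoxon_signed_rank(np.zeros(30), d, mode="approximate")
        sp = stats.wilcoxon(d, correction=False, mode="approx")
        assert res.p_value == pytest.approx(sp.pvalue, rel=1e-9)

    def test_exact_mode_rejects_large_n(self):
        d = np.arange(1.0, 31.0)
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank(np.zeros(30), d, mode="exact")


def spearman_exact_oracle(x, y):
    """Literal permutation loop for P(|rho| >= |rho_obs|), small n only."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    count = total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        count += abs(r) >= abs(rho_obs) - 1e-12
        total += 1
    return count / total


class TestSpearman:
    def test_monotone_is_plus_one(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 11.0])
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        x = np.arange(6.0)
        assert spearman(x, -(x**3)).rho == pytest.approx(-1.0)

    def test_mid_rank_pearson_with_ties(self):
        x = np.array([1.0, 2.0, 2.0, 4.0, 5.0, 7.0, 8.0, 9.0, 10.0, 12.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 6.0, 5.0, 9.0, 8.0, 7.0, 11.0])
        res = spearman(x, y)
        rho_oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert res.rho == pytest.approx(rho_oracle, abs=1e-12)
        sp = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(sp.statistic, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_permutation_p_matches_literal_loop(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = spearman(x, y)
        assert res.p_value == pytest.approx(spearman_exact_oracle(x, y), abs=1e-12)

    @pytest.mark.parametrize("transform", [np.exp, lambda v: v**3, lambda v: 5 * v - 2])
    def test_invariant_under_strictly_monotone_transforms(self, transform):
        rng = np.random.default_rng(13)
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        base = spearman(x, y)
        trans = spearman(transform(x), y)
        assert trans.rho == pytest.approx(base.rho, abs=1e-12)
        assert trans.p_value == pytest.approx(base.p_value, abs=1e-12)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateTestError):
            spearman(np.ones(5), np.arange(5.0))


class TestSummarizeCohort:
    def test_routing_and_categorical_rows(self, scored10):
        lds, _ = scored10
        rng = np.random.default_rng(0)
        n = lds.n_obs
        data = lds.data.assign(
            gaussian_var=rng.normal(10, 1, n),
            lognormal_var=np.exp(rng.normal(0, 1.2, n)),
        )
        lds2 = ea.LongitudinalDataset(data)
        table = ea.summarize_cohort(lds2, variables=["gaussian_var", "lognormal_var", "sex"])
        routed = dict(zip(table["variable"], table["test"]))
        assert routed["gaussian_var"] == "paired_t"
        assert routed["lognormal_var"] == "wilcoxon_signed_rank"
        assert routed["sex"] == "none"
        sex_row = table[table["variable"] == "sex"].iloc[0]
        assert "50%" in sex_row["summary_t0"]
        assert np.isnan(sex_row["p_value"])
        # routing agrees with an independent Shapiro-Wilk decision
        assert is_normal(data["gaussian_var"]) and not is_normal(data["lognormal_var"])

    def test_manual_override_forces_the_test(self, scored10):
        lds, _ = scored10
        table = ea.summarize_cohort(
            lds, variables=["igf1"], overrides={"igf1": "paired_t"}
        )
        assert table["test"].iloc[0] == "paired_t"

    def test_quartile_summary_round_trips_type7_convention(self, scored10):
        lds, _ = scored10
        table = ea.summarize_cohort(
            lds, variables=["igf1"], overrides={"igf1": "wilcoxon"}
        )
        x0, _ = lds.paired("igf1")
        q1, med, q3 = np.quantile(x0, [0.25, 0.5, 0.75])
        assert table["summary_t0"].iloc[0] == f"{med:.4g} [{q1:.4g};{q3:.4g}]"


class TestAgeCorrelations:
    def test_one_row_per_timepoint_with_valid_rho(self, scored10):
        lds, _ = scored10
        corr = ea.age_correlations(lds)
        assert list(corr["timepoint"]) == ["T0", "T6"]
        assert ((corr["rho"] >= -1) & (corr["rho"] <= 1)).all()
        assert (corr["n"] == lds.n_subjects).all()
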