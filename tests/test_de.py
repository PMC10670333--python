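"""Normalization and NB Wald differential expression.

Oracles: an independently coded median-of-ratios (plain loops), closed
forms for the VST surrogate, the Poisson small-dispersion limit, and a
by-hand BH step-up.
"""

import numpy as np
import pandas as pd
import pytest

from virotrans.datatypes import ValidationError
from virotrans.de import (
    NormalizationError,
    bh_adjust,
    call_degs,
    estimate_dispersion,
    size_factors,
    vst_like,
    wald_test,
)

from .conftest import make_matrix


def median_of_ratios_oracle(counts):
    """Straight-from-definition reimplementation (loops, no vectorization)."""
    counts = np.asarray(counts, dtype=float)
    n_genes, n_samples = counts.shape
    ref = [g for g in range(n_genes) if all(counts[g, j] > 0 for j in range(n_samples))]
    geomean = {g: np.exp(np.mean([np.log(counts[g, j]) for j in range(n_samples)])) for g in ref}
    return np.array([np.median([counts[g, j] / geomean[g] for g in ref]) for j in range(n_samples)])


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        m = make_matrix(np.tile([[10], [20], [5]], (1, 4)))
        np.testing.assert_allclose(size_factors(m), 1.0)

    def test_doubled_sample_has_double_factor(self):
        a = np.array([[10], [20], [5]])
        m = make_matrix(np.hstack([a, 2 * a]))
        sf = size_factors(m)
        assert sf[1] / sf[0] == pytest.approx(2.0, rel=1e-12)

    def test_matches_independent_oracle(self, rng):
        counts = rng.integers(1, 1000, size=(100, 6))
        np.testing.assert_allclose(size_factors(make_matrix(counts)), median_of_ratios_oracle(counts), atol=1e-12)

    def test_no_reference_gene_is_an_error(self):
        m = make_matrix([[0, 1], [1, 0]])
        with pytest.raises(NormalizationError):
            size_factors(m)


class TestVst:
    def test_closed_forms(self):
        m = make_matrix([[0], [3]])
        v = vst_like(m, np.array([1.0]))
        assert v[0, 0] == 0.0  # log2(0/1 + 1)
        assert v[1, 0] == 2.0  # log2(3/1 + 1)

    def test_monotone_in_counts(self):
        m = make_matrix([[1], [5], [100]])
        v = vst_like(m, np.array([1.0])).ravel()
        assert v[0] < v[1] < v[2]

    def test_scaling_one_sample_shifts_by_predicted_constant(self, rng):
        """Scaling a sample by lam rescales every normalized count by
        lam**(1/n) (the scaled sample drags the geometric reference), so
        at zero pseudocount the transform shifts by log2(lam)/n exactly."""
        counts = rng.integers(1, 500, size=(60, 5))
        lam, n = 2, counts.shape[1]
        scaled = counts.copy()
        scaled[:, 0] *= lam
        v0 = vst_like(make_matrix(counts), size_factors(make_matrix(counts)), pseudocount=0.0)
        v1 = vst_like(make_matrix(scaled), size_factors(make_matrix(scaled)), pseudocount=0.0)
        np.testing.assert_allclose(v1, v0 + np.log2(lam) / n, atol=1e-9)


class TestDispersion:
    def test_poisson_limit(self, rng):
        counts = rng.poisson(200.0, size=(300, 40))
        sf = np.ones(40)
        alpha = estimate_dispersion(make_matrix(counts), sf, [list(range(20)), list(range(20, 40))])
        assert 0 <= np.median(alpha) < 0.02

    def test_constant_gene_floored(self):
        counts = np.full((5, 6), 7)
        alpha = estimate_dispersion(make_matrix(counts), np.ones(6), [list(range(3)), list(range(3, 6))])
        assert (alpha[0] >= 1e-8) and alpha[0] < 1e-3

    def test_nb_parameter_recovery(self, rng):
        true_alpha, mu = 0.2, 150.0
        n = 1 / true_alpha
        counts = rng.negative_binomial(n, n / (n + mu), size=(400, 40))
        alpha = estimate_dispersion(make_matrix(counts), np.ones(40), [list(range(20)), list(range(20, 40))])
        assert 0.1 <= np.median(alpha) <= 0.3

    def test_singleton_groups_fall_back_to_trend(self, rng):
        counts = rng.poisson(100.0, size=(50, 2))
        with pytest.warns(UserWarning, match="singleton"):
            alpha = estimate_dispersion(make_matrix(counts), np.ones(2), [[0], [1]])
        assert (alpha > 0).all()


class TestWald:
    def test_null_gene_has_zero_lfc_unit_p(self):
        counts = np.tile([[50, 50, 50, 50, 50, 50]], (3, 1))
        m = make_matrix(counts)
        res = wald_test(m, np.ones(6), np.full(3, 0.05), ["S0", "S1", "S2"], ["S3", "S4", "S5"])
        assert res["log2fc"].abs().max() < 1e-8
        assert (res["p"] > 0.99).all()

    def test_all_zero_gene_untested(self):
        counts = np.array([[0, 0, 0, 0], [10, 12, 9, 11]])
        m = make_matrix(counts)
        res = wald_test(m, np.ones(4), np.full(2, 0.05), ["S0", "S1"], ["S2", "S3"])
        assert not res["tested"].iloc[0]
        assert np.isnan(res.loc["G0", "p"]) and np.isnan(res.loc["G0", "padj"])
        assert res["tested"].iloc[1]

    def test_one_sided_zero_gene_not_significant(self):
        # a gene absent from one group gets a huge SE, not a fake call
        counts = np.array([[0, 0, 0, 1, 1, 1]])
        m = make_matrix(counts)
        res = wald_test(m, np.ones(6), np.full(1, 0.05), ["S0", "S1", "S2"], ["S3", "S4", "S5"])
        assert res["tested"].iloc[0]
        assert res["se"].iloc[0] > 1.0
        assert res["p"].iloc[0] > 0.05

    def test_recovers_planted_fold_change(self, rng):
        n_genes, mu = 300, 200.0
        lfc = np.zeros(n_genes)
        lfc[:60], lfc[60:120] = 2.0, -2.0
        n = 1 / 0.05
        cc = rng.negative_binomial(n, n / (n + mu), size=(n_genes, 5))
        ct = rng.negative_binomial(n, n / (n + mu * 2.0**lfc)[:, None], size=(n_genes, 5))
        m = make_matrix(np.hstack([cc, ct]))
        sf = size_factors(m)
        alpha = estimate_dispersion(m, sf, [list(range(5)), list(range(5, 10))])
        res = wald_test(m, sf, alpha, [f"S{j}" for j in range(5)], [f"S{j}" for j in range(5, 10)])
        assert res["log2fc"][:60].median() == pytest.approx(2.0, abs=0.15)
        assert res["log2fc"][60:120].median() == pytest.approx(-2.0, abs=0.15)

    def test_groups_must_be_disjoint(self):
        m = make_matrix([[1, 2, 3]])
        with pytest.raises(ValidationError, match="overlap"):
            wald_test(m, np.ones(3), np.ones(1), ["S0", "S1"], ["S1", "S2"])


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        # step-up: q_(i) = min over j>=i of p_(j)*m/j -> all 0.03 here
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.2])), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust(np.ones(5)), 1.0)

    def test_nan_passthrough_excluded_from_denominator(self):
        q = bh_adjust(np.array([0.01, np.nan, 0.02, 0.03]))
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2, 3]], [0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust(np.array([1.2]))

    def test_q_dominates_p(self, rng):
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()


class TestCallDegs:
    def test_empty_result(self):
        res = pd.DataFrame(columns=["log2fc", "padj"], dtype=float)
        up, down = call_degs(res)
        assert up.genes == frozenset() and down.genes == frozenset()

    def test_single_significant_up(self):
        res = pd.DataFrame({"log2fc": [2.0], "padj": [0.01]}, index=["G"])
        up, down = call_degs(res)
        assert up.genes == frozenset({"G"}) and down.genes == frozenset()

    def test_up_down_always_disjoint(self, rng):
        res = pd.DataFrame(
            {"log2fc": rng.normal(size=500), "padj": rng.uniform(size=500)},
            index=[f"G{i}" for i in range(500)],
        )
        up, down = call_degs(res, alpha_fdr=0.5)
        assert not (up.genes & down.genes)
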