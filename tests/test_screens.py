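"""Correlation screens against viral load and the CD50 cytotoxic dose.

The published seven-culture phenotype panel doubles as an exact test
vector: Pearson on log10(CD50) vs apoptotic fractions must match a
closed-form oracle to 1e-12, with the negative sign the study reports.
"""

import numpy as np
import pandas as pd
import pytest

from virotrans.datasets import load_culture_phenotypes
from virotrans.datatypes import ValidationError
from virotrans.screens import (
    ScreenError,
    apoptosis_cd50_summary,
    cd50_covariate,
    gene_covariate_screen,
    pearson,
    top_k_split,
    viral_cd50_screen,
)


def pearson_oracle(x, y):
    """Closed-form product-moment correlation, coded independently."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


class TestPearson:
    def test_affine_is_perfect(self):
        x = np.arange(5.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_published_phenotypes_match_oracle_and_sign(self):
        ph = load_culture_phenotypes()
        x = np.log10(ph["cd50_pfu_per_cell"])
        for col in ("annv_pi_minus_pct", "annv_pi_plus_pct"):
            r = pearson(x, ph[col])
            assert r == pytest.approx(pearson_oracle(x, ph[col]), abs=1e-12)
            assert r < 0  # apoptotic response falls as resistance (CD50) rises

    def test_zero_variance_is_error(self):
        with pytest.raises(ValidationError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_p_value_from_t_distribution(self):
        r, p = pearson(np.arange(10.0), np.arange(10.0) + np.sin(np.arange(10)), with_p=True)
        assert 0 < p < 0.05 and r > 0.9


class TestCd50Covariate:
    @pytest.fixture
    def tables(self):
        samples = pd.DataFrame(
            {
                "sample_id": ["NB_a", "NB_b", "BR1_a"],
                "culture_id": ["NB", "NB", "BR1"],
                "timepoint_h": [24.0, 24.0, 24.0],
                "infected": [True, True, True],
                "replicate": [1, 2, 1],
            }
        )
        pheno = pd.DataFrame({"culture_id": ["NB", "BR1"], "cd50_pfu_per_cell": [5.8, 6.3e-3]})
        return samples, pheno

    def test_log10_by_default(self, tables):
        cov = cd50_covariate(*tables)
        assert cov["NB_a"] == pytest.approx(np.log10(5.8), abs=1e-12)

    def test_raw_scale_option(self, tables):
        cov = cd50_covariate(*tables, log10_transform=False)
        assert cov["NB_a"] == pytest.approx(5.8)

    def test_samples_of_one_culture_share_value(self, tables):
        cov = cd50_covariate(*tables)
        assert cov["NB_a"] == cov["NB_b"]

    def test_missing_culture_is_error(self, tables):
        samples, pheno = tables
        with pytest.raises(ValidationError, match="missing"):
            cd50_covariate(samples, pheno[pheno["culture_id"] == "NB"])


class TestGeneCovariateScreen:
    def test_gene_equal_to_covariate_has_unit_r(self):
        cov = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        expr = pd.DataFrame([cov.to_numpy(), [4.0, 3.0, 2.0, 1.0]], index=["g+", "g-"], columns=list("abcd"))
        table = gene_covariate_screen(expr, cov)
        assert table.loc["g+", "r"] == pytest.approx(1.0)
        assert table.loc["g-", "r"] == pytest.approx(-1.0)

    def test_null_genes_have_small_mean_r(self, rng):
        n = 21
        expr = pd.DataFrame(rng.normal(size=(300, n)), columns=[f"s{j}" for j in range(n)])
        cov = pd.Series(rng.normal(size=n), index=expr.columns)
        table = gene_covariate_screen(expr, cov)
        assert abs(table["r"].mean()) < 0.05

    def test_zero_variance_genes_excluded_and_counted(self):
        cov = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        expr = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 4.0]], index=["flat", "ok"], columns=list("abc"))
        table = gene_covariate_screen(expr, cov)
        assert list(table.index) == ["ok"]
        assert table.attrs["n_zero_variance"] == 1

    def test_too_few_samples_is_error(self):
        cov = pd.Series([1.0, 2.0], index=list("ab"))
        expr = pd.DataFrame([[1.0, 2.0]], columns=list("ab"))
        with pytest.raises(ScreenError):
            gene_covariate_screen(expr, cov)

    def test_r_invariant_under_affine_covariate(self, rng):
        n = 12
        expr = pd.DataFrame(rng.normal(size=(50, n)), columns=[f"s{j}" for j in range(n)])
        cov = pd.Series(rng.normal(size=n), index=expr.columns)
        t1 = gene_covariate_screen(expr, cov)
        t2 = gene_covariate_screen(expr, 3.0 * cov + 7.0)
        np.testing.assert_allclose(t1["r"], t2["r"], atol=1e-12)


class TestTopKSplit:
    def table(self, r_values):
        return pd.DataFrame({"r": r_values}, index=[f"g{i}" for i in range(len(r_values))])

    def test_k_exceeding_table_returns_all_qualifying(self):
        pos, neg = top_k_split(self.table([0.5, 0.2, -0.1, 0.9, 0.0]), k=300)
        assert set(pos) == {"g0", "g1", "g3"} and neg == ["g2"]

    def test_all_negative_gives_empty_positive(self):
        pos, neg = top_k_split(self.table([-0.5, -0.2]), k=2)
        assert pos == [] and set(neg) == {"g0", "g1"}

    def test_sets_disjoint_and_ordered(self, rng):
        t = self.table(rng.uniform(-1, 1, size=100))
        pos, neg = top_k_split(t, k=10)
        assert not (set(pos) & set(neg))
        assert list(t.loc[pos, "r"]) == sorted(t.loc[pos, "r"], reverse=True)
        assert list(t.loc[neg, "r"]) == sorted(t.loc[neg, "r"])

    def test_invalid_k(self):
        with pytest.raises(ValidationError):
            top_k_split(self.table([0.1]), k=0)


class TestViralCd50Screen:
    def test_degenerate_threshold_catches_all(self, rng):
        cov = pd.Series(rng.normal(size=8), index=[f"s{j}" for j in range(8)])
        expr = pd.DataFrame(rng.normal(size=(5, 8)), index=[f"V{i}" for i in range(5)], columns=cov.index)
        pos, neg = viral_cd50_screen(expr, cov, positive_threshold=-1.0)
        assert set(pos) == {f"V{i}" for i in range(5)}

    def test_negative_list_sorted_most_inverse_first(self):
        cov = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        expr = pd.DataFrame(
            [[4.0, 3.0, 2.0, 1.0], [4.0, 3.5, 2.0, 3.0]],
            index=["strong", "weak"],
            columns=list("abcd"),
        )
        _, neg = viral_cd50_screen(expr, cov)
        assert neg == ["strong", "weak"]


class TestApoptosisSummary:
    def test_linear_relation_gives_unit_r2(self):
        cd50 = np.array([0.01, 0.1, 1.0, 10.0])
        ph = pd.DataFrame(
            {"culture_id": list("abcd"), "cd50_pfu_per_cell": cd50, "annv_pi_minus_pct": 50 - 10 * np.log10(cd50)}
        )
        out = apoptosis_cd50_summary(ph)
        assert out["annv_pi_minus_pct"]["r2"] == pytest.approx(1.0)
        assert out["annv_pi_minus_pct"]["r"] == pytest.approx(-1.0)

    def test_published_panel_matches_pearson_oracle(self):
        ph = load_culture_phenotypes()
        out = apoptosis_cd50_summary(ph)
        x = np.log10(ph["cd50_pfu_per_cell"])
        for col in ("annv_pi_minus_pct", "annv_pi_plus_pct"):
            assert out[col]["r"] == pytest.approx(pearson_oracle(x, ph[col]), abs=1e-12)
            assert out[col]["n"] == 7

    def test_two_cultures_insufficient(self):
        ph = pd.DataFrame({"culture_id": ["a", "b"], "cd50_pfu_per_cell": [0.1, 1.0], "annv_pi_minus_pct": [20.0, 10.0]})
        with pytest.raises(ValidationError):
            apoptosis_cd50_summary(ph)
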