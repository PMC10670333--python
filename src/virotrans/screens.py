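"""Genome-wide Pearson correlation screens against infection covariates.

Two covariates matter in this study: the per-sample total viral RNA
fraction, and the per-culture CD50 cytotoxic dose (log10-transformed by
default, since it spans three orders of magnitude and raw-scale Pearson
would be dominated by the most resistant culture).  Transcripts whose
expression rises with CD50 are resistance-associated; transcripts that
fall with CD50 are sensitivity-associated.  Screens run on the
VST-scale expression of infected samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import ValidationError


class ScreenError(ValueError):
    pass


def pearson(x, y, with_p: bool = False):
    """Product-moment correlation (n >= 3, both variances positive);
    optionally the two-sided p from the t distribution with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("need equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance; correlation undefined")
    res = scipy.stats.pearsonr(x, y)
    return (float(res.statistic), float(res.pvalue)) if with_p else float(res.statistic)


def cd50_covariate(
    samples: pd.DataFrame, phenotype: pd.DataFrame, log10_transform: bool = True
) -> pd.Series:
    """Map each sample to its culture's CD50 (log10 by default)."""
    pheno = phenotype.set_index("culture_id")["cd50_pfu_per_cell"]
    missing = set(samples["culture_id"]) - set(pheno.index)
    if missing:
        raise ValidationError(f"cultures missing from phenotype table: {sorted(missing)}")
    if (pheno <= 0).any():
        raise ValidationError("CD50 must be positive")
    vals = samples["culture_id"].map(pheno).astype(float)
    if log10_transform:
        vals = np.log10(vals)
    return pd.Series(vals.to_numpy(), index=samples["sample_id"].tolist())


def gene_covariate_screen(expr: pd.DataFrame, covariate: pd.Series) -> pd.DataFrame:
    """Per-gene Pearson r of expression (genes x samples) vs a covariate.

    Zero-variance genes are excluded (their number is reported in
    ``.attrs['n_zero_variance']``).  Returns gene_id-indexed columns
    r, n, p.
    """
    cov = covariate.loc[expr.columns].to_numpy(dtype=float)
    n = len(cov)
    if n < 3:
        raise ScreenError("need >= 3 samples")
    if np.std(cov) == 0:
        raise ScreenError("covariate has zero variance")
    X = expr.to_numpy(dtype=float)
    xc = X - X.mean(axis=1, keepdims=True)
    yc = cov - cov.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    ok = sx > 0
    r = np.full(X.shape[0], np.nan)
    r[ok] = (xc[ok] @ yc) / (sx[ok] * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    table = pd.DataFrame({"r": r, "n": n, "p": p}, index=expr.index)[ok]
    table.attrs["n_zero_variance"] = int((~ok).sum())
    return table


def top_k_split(table: pd.DataFrame, k: int = 300) -> tuple[list[str], list[str]]:
    """(top-k positively correlated, top-k negatively correlated) gene lists.

    Fewer are returned if fewer qualify (r must be strictly >0 / <0);
    ties break by gene id for determinism.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    if table.empty:
        raise ValidationError("empty correlation table")
    t = table.copy()
    t["_gene"] = t.index
    pos = t[t["r"] > 0].sort_values(["r", "_gene"], ascending=[False, True], kind="stable")
    neg = t[t["r"] < 0].sort_values(["r", "_gene"], ascending=[True, True], kind="stable")
    return list(pos.index[:k]), list(neg.index[:k])


def viral_cd50_screen(
    expr: pd.DataFrame, covariate: pd.Series, positive_threshold: float = 0.5
) -> tuple[list[str], list[str]]:
    """Screen viral transcripts against CD50.

    Returns (positive list: r > threshold; negative list: r < 0 sorted
    ascending, i.e. strongest inverse correlation first).
    """
    table = gene_covariate_screen(expr, covariate)
    positive = sorted(table.index[table["r"] > positive_threshold])
    neg = table[table["r"] < 0].copy()
    neg["_gene"] = neg.index
    neg = neg.sort_values(["r", "_gene"], ascending=[True, True], kind="stable")
    return positive, list(neg.index)


def apoptosis_cd50_summary(phenotype: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Correlate apoptotic fractions with log10 CD50 across cultures.

    Returns {'annv_pi_minus_pct': {'r':…, 'r2':…, 'n':…}, …}; a marker
    column that is absent or has <3 values yields no entry.
    """
    out: dict[str, dict[str, float]] = {}
    x_all = np.log10(phenotype["cd50_pfu_per_cell"].to_numpy(dtype=float))
    for col in ("annv_pi_minus_pct", "annv_pi_plus_pct"):
        if col not in phenotype.columns:
            continue
        y = phenotype[col].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < 3:
            continue
        r = pearson(x_all[ok], y[ok])
        out[col] = {"r": r, "r2": r * r, "n": int(ok.sum())}
    if not out:
        raise ValidationError("need >= 3 cultures with apoptotic marker values")
    return out
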