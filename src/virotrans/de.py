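"""Normalization and negative-binomial Wald differential expression.

Reimplements the standard bulk RNA-seq workflow from counts onward:
median-of-ratios size factors, a log2(normalized + 1) surrogate for the
variance-stabilizing transform, a method-of-moments dispersion estimate
shrunk halfway to a fitted 1/mu trend, and a per-gene two-group NB GLM
(log link, size-factor offsets) with a Wald test on the log2 fold
change.  The Wald caller is a deliberate simplification of the full
empirical-Bayes machinery of dedicated DE packages: no outlier
replacement, no LFC shrinkage, two-group designs only.  All estimators
are vectorized across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CountMatrix, ValidationError

LN2 = np.log(2.0)
_ALPHA_FLOOR = 1e-8


class NormalizationError(ValueError):
    pass


def size_factors(matrix: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors.

    Reference genes are those with strictly positive counts in every
    sample; each sample's factor is the median over reference genes of
    count / geometric-mean-across-samples.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else np.asarray(matrix)
    ref = (counts > 0).all(axis=1)
    if not ref.any():
        raise NormalizationError(
            "no gene has positive counts in all samples; size factors are undefined "
            "(filter samples or supply deeper data)"
        )
    ref_counts = counts[ref, :].astype(float)
    geomean = np.exp(np.log(ref_counts).mean(axis=1, keepdims=True))
    return np.median(ref_counts / geomean, axis=0)


def vst_like(
    matrix: CountMatrix | np.ndarray, sf: np.ndarray, pseudocount: float = 1.0
) -> np.ndarray:
    """log2(count / size factor + pseudocount) — a monotone VST surrogate
    used for clustering, ordination and correlation screens."""
    counts = matrix.counts if isinstance(matrix, CountMatrix) else np.asarray(matrix)
    sf = np.asarray(sf, dtype=float)
    if (sf <= 0).any():
        raise ValidationError("size factors must be positive")
    return np.log2(counts / sf[np.newaxis, :] + pseudocount)


def estimate_dispersion(
    matrix: CountMatrix | np.ndarray,
    sf: np.ndarray,
    groups: list[np.ndarray] | list[list[int]],
) -> np.ndarray:
    """Per-gene NB dispersion: method-of-moments pooled across groups on
    normalized counts, shrunk halfway to a least-squares a0 + a1/mu trend.

    ``groups`` partitions sample columns (indices).  With all groups
    singleton there is no within-group variance; the estimate degrades
    to the trend alone with a warning.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else np.asarray(matrix)
    norm = counts / np.asarray(sf, dtype=float)[np.newaxis, :]
    groups = [np.asarray(g, dtype=int) for g in groups]

    dof = sum(max(len(g) - 1, 0) for g in groups)
    mu_bar = norm.mean(axis=1)
    if dof == 0:
        warnings.warn("all groups are singleton; dispersion falls back to the trend prior")
        alpha_hat = np.full(norm.shape[0], np.nan)
    else:
        ss = np.zeros(norm.shape[0])
        for g in groups:
            if len(g) < 2:
                continue
            sub = norm[:, g]
            ss += sub.var(axis=1, ddof=1) * (len(g) - 1)
        s2 = ss / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_hat = np.where(mu_bar > 0, np.maximum(0.0, (s2 - mu_bar) / mu_bar**2), 0.0)

    # trend alpha(mu) = a0 + a1/mu by least squares over expressed genes
    fit_mask = mu_bar > 0
    if dof > 0 and fit_mask.sum() >= 2:
        X = np.column_stack([np.ones(fit_mask.sum()), 1.0 / mu_bar[fit_mask]])
        coef, *_ = np.linalg.lstsq(X, alpha_hat[fit_mask], rcond=None)
        a0, a1 = coef
    else:
        a0, a1 = 0.01, 1.0  # weak default prior when no replication exists
    with np.errstate(divide="ignore"):
        trend = np.where(mu_bar > 0, a0 + a1 / mu_bar, a0)
    trend = np.maximum(trend, _ALPHA_FLOOR)

    if dof == 0:
        alpha = trend
    else:
        alpha = 0.5 * (alpha_hat + trend)
    return np.maximum(alpha, _ALPHA_FLOOR)


def _fit_group_log_mean(
    counts: np.ndarray, sf: np.ndarray, alpha: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-gene NB GLM intercept fit for one group.

    Model: y_gj ~ NB(mu_gj, alpha_g), mu_gj = sf_j * exp(beta_g).
    Returns (beta, observed Fisher information, converged flag).
    Groups with zero total count get a half-count floor (huge SE, so the
    gene cannot be called significant from that side).
    """
    total = counts.sum(axis=1).astype(float)
    s_total = sf.sum()
    beta = np.log(np.maximum(total, 0.5) / s_total)
    converged = np.zeros(len(beta), dtype=bool)
    active = total > 0
    for _ in range(max_iter):
        if not active.any():
            break
        mu = sf[np.newaxis, :] * np.exp(beta[active, np.newaxis])
        denom = 1.0 + alpha[active, np.newaxis] * mu
        score = ((counts[active] - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-300)
        step = np.clip(step, -5.0, 5.0)
        beta_active = beta[active] + step
        done = np.abs(step) < tol
        beta[active] = beta_active
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
        still = np.zeros_like(active)
        still[idx[~done]] = True
        active = still
    converged[total == 0] = True  # floored, not iterated
    mu = sf[np.newaxis, :] * np.exp(beta[:, np.newaxis])
    denom = 1.0 + alpha[:, np.newaxis] * mu
    obs_info = (mu * (1.0 + alpha[:, np.newaxis] * counts) / denom**2).sum(axis=1)
    return beta, obs_info, converged


def wald_test(
    matrix: CountMatrix,
    sf: np.ndarray,
    alphas: np.ndarray,
    group_control: list[str],
    group_treated: list[str],
) -> pd.DataFrame:
    """Two-group NB Wald test; returns the per-gene contrast table.

    Columns: base_mean, log2fc, se, wald_z, p, padj, tested.  Genes with
    zero counts across both groups are untested (NaN statistics) and are
    excluded from the BH denominator.
    """
    if not group_control or not group_treated:
        raise ValidationError("both groups must be non-empty")
    if set(group_control) & set(group_treated):
        raise ValidationError("control and treated groups overlap")
    pos = {s: j for j, s in enumerate(matrix.samples)}
    jc = [pos[s] for s in group_control]
    jt = [pos[s] for s in group_treated]
    sf = np.asarray(sf, dtype=float)
    counts_c = matrix.counts[:, jc]
    counts_t = matrix.counts[:, jt]
    alphas = np.maximum(np.asarray(alphas, dtype=float), _ALPHA_FLOOR)

    tested = (counts_c.sum(axis=1) + counts_t.sum(axis=1)) > 0
    beta_c, info_c, conv_c = _fit_group_log_mean(counts_c, sf[jc], alphas)
    beta_t, info_t, conv_t = _fit_group_log_mean(counts_t, sf[jt], alphas)
    converged = conv_c & conv_t
    n_failed = int((~converged & tested).sum())
    if n_failed:
        warnings.warn(f"{n_failed} genes failed to converge; flagged untested")
        tested = tested & converged

    norm_all = np.concatenate([counts_c / sf[jc], counts_t / sf[jt]], axis=1)
    base_mean = norm_all.mean(axis=1)
    log2fc = (beta_t - beta_c) / LN2
    with np.errstate(divide="ignore"):
        se = np.sqrt(1.0 / np.maximum(info_c, 1e-300) + 1.0 / np.maximum(info_t, 1e-300)) / LN2
    wald_z = log2fc / se
    p = 2.0 * scipy.stats.norm.sf(np.abs(wald_z))

    result = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald_z": wald_z,
            "p": p,
            "tested": tested,
        },
        index=matrix.gene_ids,
    )
    result.loc[~tested, ["log2fc", "se", "wald_z", "p"]] = np.nan
    result["padj"] = bh_adjust(result["p"].to_numpy())
    return result


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up; NaN entries pass through untouched and
    do not enter the denominator."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    defined = ~np.isnan(p)
    if ((p[defined] < 0) | (p[defined] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if defined.any():
        q[defined] = multipletests(p[defined], method="fdr_bh")[1]
    return q


@dataclass(frozen=True)
class DegSet:
    """Thresholded DEG call for one culture x timepoint contrast."""

    culture_id: str
    timepoint_h: float
    direction: str  # "up" | "down"
    genes: frozenset[str]


def call_degs(
    result: pd.DataFrame,
    alpha_fdr: float = 0.05,
    lfc_min: float = 0.0,
    culture_id: str = "",
    timepoint_h: float = float("nan"),
) -> tuple[DegSet, DegSet]:
    """Threshold a contrast table into disjoint up / down DEG sets."""
    sig = result["padj"] < alpha_fdr
    up = frozenset(result.index[sig & (result["log2fc"] > lfc_min)])
    down = frozenset(result.index[sig & (result["log2fc"] < -lfc_min)])
    return (
        DegSet(culture_id, timepoint_h, "up", up),
        DegSet(culture_id, timepoint_h, "down", down),
    )


def contrast_by_timepoint(
    matrix: CountMatrix,
    samples: pd.DataFrame,
    culture_id: str,
    timepoint_h: float,
    alpha_fdr: float = 0.05,
    lfc_min: float = 0.0,
) -> tuple[pd.DataFrame, DegSet, DegSet]:
    """Convenience wrapper: infected-at-timepoint vs 0 h within one culture.

    Size factors come from the full matrix (all samples) so contrasts
    share a common normalization; dispersion is estimated from the two
    groups of the contrast.
    """
    sf_all = size_factors(matrix)
    sub = samples[samples["culture_id"] == culture_id]
    ctrl = sub.loc[sub["timepoint_h"] == 0, "sample_id"].tolist()
    trt = sub.loc[sub["timepoint_h"] == timepoint_h, "sample_id"].tolist()
    if not ctrl or not trt:
        raise ValidationError(f"no samples for {culture_id} at 0 h / {timepoint_h} h")
    cols = ctrl + trt
    pos = {s: j for j, s in enumerate(matrix.samples)}
    idx = [pos[s] for s in cols]
    sf = sf_all[idx]
    sub_matrix = matrix.subset_samples(cols)
    groups = [list(range(len(ctrl))), list(range(len(ctrl), len(cols)))]
    alphas = estimate_dispersion(sub_matrix, sf, groups)
    res = wald_test(sub_matrix, sf, alphas, ctrl, trt)
    up, down = call_degs(res, alpha_fdr, lfc_min, culture_id, timepoint_h)
    return res, up, down
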