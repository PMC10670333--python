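"""Cross-culture integration of the infection response.

Viral load per sample, common/unique DEG extraction across cultures,
histone-family tagging, the DEG-count-vs-load correlation, and
viral-transcript rank-averaging (the "commonly expressed viral genes"
table): viral genes are ranked within each culture x timepoint contrast
by descending log2 fold change, and ranks are averaged over all
contrasts, which is robust to per-contrast scale differences.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import CountMatrix, ValidationError
from .de import DegSet

#: id prefixes of the replication-dependent histone families
HISTONE_PREFIXES = ("H1-", "H2AC", "H2BC", "H3C", "H4C")


def viral_fraction(matrix: CountMatrix) -> pd.Series:
    """Per-sample share of counts assigned to viral genes (viral load)."""
    total = matrix.counts.sum(axis=0).astype(float)
    viral = matrix.counts[matrix.is_viral(), :].sum(axis=0).astype(float)
    frac = np.full(len(total), np.nan)
    ok = total > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} samples have zero total counts; fraction undefined")
    frac[ok] = viral[ok] / total[ok]
    return pd.Series(frac, index=matrix.samples)


def _check_sets(deg_sets: list[DegSet], direction: str) -> None:
    cultures = [d.culture_id for d in deg_sets]
    if len(set(cultures)) != len(cultures):
        raise ValidationError("duplicate culture in DEG set list")
    if any(d.direction != direction for d in deg_sets):
        raise ValidationError(f"all DEG sets must have direction {direction!r}")


def common_degs(deg_sets: list[DegSet], direction: str) -> frozenset[str]:
    """Genes differentially expressed in *every* culture (set intersection)."""
    _check_sets(deg_sets, direction)
    if not deg_sets:
        return frozenset()
    out = set(deg_sets[0].genes)
    for d in deg_sets[1:]:
        out &= d.genes
    return frozenset(out)


def unique_deg_fraction(deg_sets: list[DegSet], direction: str) -> float:
    """Percentage of the DEG union that appears in exactly one culture."""
    _check_sets(deg_sets, direction)
    counts: dict[str, int] = {}
    for d in deg_sets:
        for g in d.genes:
            counts[g] = counts.get(g, 0) + 1
    if not counts:
        return float("nan")
    unique = sum(1 for v in counts.values() if v == 1)
    return 100.0 * unique / len(counts)


def tag_gene_family(gene_ids: set[str], prefixes: tuple[str, ...] = HISTONE_PREFIXES) -> set[str]:
    """Subset of ids starting with any family prefix (default: histones)."""
    return {g for g in gene_ids if any(g.startswith(p) for p in prefixes)}


def deg_count_load_correlation(
    deg_counts: pd.Series, load: pd.Series
) -> tuple[float, float]:
    """Pearson r (and R^2) of per-culture DEG count vs mean viral fraction."""
    common = deg_counts.index.intersection(load.index)
    if len(common) < 3:
        raise ValidationError("need >=3 cultures")
    x = deg_counts.loc[common].to_numpy(dtype=float)
    y = load.loc[common].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance; correlation undefined")
    r = float(scipy.stats.pearsonr(x, y).statistic)
    return r, r * r


def rank_viral_transcripts(
    contrasts: dict[tuple[str, float], pd.DataFrame],
    viral_gene_ids: list[str],
    top_n: int = 25,
) -> tuple[pd.DataFrame, list[str]]:
    """Average-rank table of viral transcripts over all contrasts.

    Within each contrast, viral genes are ranked 1..V by descending
    log2fc (ties get average ranks); a gene missing from a contrast
    skips it (its n_contrasts drops).  Output is sorted by ascending
    average rank, final ties broken by gene id; the second return value
    is the ordered top-``top_n`` list.
    """
    if not contrasts:
        raise ValidationError("need at least one contrast")
    rank_cols = {}
    for key, res in contrasts.items():
        present = [g for g in viral_gene_ids if g in res.index]
        lfc = res.loc[present, "log2fc"].to_numpy(dtype=float)
        ranks = scipy.stats.rankdata(-lfc, method="average")
        rank_cols[key] = pd.Series(ranks, index=present)
    ranks_df = pd.DataFrame(rank_cols)  # viral genes x contrasts, NaN where absent
    ranks_df = ranks_df.reindex(viral_gene_ids)
    table = pd.DataFrame(
        {
            "average_rank": ranks_df.mean(axis=1),
            "n_contrasts": ranks_df.notna().sum(axis=1),
        }
    )
    table = table[table["n_contrasts"] > 0]
    # ascending average rank, lexicographic gene id as the deterministic tie-break
    table = table.iloc[np.lexsort((np.array(table.index), table["average_rank"].to_numpy()))]
    top = list(table.index[:top_n])
    return table, top
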