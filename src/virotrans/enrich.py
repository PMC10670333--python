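"""Gene-set overrepresentation analysis (ORA).

One-sided Fisher / hypergeometric test of a query gene set against each
term of a GMT library, restricted to a stated universe (all genes tested
in the relevant contrast), with BH-FDR across terms.  This is the plain
ORA surrogate for web-service enrichment tools; rank-deviation z-scores
and combined scores are deliberately not reproduced.
"""

from __future__ import annotations

import pandas as pd
import scipy.stats

from .datatypes import ValidationError
from .de import bh_adjust


def fisher_ora(
    query: set[str],
    universe: set[str],
    library: dict[str, set[str]],
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Upper-tail hypergeometric ORA of ``query`` against ``library``.

    Per term (restricted to ``universe`` and of restricted size >=
    ``min_term_size``): p = P(X >= k | N, K, n) with N = |universe|,
    K = |term ∩ universe|, n = |query|, k = |term ∩ query|; the odds
    ratio carries a Haldane–Anscombe 0.5 correction.  Rows sorted by p
    then term; q is BH over the reported terms.
    """
    if not universe:
        raise ValidationError("universe must be non-empty")
    stray = query - universe
    if stray:
        raise ValidationError(f"query genes outside universe: {sorted(stray)[:10]}")
    N, n = len(universe), len(query)
    rows = []
    for term, members in library.items():
        in_universe = members & universe
        K = len(in_universe)
        if K < min_term_size:
            continue
        k = len(in_universe & query)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        odds = ((k + 0.5) * (N - K - n + k + 0.5)) / ((K - k + 0.5) * (n - k + 0.5))
        rows.append((term, k, K, n, N, odds, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["term", "k", "K", "n", "N", "odds_ratio", "p"]
    ).sort_values(["p", "term"], kind="stable", ignore_index=True)
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
    else:
        table["q"] = pd.Series(dtype=float)
    return table
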