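#!/usr/bin/env python
"""Cross-culture integration of the host response.

Intersects per-culture DEG sets to find the universal infection
response, measures how culture-specific the rest is (unique-DEG
fraction), tags histone-family genes among the common responders, and
correlates per-culture DEG counts with viral load.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from virotrans.de import DegSet
from virotrans.io import read_count_matrix, read_gene_annotation, read_sample_table
from virotrans.response import (
    common_degs,
    deg_count_load_correlation,
    tag_gene_family,
    unique_deg_fraction,
    viral_fraction,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def load_deg_sets(host_ids, cultures, timepoint, direction):
    sets = []
    for c in cultures:
        res = pd.read_csv(ROOT / "de" / f"{c}_{int(timepoint)}h.tsv", sep="\t", index_col=0)
        sig = res["padj"] < 0.05
        genes = res.index[sig & ((res["log2fc"] > 0) if direction == "up" else (res["log2fc"] < 0))]
        sets.append(DegSet(c, timepoint, direction, frozenset(genes) & host_ids))
    return sets


def main() -> None:
    annotation = read_gene_annotation(ROOT / "data" / "genes.tsv")
    matrix = read_count_matrix(ROOT / "data" / "counts.tsv", annotation=annotation)
    samples = read_sample_table(ROOT / "data" / "samples.tsv")
    host_ids = frozenset(np.array(matrix.gene_ids)[~matrix.is_viral()])
    cultures = sorted(samples["culture_id"].unique())
    out = ROOT / "response"
    out.mkdir(parents=True, exist_ok=True)

    for t in (12.0, 24.0):
        for direction in ("up", "down"):
            sets = load_deg_sets(host_ids, cultures, t, direction)
            common = sorted(common_degs(sets, direction))
            uniq = unique_deg_fraction(sets, direction)
            histone = sorted(tag_gene_family(set(common)))
            pd.Series(common, name="gene_id").to_csv(out / f"common_{direction}_{int(t)}h.tsv", sep="\t", index=False)
            print(
                f"{int(t):>2} h {direction:>4}: {len(common):>3} genes common to all {len(cultures)} cultures "
                f"({len(histone)} histone-family), {uniq:.1f}% of the union is culture-unique"
            )

    counts = pd.read_csv(ROOT / "de" / "deg_counts.tsv", sep="\t")
    c24 = counts[counts["timepoint_h"] == 24.0].set_index("culture_id")
    totals = c24["n_up"] + c24["n_down"]
    frac = viral_fraction(matrix)
    infected = samples[samples["infected"]]
    load = frac.loc[infected["sample_id"]].groupby(infected["culture_id"].to_numpy()).mean()
    r, r2 = deg_count_load_correlation(totals, load)
    print(f"\nDEG count vs mean viral load across cultures: r = {r:.3f} (R^2 = {r2:.3f})")


if __name__ == "__main__":
    main()
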