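#!/usr/bin/env python
"""Genome-wide correlation screens against viral load and CD50.

Screens VST-scale expression of infected samples against (i) the total
viral RNA fraction and (ii) the per-culture CD50 cytotoxic dose
(log10).  Transcripts rising with CD50 are resistance-associated,
falling ones sensitivity-associated; the planted modules measure the
screen's recovery.  Also screens viral transcripts against CD50 (none
should correlate positively) and summarizes apoptosis vs CD50.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from virotrans.de import size_factors, vst_like
from virotrans.io import read_count_matrix, read_gene_annotation, read_phenotype_table, read_sample_table
from virotrans.response import viral_fraction
from virotrans.screens import (
    apoptosis_cd50_summary,
    cd50_covariate,
    gene_covariate_screen,
    top_k_split,
    viral_cd50_screen,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    annotation = read_gene_annotation(ROOT / "data" / "genes.tsv")
    matrix = read_count_matrix(ROOT / "data" / "counts.tsv", annotation=annotation)
    samples = read_sample_table(ROOT / "data" / "samples.tsv")
    phenotype = read_phenotype_table(ROOT / "data" / "phenotype.tsv")
    truth = pd.read_csv(ROOT / "data" / "truth_modules.tsv", sep="\t", index_col=0)["module"]
    out = ROOT / "screens"
    out.mkdir(parents=True, exist_ok=True)

    sf = size_factors(matrix)
    vst = pd.DataFrame(vst_like(matrix, sf), index=matrix.gene_ids, columns=matrix.samples)
    inf = samples.loc[samples["infected"], "sample_id"].tolist()
    host_ids = list(np.array(matrix.gene_ids)[~matrix.is_viral()])
    viral_ids = [g.gene_id for g in matrix.genes if g.origin == "virus"]

    load = viral_fraction(matrix).loc[inf]
    load_screen = gene_covariate_screen(vst.loc[host_ids, inf], load)
    load_screen.to_csv(out / "screen_viral_load.tsv", sep="\t", index_label="gene_id")
    pos_l, neg_l = top_k_split(load_screen, k=300)
    up_mod = set(truth.index[truth == "universal_up"])
    print(
        f"viral-load screen: top-300 positive captures {len(up_mod & set(pos_l))}/{len(up_mod)} "
        "universal-up genes (their response scales with infection)"
    )

    cov = cd50_covariate(samples, phenotype).loc[inf]
    cd50_screen = gene_covariate_screen(vst.loc[host_ids, inf], cov)
    cd50_screen.to_csv(out / "screen_cd50.tsv", sep="\t", index_label="gene_id")
    pos_c, neg_c = top_k_split(cd50_screen, k=300)
    res_mod = set(truth.index[truth == "resistance"])
    sen_mod = set(truth.index[truth == "sensitivity"])
    print(
        f"CD50 screen: resistance module {len(res_mod & set(pos_c))}/{len(res_mod)} in positive top-300, "
        f"sensitivity module {len(sen_mod & set(neg_c))}/{len(sen_mod)} in negative top-300"
    )
    for name, genes in (("cd50_positive_top300", pos_c), ("cd50_negative_top300", neg_c)):
        pd.Series(genes, name="gene_id").to_csv(out / f"{name}.tsv", sep="\t", index=False)

    viral_pos, viral_neg = viral_cd50_screen(vst.loc[viral_ids, inf], cov)
    print(f"viral transcripts with r > 0.5 vs CD50: {len(viral_pos)} (expected none)")
    print(f"strongest inverse viral correlates: {', '.join(viral_neg[:5])}")

    apo = apoptosis_cd50_summary(phenotype)
    for marker, stats in apo.items():
        print(f"{marker} vs log10 CD50: r = {stats['r']:.3f}, R^2 = {stats['r2']:.3f} (n = {stats['n']})")


if __name__ == "__main__":
    main()
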