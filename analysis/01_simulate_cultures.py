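#!/usr/bin/env python
"""Generate the synthetic seven-culture infection dataset.

Emulates the study design downstream of read quantification: seven
glioma/normal-brain cultures (CD50 from the published phenotype panel),
timepoints 0/12/24 h, three replicates, ~5000 host genes plus 180 viral
transcripts with power-law abundances.  Writes counts, sample design,
phenotypes and the planted truth tables under results/data/.
"""

from pathlib import Path

from virotrans.io import (
    write_count_matrix,
    write_gene_annotation,
    write_phenotype_table,
    write_sample_table,
)
from virotrans.simulate import SimConfig, simulate

SEED = 20240901
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    matrix, samples, phenotype, truth = simulate(cfg)
    write_count_matrix(matrix, OUT / "counts.tsv")
    write_gene_annotation(matrix.genes, OUT / "genes.tsv")
    write_sample_table(samples, OUT / "samples.tsv")
    write_phenotype_table(phenotype, OUT / "phenotype.tsv")
    truth.gene_module.rename("module").to_csv(OUT / "truth_modules.tsv", sep="\t", index_label="gene_id")
    truth.target_viral_fraction.rename("target_viral_fraction").to_csv(
        OUT / "truth_viral_fraction.tsv", sep="\t", index_label="sample_id"
    )
    truth.viral_weights.rename("weight").to_csv(OUT / "truth_viral_weights.tsv", sep="\t", index_label="gene_id")
    f24 = truth.target_viral_fraction[[s for s in matrix.samples if "T24" in s]]
    print(f"wrote {matrix.counts.shape[0]} genes x {matrix.counts.shape[1]} samples (seed {SEED})")
    print(f"target viral fraction at 24 h spans {f24.min():.3f} (most resistant) to {f24.max():.3f} (most sensitive)")


if __name__ == "__main__":
    main()
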