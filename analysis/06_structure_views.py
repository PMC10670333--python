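#!/usr/bin/env python
"""Sample structure: distances, complete-linkage tree, PCA.

Confirms the expected layout: infected (12/24 h) and uninfected (0 h)
samples separate along the leading principal components, because the
universal response and the viral compartment move every infected
transcriptome the same way.
"""

from pathlib import Path

import pandas as pd
from sklearn.metrics import silhouette_score

from virotrans.de import size_factors, vst_like
from virotrans.io import read_count_matrix, read_gene_annotation, read_sample_table
from virotrans.views import euclidean_distances, hclust_complete, linkage_to_newick, pca_scores

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    annotation = read_gene_annotation(ROOT / "data" / "genes.tsv")
    matrix = read_count_matrix(ROOT / "data" / "counts.tsv", annotation=annotation)
    samples = read_sample_table(ROOT / "data" / "samples.tsv")
    out = ROOT / "views"
    out.mkdir(parents=True, exist_ok=True)

    sf = size_factors(matrix)
    vst = pd.DataFrame(vst_like(matrix, sf), index=matrix.gene_ids, columns=matrix.samples)
    dist = euclidean_distances(vst)
    dist.to_csv(out / "sample_distances.tsv", sep="\t", index_label="sample_id")
    linkage = hclust_complete(dist)
    (out / "dendrogram.nwk").write_text(linkage_to_newick(linkage, list(dist.index)) + "\n")

    scores, var = pca_scores(vst)
    scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample_id")
    labels = samples.set_index("sample_id").loc[scores.index, "infected"].to_numpy()
    sil = silhouette_score(scores.to_numpy(), labels)
    print(f"PC1/PC2 explain {var[0]:.1%} / {var[1]:.1%} of variance")
    print(f"silhouette of infected vs uninfected on PC1:PC2 = {sil:.3f} (positive = separated)")


if __name__ == "__main__":
    main()
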