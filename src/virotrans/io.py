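"""Readers/writers for the plain-text formats the pipeline exchanges.

Count matrices travel either as a wide TSV (first column ``gene_id``,
header row of sample ids) or as a MatrixMarket triplet plus two sidecar
id lists, the usual interchange for sparse count data.  Gene-set
libraries use the GMT dialect (term TAB description TAB members...).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    HOST,
    VIRUS,
    CountMatrix,
    GeneAnnotation,
    ValidationError,
    validate_phenotype_table,
    validate_sample_table,
)


class FormatError(ValueError):
    pass


def _annotate(gene_ids: list[str], annotation: dict[str, GeneAnnotation] | None) -> list[GeneAnnotation]:
    if annotation is None:
        return [GeneAnnotation(g, HOST) for g in gene_ids]
    unknown = [g for g in gene_ids if g not in annotation]
    if unknown:
        warnings.warn(f"{len(unknown)} gene ids absent from annotation, treated as host: {unknown[:5]}")
    return [annotation.get(g, GeneAnnotation(g, HOST)) for g in gene_ids]


def read_count_matrix(
    path: str | Path,
    format: str = "tsv_wide",
    annotation: dict[str, GeneAnnotation] | None = None,
) -> CountMatrix:
    """Read a gene x sample count matrix.

    ``annotation`` maps gene_id -> :class:`GeneAnnotation`; ids not in the
    map are reported and default to host origin.
    """
    path = Path(path)
    if format == "tsv_wide":
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = df.to_numpy()
        gene_ids = [str(g) for g in df.index]
        samples = [str(s) for s in df.columns]
    elif format == "mtx_triplet":
        mat = scipy.io.mmread(path)
        counts = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        gene_ids = _read_id_list(path.with_suffix(".genes.txt"))
        samples = _read_id_list(path.with_suffix(".samples.txt"))
    else:
        raise FormatError(f"unknown count format {format!r}")
    if not np.isfinite(counts).all():
        raise FormatError(f"{path}: non-finite counts")
    if not np.allclose(counts, np.round(counts)):
        raise FormatError(f"{path}: non-integer counts (counts must be raw integers)")
    if (counts < 0).any():
        raise FormatError(f"{path}: negative counts")
    return CountMatrix(genes=_annotate(gene_ids, annotation), samples=samples, counts=counts.astype(np.int64))


def _read_id_list(path: Path) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing sidecar id list {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def write_count_matrix(matrix: CountMatrix, path: str | Path, format: str = "tsv_wide") -> None:
    path = Path(path)
    if format == "tsv_wide":
        matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx_triplet":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix.counts), field="integer")
        path.with_suffix(".genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
        path.with_suffix(".samples.txt").write_text("\n".join(matrix.samples) + "\n")
    else:
        raise FormatError(f"unknown count format {format!r}")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["infected"] = df["infected"].astype(bool)
    return validate_sample_table(df)


def write_sample_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_sample_table(df).to_csv(path, sep="\t", index=False)


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    return validate_phenotype_table(pd.read_csv(path, sep="\t"))


def write_phenotype_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_phenotype_table(df).to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read a gene annotation TSV (gene_id, origin, optional family_tag,
    genome_start, genome_end) into a gene_id -> GeneAnnotation map."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, GeneAnnotation] = {}
    for row in df.itertuples(index=False):
        start = None if pd.isna(getattr(row, "genome_start", np.nan)) else int(row.genome_start)
        end = None if pd.isna(getattr(row, "genome_end", np.nan)) else int(row.genome_end)
        tag = getattr(row, "family_tag", None)
        out[str(row.gene_id)] = GeneAnnotation(
            str(row.gene_id), str(row.origin), None if pd.isna(tag) else tag, start, end
        )
    return out


def write_gene_annotation(genes: list[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "origin": [g.origin for g in genes],
            "family_tag": [g.family_tag for g in genes],
            "genome_start": [g.genome_start for g in genes],
            "genome_end": [g.genome_end for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT gene-set library into {term: member set}.

    Duplicate members within a term are deduplicated; a duplicate term
    name or a line with fewer than three fields is an error.
    """
    library: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs term, description and >=1 member")
        term = fields[0]
        if not term:
            raise ValidationError(f"{path}:{lineno}: empty term name")
        if term in library:
            raise ValidationError(f"{path}:{lineno}: duplicate term {term!r}")
        members = {m for m in fields[2:] if m}
        if not members:
            raise FormatError(f"{path}:{lineno}: term {term!r} has no members")
        library[term] = members
    return library


def write_gmt(library: dict[str, set[str]], path: str | Path) -> None:
    lines = [
        "\t".join([term, term] + sorted(members))
        for term, members in library.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def apply_mask(matrix: CountMatrix, mask_ids: set[str]) -> CountMatrix:
    """Drop *host* genes whose id is in ``mask_ids``.

    Emulates excluding transgene-duplicated host loci from the human
    genome so construct-derived reads are attributed to the viral copy:
    viral genes are never removed (a mask id hitting a viral gene only
    warns).
    """
    mask_ids = set(mask_ids)
    keep = np.ones(len(matrix.genes), dtype=bool)
    for i, g in enumerate(matrix.genes):
        if g.gene_id in mask_ids:
            if g.origin == VIRUS:
                warnings.warn(f"mask id {g.gene_id!r} matches a viral gene; kept")
            else:
                keep[i] = False
    return matrix.subset_genes(keep)


def write_viral_track(matrix: CountMatrix, normalized: np.ndarray, path: str | Path, chrom: str = "virus") -> None:
    """Write a BED-like TSV of viral genes with mean normalized expression.

    Columns: chrom, start, end, gene_id, mean normalized count (over the
    supplied columns of ``normalized``).  Genes without coordinates are
    laid out end-to-end in 1 kb slots so the track is still plottable.
    """
    viral_idx = np.flatnonzero(matrix.is_viral())
    rows = []
    cursor = 0
    for i in viral_idx:
        g = matrix.genes[i]
        if g.genome_start is not None:
            start, end = g.genome_start, g.genome_end
        else:
            start, end = cursor, cursor + 1000
        cursor = max(cursor, end)
        rows.append((chrom, start, end, g.gene_id, float(np.mean(normalized[i, :]))))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "mean_norm_count"]).to_csv(
        path, sep="\t", index=False
    )
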