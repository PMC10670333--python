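"""Core containers for dual host+virus count data.

The pipeline tracks, for every gene, which genome it came from: human
("host") or the recombinant vaccinia construct ("virus"), whose genome is
treated as one extra chromosome.  Everything downstream — masking,
viral-fraction computation, viral-transcript ranking — relies on that
origin flag, so it lives on the count matrix itself rather than in a
side table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOST = "host"
VIRUS = "virus"


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene metadata: identity, genome of origin, optional family tag
    (e.g. ``"histone"``) and, for viral genes, 0-based half-open genome
    coordinates used by the BED-like expression-track writer."""

    gene_id: str
    origin: str
    family_tag: str | None = None
    genome_start: int | None = None
    genome_end: int | None = None

    def __post_init__(self) -> None:
        if self.origin not in (HOST, VIRUS):
            raise ValidationError(f"origin must be 'host' or 'virus', got {self.origin!r}")
        if (self.genome_start is None) != (self.genome_end is None):
            raise ValidationError(f"{self.gene_id}: both or neither genome coordinate must be set")
        if self.genome_start is not None and self.genome_end <= self.genome_start:
            raise ValidationError(f"{self.gene_id}: genome_end must exceed genome_start")


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-gene annotations.

    ``counts`` is dense int64 (genes on rows, samples on columns); the
    matrices in play are a few thousand genes by tens of samples, so
    density is not a concern.
    """

    genes: list[GeneAnnotation]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.issubdtype(self.counts.dtype, np.floating) and np.allclose(
                self.counts, np.round(self.counts)
            ):
                # integral floats from text parsing are fine; true reals are not
                self.counts = self.counts.astype(np.int64)
            else:
                raise ValidationError("counts must be integers (NB model assumes counts)")
        self.counts = self.counts.astype(np.int64)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative counts")
        # a transgene can appear as both a host and a viral gene (the mask
        # stage removes the host copy), so uniqueness is per (id, origin)
        keys = [(g.gene_id, g.origin) for g in self.genes]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate gene ids within one origin")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def origins(self) -> np.ndarray:
        return np.array([g.origin for g in self.genes])

    def is_viral(self) -> np.ndarray:
        return self.origins == VIRUS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.samples)

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CountMatrix(
            genes=[self.genes[i] for i in idx],
            samples=list(self.samples),
            counts=self.counts[idx, :],
        )

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        pos = {s: j for j, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        cols = [pos[s] for s in sample_ids]
        return CountMatrix(genes=list(self.genes), samples=list(sample_ids), counts=self.counts[:, cols])


def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the sample design table (one row per sequencing library)."""
    required = {"sample_id", "culture_id", "timepoint_h", "infected", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sample table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id")
    key = df[["culture_id", "timepoint_h", "replicate"]]
    if key.duplicated().any():
        raise ValidationError("duplicate (culture_id, timepoint_h, replicate)")
    if (df["timepoint_h"] < 0).any():
        raise ValidationError("negative timepoint")
    bad = df[(df["timepoint_h"] == 0) & df["infected"].astype(bool)]
    if len(bad):
        raise ValidationError("samples at 0 h cannot be infected")
    if (df["replicate"] < 1).any():
        raise ValidationError("replicate numbers start at 1")
    return df


def validate_phenotype_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-culture phenotype table (CD50 etc.)."""
    required = {"culture_id", "cd50_pfu_per_cell"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"phenotype table missing columns: {sorted(missing)}")
    if df["culture_id"].duplicated().any():
        raise ValidationError("duplicate culture_id")
    if (df["cd50_pfu_per_cell"] <= 0).any():
        raise ValidationError("CD50 must be positive (PFU/cell)")
    for col in ("annv_pi_minus_pct", "annv_pi_plus_pct"):
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 100)).any():
                raise ValidationError(f"{col} must lie in [0, 100]")
    return df
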