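# Methods

`virotrans` implements an integrative analysis of dual host+virus
transcriptomes from cultured human glioma and normal-brain cells
infected with an oncolytic recombinant vaccinia virus (VV-GMCSF-Lact).
Everything operates downstream of read quantification: the unit of
input is an integer gene × sample count matrix in which every gene is
flagged as originating from the human genome ("host") or from the viral
genome, which is treated as one extra chromosome.  Because real
sequencing data of this design are not bundled, a synthetic generator
with planted ground truth stands in for them; this note documents the
models, the parameters that matter, and what the synthetic results do
and do not demonstrate.

## Data model and masking

Genes carry an origin flag, an optional family tag and, for viral
genes, 0-based half-open genome coordinates used by the BED-like
expression-track writer.  A transgene (here the lactaptin-encoding CSN3
fragment and the GM-CSF gene carried by the virus) can legitimately
appear under the same symbol as both a host and a viral gene, so id
uniqueness is enforced per (id, origin) pair.  `apply_mask` removes
listed *host* genes — the standard fix for construct-duplicated loci,
ensuring construct-derived reads are attributed to the viral copy — and
never removes viral genes.  The mask list is user-supplied and defaults
to `{CSF2, CSN3}`; no particular list is hard-coded as authoritative
because the correct set depends on how the reference was built.

## Synthetic infection model

The generator emulates a seven-culture panel (four patient-derived
gliomas, two immortalized lines, one normal-brain culture) measured at
0, 12 and 24 h post-infection with 3 replicates, ~5000 host genes and
180 viral transcripts, 2·10⁶ counts per library.  Per-culture CD50
cytotoxic doses default to the published panel values (6.3·10⁻³ …
5.8 PFU/cell; the normal-brain culture is the most resistant).

**Viral load.**  Susceptibility is logistic in log CD50,
`s(c) = 1/(1+(cd50_c/κ)^h)` with κ = 0.5 PFU/cell and h = 0.6, and the
target viral fraction of the transcriptome is
`f(c,t) = f24_max · (t/24)^γ · s(c)` with `f24_max = 0.4`, γ = 1.5.
This makes viral load strictly decreasing in CD50 at fixed t > 0 —
the coupling every CD50 screen relies on — and spans roughly 7–37% of
the library at 24 h across the default panel.  Viral counts distribute
over transcripts proportionally to power-law weights `w_r ∝ r^(−1.5)`,
which fixes a known true abundance order for the rank-recovery checks.
The top 25 weights carry the names of the study's commonly expressed
viral transcripts so outputs read naturally.

**Planted host modules.**  Universal up- (histone-like) and down-
(cell-cycle-like) modules respond in every culture with effect
`±β · (t/24)^γ` in log2 units (β = 2 by default), i.e. the effect
follows the culture-normalised infection ramp `f(c,t)/f(c,24)` and
reaches exactly ±β at 24 h in every culture.  An alternative would be
to scale the effect by the culture's absolute viral load; we use the
normalised ramp deliberately so that a "universal" module is universal
— resistant cultures respond like sensitive ones at 24 h, only the
viral compartment differs.  One consequence worth knowing: at 12 h the
planted effect is β·(0.5)^1.5 ≈ 0.35β, so per-culture detection is
partial and the 7-way-common sets at 12 h are nearly empty — the same
qualitative asymmetry the real study reports between its 12 h and 24 h
universal lists.  Resistance and sensitivity modules get a *baseline*
shift `±λ·(log10 cd50_c − mean log10 cd50)` (λ = 0.6) applied at all
timepoints, including 0 h; centring keeps library composition stable
and leaves every Pearson screen invariant (correlation is unaffected
by affine transforms of the covariate).  Per-culture private modules
(30 genes, +1.5 log2) respond only in that culture's infected samples.
If the target viral fraction is identically zero (`f24_max = 0`), no
infection-response effect is applied at all — the no-virus limit is a
true null.

**Baselines and noise.**  Host baseline abundances are log-normal
(σ = 1.6 on the natural-log scale).  Planted responders are floored at
the 75th percentile of baseline abundance: the emulated gene classes
(histone clusters, ACTB/VIM-tier housekeeping genes, cell-cycle
machinery) are solidly expressed transcripts in real cells, and an
unexpressed "universal responder" would be a simulation artifact.  All
counts are negative-binomial with dispersion trend
`α(μ) = α₀ + a₁/μ`, α₀ = 0.02, a₁ = 2 — within the range typical for
replicate cell-culture RNA-seq, with realistic extra noise at low
counts.  The host mean model is not renormalised after applying
effects, so library totals equal the nominal size only up to the
planted mass (≪ 10% at default scale).

**Phenotype.**  Early-apoptosis percentages follow
`a − b·log10(cd50)` plus Gaussian noise (a = 12.6, b = 9.4, σ = 4,
clipped to [0, 100]); the line and spread reproduce the published
seven-culture panel, whose CD50 range spans three orders of magnitude
(hence the log scale).  Late apoptosis tracks early apoptosis
attenuated by 0.6.

**What the generator does not emulate:** single-cell heterogeneity,
splicing structure, batch effects, varying library depth, count
outliers, and any load-dependence of the *number* of culture-private
DEGs (private modules have fixed size, so the DEG-count-vs-load
correlation of the real data is not planted and the corresponding
statistic on synthetic data is uninformative noise).  Passing the
recovery tests therefore demonstrates correctness of the estimators
under NB sampling with known structure, not robustness to everything
real data can do.

## Normalization and differential expression

Size factors are classical median-of-ratios: reference genes are those
with strictly positive counts in every sample; each sample's factor is
the median of count/geometric-mean ratios (the median of the ratios
themselves, not of their logs — the two differ for even reference
counts).  The variance-stabilizing transform used for clustering, PCA
and screens is the monotone surrogate `log2(count/sf + 1)`; distance
and correlation analyses only need a monotone, variance-damping scale,
not the parametric VST.

Dispersion is estimated per gene by method of moments on normalized
counts, pooling within-group variances, then shrunk halfway to a least-
squares `a₀ + a₁/μ` trend fitted across genes, floored at 10⁻⁸.  This
is a deliberate simplification of empirical-Bayes dispersion machinery:
adequate for two-group designs with replicates, it degrades to the
trend alone (with a warning) when all groups are singletons.

The Wald test fits, per gene, a two-group NB GLM with log link and
log-size-factor offsets.  Because each group has its own intercept, the
per-group MLE is found by Fisher-scored Newton iterations on the group
log-mean (step clipped to ±5, tolerance 10⁻¹⁰); standard errors come
from the observed Fisher information, `z = log2FC/se`, two-sided normal
p.  Genes with zero counts in both groups are untested (NaN, excluded
from the BH denominator).  A gene with zero counts in only one group
gets a half-count floor on that group's mean — the fold change is
finite and large but the information is tiny, so the huge standard
error tempers the call; for ranking purposes the induced ordering by
the expressed group's mean is exactly what rank-averaging needs.
BH adjustment wraps `statsmodels`' step-up with NaN passthrough.
DEG thresholds default to padj < 0.05 with no fold-change floor, both
configurable.

A known property inherited from median-of-ratios: if a large,
one-directional fraction of the library is differentially expressed
(≳10–20%), normalization absorbs part of the shift and fold-change
estimates are biased toward zero by the median shift of the ratio
distribution.  Balanced effects leave the normalization centred; the
recovery tests use balanced planting for this reason.

## Cross-culture integration

Common DEGs are the plain intersection of per-culture sets (restricted
to host genes; viral transcripts are trivially "differential" versus
uninfected controls and would pollute the universal-response lists).
The unique-DEG fraction is the percentage of the union appearing in
exactly one culture.  Histone tagging is by id prefix
(`H1-, H2AC, H2BC, H3C, H4C` — the replication-dependent clusters).

Viral transcripts are ranked within each culture × timepoint contrast
by descending log2FC (average ranks on ties) and the ranks averaged
over all contrasts that contain the gene — ranking before averaging is
robust to per-contrast scale differences, and the result is invariant
to any strictly monotone within-contrast transform of the fold
changes.  All 14 contrasts (7 cultures × 2 infected timepoints) enter
the average; final ties break lexicographically for determinism.

## Correlation screens

Screens run on VST-scale expression of infected samples (both
timepoints pooled), Pearson per gene against (i) the per-sample total
viral RNA fraction or (ii) the per-culture CD50 (log10 by default —
raw-scale correlation over a 3-decade dose range is dominated by the
single most resistant culture).  Zero-variance genes are excluded and
counted.  Top-k membership (default k = 300 per direction, strict
r > 0 / r < 0, id tie-break) defines the resistance-/sensitivity-
associated candidate sets; the viral screen reports transcripts with
r > 0.5 as positively CD50-associated (by construction of the load
model there should be none) and orders the inverse correlates most
negative first.

## Enrichment

Overrepresentation uses the upper-tail hypergeometric p against each
GMT term restricted to a user-stated universe (all genes tested in the
relevant contrast — standard ORA practice), terms under 3 in-universe
members skipped, Haldane–Anscombe-corrected odds ratios, BH across
reported terms.  Rank-based enrichment statistics and combined scores
of web enrichment services are intentionally out of scope.

## Structure views

Euclidean distances on VST expression; complete-linkage agglomeration
(scipy linkage, merge heights provably non-decreasing, verified against
a brute-force oracle on small instances) with Newick export; PCA on the
500 most variable genes, gene-centred, components signed so the
largest-magnitude loading is positive (reproducible across linear-
algebra backends).

## Orchestration and reproducibility

The pipeline runs simulate → DE → integration → screens → optional
enrichment → views, writing per-stage TSVs, a JSON summary and a
SHA-256 MANIFEST.  One user seed governs all randomness; per-stage
seeds derive from it by hashing the stage name (stable, < 2³¹).  The
summary contains no timestamps, so identical config + seed reproduces
it byte-for-byte; timings live in `run.log`.

Default problem sizes (5000 host genes, 63 libraries, 14 contrasts)
were chosen so a full pipeline run takes a few seconds on one CPU while
leaving every per-gene estimate in its asymptotically sensible regime;
all validation suites run at these sizes.

## Known limitations

* The DE caller is a simplified NB Wald test: no outlier handling, no
  fold-change shrinkage, two-group designs only; it does not aim to
  reproduce any specific published DE tool's numbers.
* The dispersion trend fit is unweighted least squares; with very few
  genes the trend can be poorly determined.
* Screens treat samples as exchangeable; culture identity is not
  modelled as a covariate, so per-culture pseudo-replication inflates
  nominal screen p-values (the screens are used for ranking and
  membership, not inference).
* The apoptosis model is a single linear trend in log10 CD50; it does
  not emulate assay-specific measurement error structure.
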