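"""Synthetic dual host+virus RNA-seq generator with planted ground truth.

The generator emulates the design of the infection study downstream of
quantification: seven cultures (one normal-like, with the largest CD50)
sampled at 0/12/24 h post-infection with replicates, counts over ~5000
host genes plus a viral-gene compartment whose share of the library
grows with time and shrinks with the culture's CD50 (resistant cultures
carry less viral RNA).

Planted structure gives every downstream stage a truth table:

* a universal up-module (histone-like) and down-module (cell-cycle-like)
  responding in every culture,
* resistance / sensitivity modules whose baseline expression tracks
  log10(CD50) across cultures (positively / negatively),
* per-culture private responders,
* power-law viral-transcript abundances fixing the true rank order.

Viral load model: susceptibility ``s(c) = 1 / (1 + (cd50_c/kappa)**h)``
(logistic in log CD50) and target viral fraction
``f(c, t) = f24_max * (t/24)**gamma * s(c)``, zero at t=0.  The planted
universal/private effects scale with the culture-normalised infection
ramp ``f(c,t)/f(c,24) = (t/24)**gamma``, so a module planted at
|log2FC| = beta reaches exactly beta at 24 h in every culture — the
response is universal even though the absolute viral load is not.

All counts are negative-binomial with a mean-dispersion trend
``alpha(mu) = alpha0 + a1/mu``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import HOST, VIRUS, CountMatrix, GeneAnnotation, ValidationError

#: default seven-culture panel: (culture_id, CD50 in PFU/cell, kind);
#: CD50 values are the published phenotypes of the study's cultures.
DEFAULT_CULTURES: tuple[tuple[str, float, str], ...] = (
    ("BR1", 6.3e-3, "patient_derived"),
    ("BR3", 2.4e-2, "patient_derived"),
    ("BR4", 6.5e-1, "patient_derived"),
    ("BR5", 5.2e-1, "patient_derived"),
    ("NB", 5.8, "normal"),
    ("U87", 1.2e-1, "immortalized"),
    ("U343", 6.5e-2, "immortalized"),
)

#: top-25 commonly expressed viral transcripts (published order); they seed
#: the viral namespace so the largest planted abundances carry real names.
NAMED_VIRAL_GENES: tuple[str, ...] = (
    "E3L", "E9L", "I3L", "I4L", "B8R", "H5R", "O1L", "D1R", "F4L", "J6R",
    "A12L", "C4L", "B2R", "CSN3", "F1L", "D13L", "A3L", "D5R", "A10L",
    "A37R", "A24R", "F12L", "A46R", "A35R", "M1L",
)


class ConfigError(ValidationError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the emulated study conditions."""

    seed: int
    cultures: tuple[tuple[str, float, str], ...] = DEFAULT_CULTURES
    timepoints_h: tuple[float, ...] = (0.0, 12.0, 24.0)
    replicates: int = 3
    n_host_genes: int = 5000
    n_viral_genes: int = 180
    library_size: int = 2_000_000

    # viral-load model
    f24_max: float = 0.40
    gamma: float = 1.5
    kappa: float = 0.5
    hill: float = 0.6
    viral_powerlaw_exponent: float = 1.5

    # planted modules: (size, effect)
    universal_up_size: int = 80
    universal_up_beta: float = 2.0
    universal_down_size: int = 50
    universal_down_beta: float = 2.0
    resistance_size: int = 40
    resistance_lambda: float = 0.6
    sensitivity_size: int = 40
    sensitivity_lambda: float = 0.6
    private_size: int = 30
    private_beta: float = 1.5

    # optional named universal modules (override the sizes above)
    universal_up_ids: tuple[str, ...] | None = None
    universal_down_ids: tuple[str, ...] | None = None

    # noise
    alpha0: float = 0.02
    alpha_a1: float = 2.0
    baseline_log_sd: float = 1.6

    # apoptosis phenotype model: annv = intercept - slope * log10(cd50) + noise
    apoptosis_intercept: float = 12.6
    apoptosis_slope: float = 9.4
    apoptosis_noise_sd: float = 4.0

    def n_universal_up(self) -> int:
        return len(self.universal_up_ids) if self.universal_up_ids is not None else self.universal_up_size

    def n_universal_down(self) -> int:
        return len(self.universal_down_ids) if self.universal_down_ids is not None else self.universal_down_size

    def validate(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if any(cd50 <= 0 for _, cd50, _ in self.cultures):
            raise ConfigError("CD50 must be positive")
        sizes = [
            self.n_universal_up(),
            self.n_universal_down(),
            self.resistance_size,
            self.sensitivity_size,
            self.private_size * len(self.cultures),
        ]
        if any(s < 0 for s in sizes[:4]) or self.private_size < 0:
            raise ConfigError("module sizes must be >= 0")
        if sum(sizes) > self.n_host_genes:
            raise ConfigError("module sizes exceed n_host_genes")
        if self.universal_up_ids is not None and self.universal_down_ids is not None:
            overlap = set(self.universal_up_ids) & set(self.universal_down_ids)
            if overlap:
                raise ConfigError(f"up/down universal lists overlap: {sorted(overlap)[:5]}")


def plant_named_universal_sets(
    config: SimConfig, up_ids: list[str], down_ids: list[str]
) -> SimConfig:
    """Return a config whose universal modules are exactly the given ids
    (e.g. the study's printed universal-response gene lists)."""
    overlap = set(up_ids) & set(down_ids)
    if overlap:
        raise ConfigError(f"up/down lists overlap: {sorted(overlap)[:5]}")
    return replace(config, universal_up_ids=tuple(up_ids), universal_down_ids=tuple(down_ids))


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a simulated dataset."""

    gene_module: pd.Series  # gene_id -> module label
    target_viral_fraction: pd.Series  # sample_id -> f(c, t)
    host_baseline: pd.Series  # gene_id -> baseline relative abundance p_i (sums to 1)
    planted_effects: pd.DataFrame  # gene_id, culture_id, timepoint_h, log2fc (infection response)
    baseline_shifts: pd.DataFrame  # gene_id, culture_id, log2_shift (resistance/sensitivity)
    viral_weights: pd.Series  # viral gene_id -> relative abundance weight
    viral_rank_order: list[str]  # viral gene ids, descending true abundance


def susceptibility(cd50: np.ndarray | float, kappa: float, hill: float) -> np.ndarray | float:
    """Logistic-in-log-CD50 susceptibility in (0, 1); lower CD50 => higher."""
    return 1.0 / (1.0 + (np.asarray(cd50, dtype=float) / kappa) ** hill)


def target_viral_fraction(cd50: float, t: float, cfg: SimConfig) -> float:
    if t <= 0:
        return 0.0
    return cfg.f24_max * (t / 24.0) ** cfg.gamma * float(susceptibility(cd50, cfg.kappa, cfg.hill))


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Draw NB2 counts with mean mu and dispersion alpha (var = mu + alpha mu^2)."""
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        n = 1.0 / np.maximum(alpha[pos], 1e-12)
        p = n / (n + mu[pos])
        out[pos] = rng.negative_binomial(n, p)
    return out


def simulate(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (counts, sample table, phenotype table, truth). Deterministic in seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cultures = list(config.cultures)
    cd50 = {c: v for c, v, _ in cultures}
    log_cd50 = {c: math.log10(v) for c, v, _ in cultures}
    mean_log_cd50 = float(np.mean(list(log_cd50.values())))

    # --- gene namespace and module assignment -------------------------------
    n_up = config.n_universal_up()
    n_down = config.n_universal_down()
    host_ids = [f"HG{i + 1:05d}" for i in range(config.n_host_genes)]
    cursor = 0

    def take(n: int) -> list[int]:
        nonlocal cursor
        idx = list(range(cursor, cursor + n))
        cursor += n
        return idx

    up_idx = take(n_up)
    down_idx = take(n_down)
    res_idx = take(config.resistance_size)
    sen_idx = take(config.sensitivity_size)
    private_idx = {c: take(config.private_size) for c, _, _ in cultures}

    if config.universal_up_ids is not None:
        for i, g in zip(up_idx, config.universal_up_ids):
            host_ids[i] = g
    if config.universal_down_ids is not None:
        for i, g in zip(down_idx, config.universal_down_ids):
            host_ids[i] = g

    module = pd.Series("null", index=host_ids, dtype=object)
    module.iloc[up_idx] = "universal_up"
    module.iloc[down_idx] = "universal_down"
    module.iloc[res_idx] = "resistance"
    module.iloc[sen_idx] = "sensitivity"
    for c, idx in private_idx.items():
        module.iloc[idx] = f"private:{c}"

    viral_ids = list(NAMED_VIRAL_GENES[: config.n_viral_genes])
    viral_ids += [f"VACV{i + 1:03d}" for i in range(len(viral_ids), config.n_viral_genes)]

    # --- baselines and viral weights ---------------------------------------
    base = rng.lognormal(mean=0.0, sigma=config.baseline_log_sd, size=config.n_host_genes)
    planted = np.zeros(config.n_host_genes, dtype=bool)
    planted[up_idx + down_idx + res_idx + sen_idx + [i for v in private_idx.values() for i in v]] = True
    if planted.any():
        # planted responders emulate histone / housekeeping-tier genes
        # (ACTB, VIM, histone clusters...), which sit in the upper
        # expression quartile in real cells: floor their baseline there
        base[planted] = np.maximum(base[planted], np.quantile(base, 0.75))
    p = base / base.sum()

    if config.n_viral_genes > 0:
        ranks = np.arange(1, config.n_viral_genes + 1, dtype=float)
        w = ranks ** (-config.viral_powerlaw_exponent)
        w /= w.sum()
    else:
        w = np.zeros(0)
    viral_weights = pd.Series(w, index=viral_ids)
    viral_rank_order = list(viral_weights.sort_values(ascending=False, kind="stable").index)

    # --- sample design ------------------------------------------------------
    rows = []
    for c, _, _ in cultures:
        for t in config.timepoints_h:
            for r in range(1, config.replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{c}_T{int(t):02d}_R{r}",
                        "culture_id": c,
                        "timepoint_h": float(t),
                        "infected": t > 0,
                        "replicate": r,
                    }
                )
    samples = pd.DataFrame(rows)
    t_max = max(config.timepoints_h)

    # --- expected counts ----------------------------------------------------
    n_genes = config.n_host_genes + config.n_viral_genes
    mu = np.zeros((n_genes, len(samples)))
    f_target = np.zeros(len(samples))
    effects_rows = []
    shift_rows = []
    ramp = {t: (t / t_max) ** config.gamma if t > 0 else 0.0 for t in config.timepoints_h}

    shift = np.zeros((config.n_host_genes, len(cultures)))
    for jc, (c, v, _) in enumerate(cultures):
        centred = log_cd50[c] - mean_log_cd50
        shift[res_idx, jc] = config.resistance_lambda * centred
        shift[sen_idx, jc] = -config.sensitivity_lambda * centred
        for i in res_idx:
            shift_rows.append((host_ids[i], c, config.resistance_lambda * centred))
        for i in sen_idx:
            shift_rows.append((host_ids[i], c, -config.sensitivity_lambda * centred))

    for j, row in samples.iterrows():
        c = row["culture_id"]
        jc = [k for k, (cc, _, _) in enumerate(cultures) if cc == c][0]
        t = row["timepoint_h"]
        f = target_viral_fraction(cd50[c], t, config)
        f_target[j] = f
        eff = shift[:, jc].copy()  # baseline resistance/sensitivity shift, all timepoints
        if row["infected"] and f > 0:  # f == 0 means no virus ever reaches the cells
            r_t = ramp[t]
            eff[up_idx] += config.universal_up_beta * r_t
            eff[down_idx] -= config.universal_down_beta * r_t
            eff[private_idx[c]] += config.private_beta
        mu[: config.n_host_genes, j] = config.library_size * (1.0 - f) * p * np.exp2(eff)
        if config.n_viral_genes > 0:
            mu[config.n_host_genes :, j] = config.library_size * f * w

    for c, _, _ in cultures:
        for t in config.timepoints_h:
            if t <= 0 or target_viral_fraction(cd50[c], t, config) <= 0:
                continue
            r_t = ramp[t]
            for i in up_idx:
                effects_rows.append((host_ids[i], c, t, config.universal_up_beta * r_t))
            for i in down_idx:
                effects_rows.append((host_ids[i], c, t, -config.universal_down_beta * r_t))
            for i in private_idx[c]:
                effects_rows.append((host_ids[i], c, t, config.private_beta))

    alpha = config.alpha0 + config.alpha_a1 / np.maximum(mu, 1e-8)
    counts = _nb_sample(rng, mu, alpha)

    genes = [GeneAnnotation(g, HOST) for g in host_ids]
    span = 1000
    genes += [
        GeneAnnotation(g, VIRUS, genome_start=i * span, genome_end=(i + 1) * span)
        for i, g in enumerate(viral_ids)
    ]
    matrix = CountMatrix(genes=genes, samples=samples["sample_id"].tolist(), counts=counts)

    # --- phenotype ----------------------------------------------------------
    pheno_rows = []
    for c, v, kind in cultures:
        annv_m = config.apoptosis_intercept - config.apoptosis_slope * log_cd50[c]
        annv_p = 0.6 * annv_m  # late apoptosis tracks early apoptosis, attenuated
        noise = rng.normal(0.0, config.apoptosis_noise_sd, size=2)
        pheno_rows.append(
            {
                "culture_id": c,
                "cd50_pfu_per_cell": v,
                "annv_pi_minus_pct": float(np.clip(annv_m + noise[0], 0.0, 100.0)),
                "annv_pi_plus_pct": float(np.clip(annv_p + noise[1], 0.0, 100.0)),
                "cell_index": float(np.round(rng.lognormal(0.8, 0.9), 2)),
                "culture_kind": kind,
            }
        )
    phenotype = pd.DataFrame(pheno_rows)

    all_module = pd.concat([module, pd.Series("viral", index=viral_ids, dtype=object)])
    truth = SyntheticTruth(
        gene_module=all_module,
        target_viral_fraction=pd.Series(f_target, index=samples["sample_id"].tolist()),
        host_baseline=pd.Series(p, index=host_ids),
        planted_effects=pd.DataFrame(effects_rows, columns=["gene_id", "culture_id", "timepoint_h", "log2fc"]),
        baseline_shifts=pd.DataFrame(shift_rows, columns=["gene_id", "culture_id", "log2_shift"]),
        viral_weights=viral_weights,
        viral_rank_order=viral_rank_order,
    )
    return matrix, samples, phenotype, truth
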