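"""End-to-end orchestration: simulate -> normalize/DE -> cross-culture
response -> correlation screens -> (optional) enrichment -> structure
views, with a machine-readable JSON summary and a checksummed MANIFEST.

One seed governs every stochastic stage; stage seeds are derived from it
by hashing the stage name, so adding a stage never perturbs the others.
Identical config + seed reproduces the summary byte-for-byte (the
summary carries no timestamps; timings go to run.log).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import CountMatrix
from .de import contrast_by_timepoint, size_factors, vst_like
from .enrich import fisher_ora
from .io import read_gmt, write_count_matrix, write_phenotype_table, write_sample_table, write_viral_track
from .response import (
    common_degs,
    deg_count_load_correlation,
    rank_viral_transcripts,
    tag_gene_family,
    unique_deg_fraction,
    viral_fraction,
)
from .screens import (
    apoptosis_cd50_summary,
    cd50_covariate,
    gene_covariate_screen,
    top_k_split,
    viral_cd50_screen,
)
from .simulate import SimConfig, simulate
from .views import euclidean_distances, hclust_complete, linkage_to_newick, pca_scores

log = logging.getLogger("virotrans")


def derive_seed(seed: int, stage: str) -> int:
    """Stage-keyed seed below 2**31, stable across runs and platforms."""
    return (int(seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


def _config_hash(config: SimConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    config: SimConfig,
    outdir: str | Path,
    alpha_fdr: float = 0.05,
    lfc_min: float = 0.0,
    top_k: int = 300,
    gmt_path: str | Path | None = None,
) -> dict:
    """Run every stage on a simulated dataset and write the report bundle.

    Returns the summary dict (also written as ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    log.addHandler(handler)
    t0 = time.time()

    summary: dict = {
        "tool": "virotrans",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
    }
    try:
        # --- simulate -------------------------------------------------------
        config = dataclasses.replace(config, seed=derive_seed(config.seed, "simulate"))
        matrix, samples, phenotype, truth = simulate(config)
        log.info("simulated %d genes x %d samples (%.1fs)", *matrix.counts.shape, time.time() - t0)
        write_count_matrix(matrix, outdir / "counts.tsv")
        write_sample_table(samples, outdir / "samples.tsv")
        write_phenotype_table(phenotype, outdir / "phenotype.tsv")
        truth.gene_module.rename("module").to_csv(outdir / "truth_modules.tsv", sep="\t", index_label="gene_id")

        # --- normalize / DE --------------------------------------------------
        sf = size_factors(matrix)
        vst = pd.DataFrame(vst_like(matrix, sf), index=matrix.gene_ids, columns=matrix.samples)
        contrasts: dict[tuple[str, float], pd.DataFrame] = {}
        deg_sets: dict[tuple[str, float, str], object] = {}
        cultures = [c for c, _, _ in config.cultures]
        timepoints = [t for t in config.timepoints_h if t > 0]
        host_genes = frozenset(np.array(matrix.gene_ids)[~matrix.is_viral()])
        for c in cultures:
            for t in timepoints:
                res, up, down = contrast_by_timepoint(matrix, samples, c, t, alpha_fdr, lfc_min)
                contrasts[(c, t)] = res
                # DEG bookkeeping concerns the *host* response; viral genes
                # stay in the contrast tables for rank-averaging
                deg_sets[(c, t, "up")] = dataclasses.replace(up, genes=up.genes & host_genes)
                deg_sets[(c, t, "down")] = dataclasses.replace(down, genes=down.genes & host_genes)
                res.to_csv(outdir / f"de_{c}_{int(t)}h.tsv", sep="\t", index_label="gene_id")
        summary["deg_counts"] = {
            f"{c}_{int(t)}h": {
                "up": len(deg_sets[(c, t, "up")].genes),
                "down": len(deg_sets[(c, t, "down")].genes),
            }
            for c in cultures
            for t in timepoints
        }
        log.info("DE done over %d contrasts (%.1fs)", len(contrasts), time.time() - t0)

        # --- cross-culture response -----------------------------------------
        frac = viral_fraction(matrix)
        frac.rename("viral_fraction").to_csv(outdir / "viral_fraction.tsv", sep="\t", index_label="sample_id")
        summary["viral_fraction"] = {k: round(float(v), 6) for k, v in frac.items()}
        resp: dict = {}
        for t in timepoints:
            for direction in ("up", "down"):
                sets = [deg_sets[(c, t, direction)] for c in cultures]
                common = sorted(common_degs(sets, direction))
                resp[f"common_{direction}_{int(t)}h"] = common
                resp[f"n_common_{direction}_{int(t)}h"] = len(common)
                resp[f"unique_pct_{direction}_{int(t)}h"] = round(unique_deg_fraction(sets, direction), 4)
                resp[f"histone_common_{direction}_{int(t)}h"] = sorted(tag_gene_family(set(common)))
        summary["response"] = resp

        t_last = max(timepoints)
        deg_totals = pd.Series(
            {
                c: len(deg_sets[(c, t_last, "up")].genes) + len(deg_sets[(c, t_last, "down")].genes)
                for c in cultures
            }
        )
        infected = samples[samples["infected"]]
        load_by_culture = frac.loc[infected["sample_id"]].groupby(infected["culture_id"].to_numpy()).mean()
        r_load, r2_load = deg_count_load_correlation(deg_totals, load_by_culture)
        summary["deg_count_vs_load"] = {"r": round(r_load, 6), "r2": round(r2_load, 6)}

        viral_ids = [g.gene_id for g in matrix.genes if g.origin == "virus"]
        rank_table, top25 = rank_viral_transcripts(contrasts, viral_ids, top_n=25)
        rank_table.to_csv(outdir / "viral_rank_table.tsv", sep="\t", index_label="viral_gene")
        summary["viral_top25"] = top25
        norm = matrix.counts / sf[np.newaxis, :]
        write_viral_track(matrix, norm, outdir / "viral_track.bed.tsv")

        # --- correlation screens --------------------------------------------
        inf_ids = infected["sample_id"].tolist()
        expr_inf = vst[inf_ids]
        host_mask = ~matrix.is_viral()
        host_expr = expr_inf.loc[np.array(matrix.gene_ids)[host_mask]]
        viral_expr = expr_inf.loc[viral_ids]

        load_screen = gene_covariate_screen(host_expr, frac.loc[inf_ids])
        load_screen.to_csv(outdir / "screen_viral_load.tsv", sep="\t", index_label="gene_id")
        pos_load, neg_load = top_k_split(load_screen, k=top_k)

        cd50_cov = cd50_covariate(samples, phenotype).loc[inf_ids]
        cd50_screen = gene_covariate_screen(host_expr, cd50_cov)
        cd50_screen.to_csv(outdir / "screen_cd50.tsv", sep="\t", index_label="gene_id")
        pos_cd50, neg_cd50 = top_k_split(cd50_screen, k=top_k)

        viral_pos, viral_neg = viral_cd50_screen(viral_expr, cd50_cov)
        summary["screens"] = {
            "top_k": top_k,
            "viral_load_positive": pos_load,
            "viral_load_negative": neg_load,
            "cd50_positive": pos_cd50,
            "cd50_negative": neg_cd50,
            "viral_cd50_positive": viral_pos,
            "viral_cd50_negative_order": viral_neg,
        }
        summary["apoptosis_cd50"] = {
            k: {kk: round(vv, 6) for kk, vv in v.items()} for k, v in apoptosis_cd50_summary(phenotype).items()
        }

        # --- enrichment -----------------------------------------------------
        if gmt_path is not None:
            library = read_gmt(gmt_path)
            universe = set(contrasts[(cultures[0], t_last)].index[contrasts[(cultures[0], t_last)]["tested"]])
            enr = {}
            for direction in ("up", "down"):
                query = set(resp[f"common_{direction}_{int(t_last)}h"]) & universe
                table = fisher_ora(query, universe, library)
                table.to_csv(outdir / f"enrichment_common_{direction}.tsv", sep="\t", index=False)
                enr[direction] = table.head(10)[["term", "k", "p", "q"]].to_dict(orient="records")
            summary["enrichment"] = enr

        # --- structure views ------------------------------------------------
        dist = euclidean_distances(vst)
        dist.to_csv(outdir / "sample_distances.tsv", sep="\t", index_label="sample_id")
        linkage = hclust_complete(dist)
        (outdir / "dendrogram.nwk").write_text(linkage_to_newick(linkage, list(dist.index)) + "\n")
        scores, var_explained = pca_scores(vst)
        scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index_label="sample_id")
        summary["pca_variance_explained"] = [round(float(v), 6) for v in var_explained]
    except Exception as err:  # partial outputs stay behind with an incomplete MANIFEST
        _write_manifest(outdir, complete=False, note=f"aborted: {err}")
        log.removeHandler(handler)
        raise

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    _write_manifest(outdir, complete=True)
    log.info("pipeline complete (%.1fs)", time.time() - t0)
    log.removeHandler(handler)
    handler.close()
    return summary


def _write_manifest(outdir: Path, complete: bool, note: str = "") -> None:
    lines = [f"# complete: {complete}"]
    if note:
        lines.append(f"# {note}")
    for p in sorted(outdir.iterdir()):
        if p.name in ("MANIFEST", "run.log") or p.is_dir():
            continue
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        lines.append(f"{digest}  {p.name}")
    (outdir / "MANIFEST").write_text("\n".join(lines) + "\n")
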