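"""End-to-end synthetic pipeline: simulate, score, characterise, report.

``PipelineConfig`` collects every tunable threshold; ``run_pipeline``
executes the stages in dependency order and writes one artifact per stage
into the output directory, along with a resolved-config snapshot so any
stage can be re-run from prior outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, conservation, enrichment, linkage, motif, scoring, topology
from .io import (
    config_hash,
    write_exon_bed,
    write_fasta,
    write_reads_tsv,
    write_site_table,
    write_true_sites,
)
from .simulate import (
    SimParams,
    plant_m6a_sites,
    simulate_de_table,
    simulate_glori_reads,
    simulate_homologs,
    simulate_transcriptome,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Resolved configuration for a full synthetic run."""

    sim: SimParams = field(default_factory=SimParams)
    # scoring
    min_reads_per_transcript: int = 10
    max_read_span: int = 700
    min_count: int = 10
    min_score: float = 0.1
    alpha: float = 0.05
    replicate_support: int = 1
    # linkage
    max_gap: int = 40
    score_lo: float = 0.4
    score_hi: float = 0.7
    min_spanning: int = 10
    # motif model
    model_min_cov: float = 40.0
    test_frac: float = 0.2
    top_frac: float = 0.01
    coherent_cut: float = 0.8
    low_cut: float = 0.1
    # conservation
    max_hamming: int = 3
    homolog_sub_rate_AT: float = 0.05
    homolog_sub_rate_CG: float = 0.15
    n_species: int = 2
    # enrichment
    min_basemean: float = 200.0
    n_bins: int = 10
    bootstrap_frac: float = 0.8
    n_iter: int = 1000
    de_frac_m6a: float = 0.3
    de_effect: float = 0.15
    de_n_genes: int = 4000
    # stage toggles
    run_linkage: bool = True
    run_motif: bool = True
    run_conservation: bool = True
    run_enrichment: bool = True


def load_config(path: str | Path) -> PipelineConfig:
    """YAML -> PipelineConfig; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("sim", {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim_known = {f.name for f in dataclasses.fields(SimParams)}
    sim_unknown = set(sim_raw) - sim_known
    if sim_unknown:
        raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
    for key in ("length_range", "exon_count_range", "stoich_high", "stoich_mid"):
        if key in sim_raw:
            sim_raw[key] = tuple(sim_raw[key])
    if "seed" not in sim_raw:
        raise ValueError("sim.seed is required in the config file")
    return PipelineConfig(sim=SimParams(**sim_raw), **raw)


def _dump_config(cfg: PipelineConfig, outdir: Path) -> str:
    d = dataclasses.asdict(cfg)
    h = config_hash(d)
    d["_version"] = __version__
    d["_config_hash"] = h
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
    return h


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run all enabled stages on synthetic data; returns a summary dict
    (also written to ``summary.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = _dump_config(cfg, outdir)
    summary: dict = {"version": __version__, "config_hash": h}

    # --- simulate -----------------------------------------------------
    transcripts = simulate_transcriptome(cfg.sim)
    sites_true = plant_m6a_sites(transcripts, cfg.sim)
    treated, untreated = simulate_glori_reads(transcripts, sites_true, cfg.sim)
    write_fasta({t.gene_id: t.sequence for t in transcripts}, outdir / "transcripts.fasta")
    write_exon_bed(transcripts, outdir / "exons.bed")
    write_true_sites(sites_true, outdir / "true_sites.tsv")
    write_reads_tsv(treated, outdir / "reads_treated.tsv")
    if untreated is not None:
        write_reads_tsv(untreated, outdir / "reads_input.tsv")
    summary["n_transcripts"] = len(transcripts)
    summary["n_true_sites"] = len(sites_true)

    # --- score --------------------------------------------------------
    counts = scoring.pileup_counts(
        treated,
        transcripts,
        min_reads_per_transcript=cfg.min_reads_per_transcript,
        max_read_span=cfg.max_read_span,
    )
    backgrounds = {
        s: scoring.estimate_background(per_gene, transcripts)
        for s, per_gene in counts.items()
    }
    calls = scoring.call_sites(
        counts,
        transcripts,
        backgrounds,
        min_score=cfg.min_score,
        min_count=cfg.min_count,
        alpha=cfg.alpha,
        replicate_support=cfg.replicate_support,
    )
    condition_map = {s: s.rsplit("_rep", 1)[0] for s in counts}
    site_df = scoring.aggregate_conditions(calls, condition_map)
    full_df = scoring.site_calls_to_frame(calls)
    write_site_table(full_df, outdir / "sites.tsv", cfg_hash=h)
    summary["n_called_sites"] = len(site_df)
    summary["backgrounds"] = {k: float(v) for k, v in backgrounds.items()}
    summary["cutoff_counts"] = site_df.attrs.get("cutoff_counts", {})

    if site_df.empty:
        log.warning("no sites called; downstream stages skipped")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        return summary

    # --- topology -----------------------------------------------------
    prof = topology.metagene(site_df, transcripts)
    spacing = topology.nearest_secondary_spacing(site_df)
    r, p, n_pairs = topology.adjacent_score_correlation(site_df, max_gap=cfg.max_gap)
    sbb = topology.score_by_bin(site_df, transcripts)
    topo = {
        "bin_counts": prof.bin_counts.tolist(),
        "median_spacing": spacing.median_distance,
        "adjacent_score_r": r,
        "adjacent_score_p": p,
        "n_adjacent_pairs": n_pairs,
        "bin10_vs_rest_t": sbb["t_stat"],
        "bin10_vs_rest_p": sbb["p_value"],
    }
    with open(outdir / "topology.json", "w") as fh:
        json.dump(topo, fh, indent=2)
    summary["topology"] = topo

    # --- linkage ------------------------------------------------------
    if cfg.run_linkage:
        pairs = linkage.select_pairs(
            site_df, max_gap=cfg.max_gap, score_lo=cfg.score_lo, score_hi=cfg.score_hi
        )
        surv = linkage.linkage_survey(pairs, treated, min_spanning=cfg.min_spanning)
        surv.to_csv(outdir / "linkage.tsv", sep="\t", index=False)
        summary["linkage"] = {
            "n_candidate_pairs": len(pairs),
            "n_tested": surv.attrs["n_tested"],
            "frac_p_lt_05": surv.attrs["frac_p_lt_05"],
            "ks_stat": surv.attrs["ks_stat"],
        }

    # --- motif model --------------------------------------------------
    if cfg.run_motif:
        cmx = motif.build_context_matrix(site_df, transcripts)
        logo = motif.logo_matrix(cmx.contexts)
        logo.to_csv(outdir / "logo_matrix.tsv", sep="\t", index=False)
        comp = motif.plus1_composition(site_df)
        comp.to_csv(outdir / "plus1_composition.tsv", sep="\t", index=False)
        try:
            report = motif.fit_score_model(
                cmx,
                min_cov=cfg.model_min_cov,
                test_frac=cfg.test_frac,
                seed=cfg.sim.seed,
            )
            contrast = motif.predicted_vs_observed_contrast(
                report, cmx, top_frac=cfg.top_frac, hi=cfg.coherent_cut, lo=cfg.low_cut
            )
            summary["motif_model"] = {
                "r2_test": report.r2_test,
                "mse_test": report.mse_test,
                "top_importance_offset": int(
                    np.argmax(report.importance_by_position()) - motif.FLANK
                ),
                "median_eij_coherent": contrast["median_eij_coherent"],
                "median_eij_low": contrast["median_eij_low"],
            }
        except ValueError as e:
            log.warning("score model skipped: %s", e)
            summary["motif_model"] = {"skipped": str(e)}

    # --- conservation -------------------------------------------------
    if cfg.run_conservation:
        contexts = {
            f"{r.gene_id}:{r.position}": r.context13
            for r in site_df.itertuples(index=False)
        }
        homolog_sets = {}
        for sp in range(cfg.n_species):
            homolog_sets[f"species{sp + 1}"] = simulate_homologs(
                transcripts,
                cfg.homolog_sub_rate_AT,
                cfg.homolog_sub_rate_CG,
                seed=cfg.sim.seed + 100 + sp,
            )
        matches = conservation.scan_sites(
            contexts, homolog_sets, max_hamming=cfg.max_hamming
        )
        retained = [m for m in matches if m.retained]
        summary["conservation"] = {
            "n_matches": len(matches),
            "n_retained": len(retained),
        }
        if len(retained) >= 30:
            pos = conservation.positional_conservation(matches)
            pos.to_csv(outdir / "conservation_positional.tsv", sep="\t", index=False)
            ref = {k: v for k, v in contexts.items()}
            sub = conservation.substitution_by_class(matches, ref)
            sub.to_csv(outdir / "conservation_by_class.tsv", sep="\t", index=False)

    # --- enrichment ---------------------------------------------------
    if cfg.run_enrichment:
        de = simulate_de_table(
            cfg.de_n_genes, cfg.de_frac_m6a, cfg.de_effect, seed=cfg.sim.seed
        )
        de.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
        boot = enrichment.expression_matched_bootstrap(
            de,
            min_basemean=cfg.min_basemean,
            alpha=cfg.alpha,
            n_bins=cfg.n_bins,
            frac=cfg.bootstrap_frac,
            n_iter=cfg.n_iter,
            seed=cfg.sim.seed,
        )
        summary["enrichment"] = {
            "observed_diff": boot.observed_diff,
            "p_value": boot.p_value,
            "ci": list(boot.ci),
            "matching_quality": boot.matching_quality,
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
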