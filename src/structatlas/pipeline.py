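"""End-to-end orchestration of the synthetic-atlas analysis.

Runs the stages in order - simulate, annotate, expression stats, region
sweep, correlation pairs, modules, motif scan, interaction scan - on one
config with fixed per-stage seeds, and writes tidy outputs plus a manifest
(seeds, per-stage counts) into the output directory.  Every stage is a thin
wrapper over the library modules so the same computations are importable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import annotation, conet, expression, interaction, io, motifs, robust_stats
from .synthetic import (SyntheticConfig, simulate_expression, simulate_genome,
                        simulate_interaction_pairs, simulate_ontology)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "annotate", "expression_stats", "region_sweep",
          "correlate", "modules", "motifs", "interact")


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    granularity: str = "coarse"          # region level for the sweep
    alpha: float = 0.25                  # BH-adjusted significance level
    gamma: float = 0.2                   # trimming fraction
    n_boot: int = 500
    e_min: float = 2.0                   # Eq.-1 energy threshold
    rho_thresholds: dict[str, float] = field(
        default_factory=lambda: {"brain": 0.85, "spatial": 0.9, "ncrna": 0.8})
    n_shuffles: int = 30                 # interaction/motif background size
    evd_bins: tuple[int, int] = (3, 3)   # (length, GC) bins at desk scale
    censor_cutoff: float = -10.0
    min_per_bin: int = 50
    filters: dict[str, float] = field(
        default_factory=lambda: {"min_len": 9, "max_mfe": -40.0,
                                 "max_p": 1e-5})
    module_cut_k: int | None = None

    def stage_seed(self, stage: str) -> int:
        return int(np.random.SeedSequence(
            [self.synthetic.seed, STAGES.index(stage) + 10]
        ).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk).

    A stage failure aborts with the stage name; outputs of completed stages
    (and the manifest listing them) stay on disk.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seeds": {}, "counts": {},
                      "config": {"alpha": config.alpha, "gamma": config.gamma,
                                 "e_min": config.e_min,
                                 "rho_thresholds": config.rho_thresholds,
                                 "filters": config.filters,
                                 "seed": config.synthetic.seed}}
    try:
        _run_stages(config, out, manifest)
    except Exception as err:
        _write_manifest(out, manifest)
        n = len(manifest["stages"])
        stage = STAGES[n] if n < len(STAGES) else "finalize"
        raise RuntimeError(f"pipeline aborted at stage {stage!r}: {err}") from err
    return manifest


def _run_stages(config: PipelineConfig, out: Path, manifest: dict) -> None:
    scfg = config.synthetic

    def done(stage, **counts):
        manifest["stages"].append(stage)
        manifest["seeds"][stage] = config.stage_seed(stage)
        manifest["counts"][stage] = counts
        logger.info("stage %s done: %s", stage, counts)
        _write_manifest(out, manifest)

    # -- simulate ----------------------------------------------------
    ontology = simulate_ontology(scfg)
    volumes, expr_manifest = simulate_expression(scfg, ontology)
    genes, probe_recs, structures, sequences, genome_truth = simulate_genome(scfg)
    pairs = simulate_interaction_pairs(scfg)
    io.write_ontology_json(out / "ontology.json", ontology)
    io.write_voxel_tsv(out / "voxels.tsv", volumes)
    io.write_gene_parts_bed(out / "gene_parts.bed", genes)
    io.write_bed(out / "probes.bed",
                 [(p["interval"], p["probe_id"]) for p in probe_recs])
    io.write_structures_bed(out / "structures.bed", structures)
    io.write_fasta(out / "transcripts.fa", sequences)
    io.write_fasta(out / "pairs_query.fa",
                   {p["query_id"]: p["query_seq"] for p in pairs})
    io.write_fasta(out / "pairs_target.fa",
                   {p["target_id"]: p["target_seq"] for p in pairs})
    (out / "ground_truth.json").write_text(json.dumps(
        {"genome": genome_truth, "expression": {
            "groups": expr_manifest["groups"],
            "cliques": expr_manifest["cliques"]}}, indent=1, default=str))
    done("simulate", probes=len(probe_recs), volumes=len(volumes),
         genes=len(genes), structures=len(structures),
         interaction_pairs=len(pairs))

    # -- annotate ----------------------------------------------------
    classified = []
    for p in probe_recs:
        rec = annotation.ProbeRecord(p["probe_id"], p["interval"])
        rec.classes = annotation.classify_probe(p["interval"], genes)
        annotation.map_structures(rec, structures, genes)
        seq = sequences[p["probe_id"]]
        rec.coding_potential = (len(seq) >= 3
                                and annotation.coding_potential(seq))
        classified.append(rec)
    io.write_probe_table(out / "probe_table.tsv", classified)
    class_counts = {}
    for rec in classified:
        for c in sorted(rec.classes) or ["unclassified"]:
            key = f"{'structured' if rec.structured else 'unstructured'}_{c}"
            class_counts[key] = class_counts.get(key, 0) + 1
    pd.Series(class_counts, name="n").rename_axis("category").to_csv(
        out / "classification_counts.tsv", sep="\t")
    done("annotate", classified=len(classified), **class_counts)

    # -- expression stats --------------------------------------------
    level = "fine" if config.granularity == "fine" else "coarse"
    fine_means = expression.region_mean_table(volumes, ontology, level="fine")
    sweep_means = (fine_means if level == "fine"
                   else expression.region_mean_table(volumes, ontology,
                                                     level="coarse"))
    fine_means.rename_axis("probe_id").to_csv(out / "region_means_fine.tsv",
                                              sep="\t")
    groups = expr_manifest["groups"]
    summary = []
    for pid in fine_means.index:
        v = next(v for v in volumes if v.probe_id == pid)
        summary.append({
            "probe_id": pid, "group": groups[pid],
            "brain_mean": float(v.energy[ontology.mask("brain")].mean()),
            "spatial_divergence": expression.spatial_divergence(
                fine_means.loc[pid].to_numpy()),
        })
    pd.DataFrame(summary).to_csv(out / "expression_summary.tsv", sep="\t",
                                 index=False)
    done("expression_stats", probes=len(summary),
         regions=sweep_means.shape[1])

    # -- region sweep: structured vs unstructured UTR groups ----------
    a_ids = [p for p, g in groups.items() if g == "utr_structured"]
    b_ids = [p for p, g in groups.items() if g == "utr_unstructured"]
    sweep = robust_stats.region_sweep(
        sweep_means.loc[a_ids], sweep_means.loc[b_ids], alpha=config.alpha,
        gamma=config.gamma, B=config.n_boot,
        seed=config.stage_seed("region_sweep"))
    sweep.to_csv(out / "region_sweep.tsv", sep="\t", index=False)
    done("region_sweep", regions=len(sweep),
         significant=int(sweep["significant"].sum()) if len(sweep) else 0)

    # -- correlation pairs + network ----------------------------------
    cpairs = conet.correlate_pairs(volumes, ontology, "brain")
    io.write_edges_tsv(out / "correlation_pairs.tsv", cpairs)
    rho_t = config.rho_thresholds["brain"]
    g, comps, cliques = conet.build_network(cpairs, rho_t)
    nx.write_graphml(g, out / "network.graphml")
    (out / "network.json").write_text(json.dumps({
        "rho_threshold": rho_t,
        "edges": [[u, v, d["rho"]] for u, v, d in g.edges(data=True)],
        "components": [sorted(c) for c in comps],
        "cliques": cliques}, indent=1))
    done("correlate", pairs=len(cpairs), edges=g.number_of_edges(),
         components=len(comps), cliques=len(cliques))

    # -- modules ------------------------------------------------------
    utr_structured = [p for p in fine_means.index
                      if groups[p] == "utr_structured"]
    modules = conet.detect_modules(fine_means.loc[utr_structured],
                                   cut_k=config.module_cut_k)
    (out / "modules.json").write_text(json.dumps(
        [dataclasses.asdict(m) for m in modules], indent=1, default=int))
    done("modules", modules=len(modules))

    # -- motifs -------------------------------------------------------
    rng = np.random.default_rng(config.stage_seed("motifs"))
    pwms = [_random_pwm(f"PWM{k}", rng) for k in range(3)]
    utr_seqs = [sequences[g.gene_id] for g in genes]
    motif_rows = []
    for pwm in pwms:
        p = motifs.motif_enrichment(utr_seqs, pwm,
                                    n_shuffles=config.n_shuffles,
                                    seed=config.stage_seed("motifs"))
        n_hits = sum(len(motifs.pwm_scan(s, pwm)) for s in utr_seqs
                     if len(s) >= len(pwm))
        motif_rows.append({"pwm_id": pwm.id, "n_hits": n_hits, "p": p})
    mdf = pd.DataFrame(motif_rows)
    mdf["p_adj"] = robust_stats.bh_adjust(mdf["p"].to_numpy())
    mdf.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
    done("motifs", pwms=len(pwms))

    # -- interactions -------------------------------------------------
    model = interaction.EnergyModel()
    bg = interaction.build_background(
        [(p["query_seq"], p["target_seq"]) for p in pairs],
        n_shuffles=config.n_shuffles, model=model,
        seed=config.stage_seed("interact"))
    evd = interaction.bin_and_fit(bg, n_len_bins=config.evd_bins[0],
                                  n_gc_bins=config.evd_bins[1],
                                  censor_cutoff=config.censor_cutoff,
                                  min_per_bin=config.min_per_bin)
    hits = interaction.score_pairs(pairs, evd, model)
    kept = interaction.filter_hits(
        hits, min_len_exclusive=int(config.filters["min_len"]),
        max_mfe=config.filters["max_mfe"], max_p=config.filters["max_p"])
    io.write_hits_tsv(out / "interaction_hits.tsv", hits)
    io.write_hits_tsv(out / "interaction_hits_significant.tsv", kept)
    done("interact", pairs=len(pairs), background_samples=len(bg),
         hits=len(hits), significant=len(kept))


def _random_pwm(pwm_id: str, rng) -> "motifs.PWM":
    """A sharp random PWM of length 7 (Dirichlet columns, one favored base)."""
    L = 7
    mat = rng.dirichlet([0.4, 0.4, 0.4, 0.4], size=L)
    return motifs.PWM(pwm_id, mat)


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
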