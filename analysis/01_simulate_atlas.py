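#!/usr/bin/env python
"""Generate the synthetic brain atlas used by every downstream analysis.

Writes the full input bundle (region ontology, per-probe voxel energies,
gene models, probes, structure intervals, transcript FASTA, interaction
pairs, ground-truth manifest) to results/atlas/ at the default study
conditions: an 11-coarse / 115-fine region ontology on a 20x16x12 voxel
lattice, 120 UTR probes (half structured, carrying a +2 mean energy shift
and one planted 5-probe correlated clique), 40 ncRNA probes, a 20-gene
genome and 40 RNA-RNA interaction pairs (half with planted 15-nt sites).
"""

import json
from pathlib import Path

from structatlas import io
from structatlas.synthetic import (SyntheticConfig, simulate_expression,
                                   simulate_genome, simulate_interaction_pairs,
                                   simulate_ontology)

OUT = Path(__file__).resolve().parent.parent / "results" / "atlas"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(seed=SEED)
    ontology = simulate_ontology(cfg)
    volumes, expr_manifest = simulate_expression(cfg, ontology)
    genes, probes, structures, sequences, truth = simulate_genome(cfg)
    pairs = simulate_interaction_pairs(cfg)

    io.write_ontology_json(OUT / "ontology.json", ontology)
    io.write_voxel_tsv(OUT / "voxels.tsv", volumes)
    io.write_gene_parts_bed(OUT / "gene_parts.bed", genes)
    io.write_bed(OUT / "probes.bed",
                 [(p["interval"], p["probe_id"]) for p in probes])
    io.write_structures_bed(OUT / "structures.bed", structures)
    io.write_fasta(OUT / "transcripts.fa", sequences)
    io.write_fasta(OUT / "pairs_query.fa",
                   {p["query_id"]: p["query_seq"] for p in pairs})
    io.write_fasta(OUT / "pairs_target.fa",
                   {p["target_id"]: p["target_seq"] for p in pairs})
    (OUT / "ground_truth.json").write_text(json.dumps(
        {"genome": truth,
         "expression": {"groups": expr_manifest["groups"],
                        "cliques": expr_manifest["cliques"]},
         "interaction_pairs": [
             {k: p[k] for k in ("query_id", "target_id", "planted",
                                "query_site", "target_site")}
             for p in pairs],
         "seed": SEED}, indent=1, default=str))

    n_regions = len(ontology.fine_ids)
    print(f"lattice {cfg.lattice_shape}, {len(ontology.coarse_ids)} coarse / "
          f"{n_regions} fine regions")
    print(f"{len(volumes)} probe volumes, {len(genes)} genes, "
          f"{len(structures)} structure predictions, {len(pairs)} "
          f"interaction pairs -> {OUT}")


if __name__ == "__main__":
    main()
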