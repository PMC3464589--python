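"""Readers and writers for the pipeline's on-disk formats.

Coordinates are BED-style (0-based, half-open) everywhere.  Voxel tables
are long-format TSV (probe_id, x, y, z, energy) or the intensity+density
pair form, which is converted to energy on load.  FASTA sequences may use
T; they are mapped to U on read (the package works in ACGU internally).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import ProbeRecord, StructurePrediction
from .expression import ExpressionVolume, RegionOntology
from .intervals import GeneModel, GenomicInterval


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper().replace("T", "U")
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


# ------------------------------------------------------------------ BED

def write_bed(path, records: list[tuple[GenomicInterval, str]],
              scores=None) -> None:
    """BED6 with the feature name in column 4."""
    with open(path, "w") as fh:
        for k, (iv, name) in enumerate(records):
            score = 0 if scores is None else scores[k]
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t"
                     f"{iv.strand}\n")


def read_bed(path) -> list[tuple[GenomicInterval, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "."
            name = f[3] if len(f) > 3 else ""
            out.append((GenomicInterval(f[0], int(f[1]), int(f[2]), strand),
                        name))
    return out


def write_gene_parts_bed(path, genes: list[GeneModel]) -> None:
    """Gene parts as BED with ``gene_id|part_kind`` in the name field."""
    recs = [(iv, f"{g.gene_id}|{kind}") for g in genes for iv, kind in g.parts]
    write_bed(path, recs)


def read_gene_parts_bed(path) -> list[GeneModel]:
    by_gene: dict[str, list] = {}
    for iv, name in read_bed(path):
        gene_id, kind = name.split("|", 1)
        by_gene.setdefault(gene_id, []).append((iv, kind))
    return [GeneModel(gid, parts) for gid, parts in by_gene.items()]


def write_structures_bed(path, structures: list[StructurePrediction]) -> None:
    write_bed(path, [(s.interval, s.source_id) for s in structures])


def read_structures_bed(path) -> list[StructurePrediction]:
    return [StructurePrediction(iv, name) for iv, name in read_bed(path)]


# ----------------------------------------------------------- voxel TSV

def write_voxel_tsv(path, volumes: list[ExpressionVolume]) -> None:
    frames = []
    for v in volumes:
        idx = np.indices(v.lattice_shape).reshape(3, -1)
        frames.append(pd.DataFrame({
            "probe_id": v.probe_id, "x": idx[0], "y": idx[1], "z": idx[2],
            "energy": v.energy.ravel()}))
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_voxel_tsv(path, lattice_shape=None) -> list[ExpressionVolume]:
    """Long-format voxel table -> dense volumes.

    Accepts either an ``energy`` column or ``intensity`` + ``density``
    columns (converted to energy = intensity * density on load).
    """
    df = pd.read_csv(path, sep="\t")
    if "energy" not in df.columns:
        if {"intensity", "density"} <= set(df.columns):
            df["energy"] = df["intensity"] * df["density"]
        else:
            raise ValueError("need an energy or intensity+density columns")
    if lattice_shape is None:
        lattice_shape = tuple(int(df[c].max()) + 1 for c in ("x", "y", "z"))
    out = []
    for pid, sub in df.groupby("probe_id", sort=False):
        e = np.zeros(lattice_shape)
        e[sub["x"], sub["y"], sub["z"]] = sub["energy"]
        out.append(ExpressionVolume(str(pid), e))
    return out


# -------------------------------------------------------- ontology JSON

def write_ontology_json(path, ontology: RegionOntology) -> None:
    payload = {
        "lattice_shape": list(ontology.lattice_shape),
        "tree": {str(k): v for k, v in ontology.tree.items()},
        "names": {str(k): v for k, v in ontology.names.items()},
        "coarse_names": {str(k): v for k, v in ontology.coarse_names.items()},
        "labels": ontology.labels.ravel().tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_ontology_json(path) -> RegionOntology:
    payload = json.loads(Path(path).read_text())
    shape = tuple(payload["lattice_shape"])
    labels = np.array(payload["labels"], dtype=int).reshape(shape)
    tree = {int(k): [int(x) for x in v] for k, v in payload["tree"].items()}
    names = {int(k): v for k, v in payload.get("names", {}).items()}
    coarse_names = {int(k): v
                    for k, v in payload.get("coarse_names", {}).items()}
    return RegionOntology(tree=tree, labels=labels, names=names,
                          coarse_names=coarse_names)


# ----------------------------------------------------------- tables

def write_probe_table(path, probes: list[ProbeRecord]) -> None:
    rows = [{
        "probe_id": p.probe_id, "chrom": p.interval.chrom,
        "start": p.interval.start, "end": p.interval.end,
        "classes": ",".join(sorted(p.classes)),
        "structured": p.structured, "expressed": p.expressed,
        "coding_potential": p.coding_potential,
        "known_rna_labels": ",".join(p.known_rna_labels),
    } for p in probes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_edges_tsv(path, pairs) -> None:
    pd.DataFrame([{"probe_a": p.probe_a, "probe_b": p.probe_b,
                   "rho": p.rho, "domain": p.domain}
                  for p in pairs]).to_csv(path, sep="\t", index=False)


def write_hits_tsv(path, hits) -> None:
    pd.DataFrame([{
        "query_id": h.query_id, "target_id": h.target_id,
        "query_start": h.query_site[0], "query_end": h.query_site[1],
        "target_start": h.target_site[0], "target_end": h.target_site[1],
        "mfe": h.mfe, "site_length": h.site_length, "gc_frac": h.gc_frac,
        "p_value": h.p_value,
    } for h in hits]).to_csv(path, sep="\t", index=False)

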