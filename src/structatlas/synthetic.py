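"""Synthetic voxel atlas, gene models and interaction pairs with known truth.

Everything the pipeline consumes can be generated here with the
statistical structure the analysis assumes, so every downstream stage is
testable against planted ground truth: a two-level region ontology grown on
a voxel lattice (default 11 coarse / 115 fine regions, voxels nominally
200 µm per side), per-probe expression-energy volumes with a group-level
mean shift for "structured" groups and shared latent patterns for planted
correlated cliques, gene models with UTR/CDS/intron parts plus probes and
strandless structure intervals covering every classification category, and
query/target sequence pairs with planted reverse-complement interaction
sites.

All outputs are deterministic functions of the config (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import StructurePrediction
from .expression import ExpressionVolume, RegionOntology
from .intervals import GeneModel, GenomicInterval

#: Canonical coarse-region names used when n_coarse_regions == 11.
COARSE_NAMES_11 = ["CTX", "OLF", "HPF", "STR", "PAL", "TH", "MB", "MY", "HY",
                   "CB", "P"]

#: Probe groups; the *_structured groups receive the mean energy shift.
GROUPS = ("utr_structured", "utr_unstructured",
          "ncrna_structured", "ncrna_unstructured")

_RC = str.maketrans("ACGU", "UGCA")
_STOPS = ("UAA", "UAG", "UGA")


@dataclass
class SyntheticConfig:
    seed: int = 0
    lattice_shape: tuple[int, int, int] = (20, 16, 12)
    n_coarse_regions: int = 11
    n_fine_regions: int = 115
    n_probes_per_group: dict[str, int] = field(
        default_factory=lambda: {"utr_structured": 60, "utr_unstructured": 60,
                                 "ncrna_structured": 20,
                                 "ncrna_unstructured": 20})
    effect_size: float = 2.0
    clique_spec: list[tuple[int, float]] = field(
        default_factory=lambda: [(5, 0.95)])
    noise_sd: float = 1.0
    baseline: float = 5.0
    focal_boost: float = 2.0
    expressed_threshold: float = 0.5
    genome_length: int = 200_000
    n_genes: int = 20
    interaction_site_length: int = 15
    interaction_site_gc: float = 0.8
    n_interaction_pairs: int = 40
    planted_pair_fraction: float = 0.5
    pair_seq_length: int = 100

    def __post_init__(self) -> None:
        if len(self.lattice_shape) != 3 or any(s <= 0 for s in self.lattice_shape):
            raise ValueError("lattice_shape must be 3 positive integers")
        if not (1 <= self.n_coarse_regions <= self.n_fine_regions):
            raise ValueError("need n_fine_regions >= n_coarse_regions >= 1")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("noise_sd and effect_size must be >= 0")
        if self.interaction_site_length < 2:
            raise ValueError("interaction sites need length >= 2")
        if self.interaction_site_length > self.pair_seq_length:
            raise ValueError("interaction site longer than the sequences")
        if any(n <= 0 for n in self.n_probes_per_group.values()):
            raise ValueError("probe counts must be positive")


def _accrete(shape, voxel_subset: np.ndarray, n_regions: int, rng,
             offset: int = 0) -> np.ndarray:
    """Randomized multi-source accretion of ``n_regions`` contiguous regions.

    ``voxel_subset`` is a boolean mask of the voxels to partition.  Returns
    an int array with labels ``offset .. offset+n_regions-1`` inside the
    subset and -1 outside.
    """
    coords = np.argwhere(voxel_subset)
    if len(coords) < n_regions:
        raise ValueError(
            f"cannot partition {len(coords)} voxels into {n_regions} regions")
    labels = np.full(shape, -1, dtype=int)
    seeds = coords[rng.choice(len(coords), size=n_regions, replace=False)]
    steps = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]

    def neighbors(v):
        for dx, dy, dz in steps:
            w = (v[0] + dx, v[1] + dy, v[2] + dz)
            if all(0 <= w[i] < shape[i] for i in range(3)) and \
                    voxel_subset[w] and labels[w] == -1:
                yield w

    frontiers: list[list] = [[] for _ in range(n_regions)]
    for r, s in enumerate(seeds):
        v = tuple(s)
        labels[v] = offset + r
        frontiers[r].extend(neighbors(v))
    # round-robin growth: each region claims one adjacent voxel per round,
    # which keeps region sizes near-balanced and guarantees contiguity
    remaining = int(voxel_subset.sum()) - n_regions
    while remaining > 0:
        progressed = False
        for r in rng.permutation(n_regions):
            fr = frontiers[r]
            while fr:
                k = int(rng.integers(len(fr)))
                fr[k], fr[-1] = fr[-1], fr[k]
                v = fr.pop()
                if labels[v] == -1:
                    labels[v] = offset + r
                    fr.extend(neighbors(v))
                    remaining -= 1
                    progressed = True
                    break
        if not progressed:
            # disconnected subset: attach stragglers to any labeled neighbor
            for v in map(tuple, np.argwhere(voxel_subset & (labels == -1))):
                for dx, dy, dz in steps:
                    w = (v[0] + dx, v[1] + dy, v[2] + dz)
                    if all(0 <= w[i] < shape[i] for i in range(3)) and \
                            labels[w] != -1 and voxel_subset[w]:
                        labels[v] = labels[w]
                        remaining -= 1
                        break
            if np.any(voxel_subset & (labels == -1)):
                raise ValueError("voxel subset is disconnected; cannot partition")
    return labels


def simulate_ontology(config: SyntheticConfig) -> RegionOntology:
    """Grow the two-level region hierarchy on the voxel lattice.

    Coarse regions are grown by seeded accretion over the whole lattice;
    fine regions are grown the same way inside each coarse region, with the
    115 fine regions distributed across coarse regions proportionally to
    their voxel counts (at least one each).
    """
    shape = tuple(config.lattice_shape)
    n_vox = int(np.prod(shape))
    if config.n_fine_regions > n_vox:
        raise ValueError("more fine regions than voxels")
    rng = np.random.default_rng(config.seed)
    coarse = _accrete(shape, np.ones(shape, dtype=bool),
                      config.n_coarse_regions, rng)
    sizes = np.bincount(coarse.ravel(), minlength=config.n_coarse_regions)
    # largest-remainder apportionment of fine regions, >= 1 per coarse region
    quota = sizes / sizes.sum() * config.n_fine_regions
    n_fine = np.maximum(1, np.floor(quota).astype(int))
    # regions cannot get more fine regions than voxels
    n_fine = np.minimum(n_fine, sizes)
    rem = config.n_fine_regions - n_fine.sum()
    order = np.argsort(-(quota - np.floor(quota)))
    i = 0
    while rem != 0:
        c = order[i % len(order)]
        if rem > 0 and n_fine[c] < sizes[c]:
            n_fine[c] += 1
            rem -= 1
        elif rem < 0 and n_fine[c] > 1:
            n_fine[c] -= 1
            rem += 1
        i += 1
    labels = np.full(shape, -1, dtype=int)
    tree: dict[int, list[int]] = {}
    nxt = 0
    for c in range(config.n_coarse_regions):
        fl = _accrete(shape, coarse == c, int(n_fine[c]), rng, offset=nxt)
        labels = np.where(fl >= 0, fl, labels)
        tree[c] = list(range(nxt, nxt + int(n_fine[c])))
        nxt += int(n_fine[c])
    names, coarse_names = {}, {}
    for c in range(config.n_coarse_regions):
        cname = (COARSE_NAMES_11[c] if config.n_coarse_regions == 11
                 else f"C{c:02d}")
        coarse_names[c] = cname
        for k, f in enumerate(tree[c]):
            names[f] = f"{cname}.{k:02d}"
    return RegionOntology(tree=tree, labels=labels, names=names,
                          coarse_names=coarse_names)


def simulate_expression(config: SyntheticConfig, ontology: RegionOntology):
    """Per-probe energy volumes with planted group effects and cliques.

    energy = baseline + effect_size (structured groups)
             + clique latent pattern + iid Gaussian noise, clipped at 0.

    Clique members share a spatial latent field Z (a standard-normal voxel
    field plus a mean boost in the clique's focal coarse region); a member
    with clique strength s gets s*sd*Z + sqrt(1-s^2)*sd*eps so within-
    clique voxel correlations are ~s^2 while marginal noise variance stays
    at noise_sd^2.  Cliques are planted among the structured-UTR probes.

    Returns ``(volumes, manifest)`` where the manifest records each probe's
    group, expressed flag, clique id and each clique's focal region.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    shape = ontology.lattice_shape
    probe_ids, groups = [], {}
    for g in GROUPS:
        for k in range(config.n_probes_per_group.get(g, 0)):
            pid = f"{g}_{k:04d}"
            probe_ids.append(pid)
            groups[pid] = g
    # assign cliques to structured-UTR probes, one focal region per clique
    clique_of: dict[str, int] = {}
    strength_of: dict[int, float] = {}
    utr_s = [p for p in probe_ids if groups[p] == "utr_structured"]
    pos = 0
    focal = {}
    coarse_ids = ontology.coarse_ids
    focal_choices = rng.permutation(coarse_ids)
    for ci, (size, strength) in enumerate(config.clique_spec):
        members = utr_s[pos:pos + size]
        if len(members) < size:
            raise ValueError("not enough structured-UTR probes for cliques")
        pos += size
        for m in members:
            clique_of[m] = ci
        strength_of[ci] = float(strength)
        focal[ci] = int(focal_choices[ci % len(focal_choices)])
    zfields = {}
    for ci in strength_of:
        z = rng.standard_normal(shape)
        z[ontology.mask(focal[ci], level="coarse")] += config.focal_boost
        zfields[ci] = z
    volumes, expressed = [], {}
    for pid in probe_ids:
        e = np.full(shape, config.baseline, dtype=float)
        if groups[pid].endswith("_structured"):
            e += config.effect_size
        eps = rng.standard_normal(shape)
        if pid in clique_of:
            s = strength_of[clique_of[pid]]
            e += config.noise_sd * (s * zfields[clique_of[pid]]
                                    + np.sqrt(1 - s**2) * eps)
        else:
            e += config.noise_sd * eps
        e = np.clip(e, 0.0, None)
        volumes.append(ExpressionVolume(pid, e))
        expressed[pid] = bool(e.mean() > config.expressed_threshold)
    manifest = {
        "groups": groups,
        "expressed": expressed,
        "cliques": [{"id": ci,
                     "probes": [p for p, c in clique_of.items() if c == ci],
                     "strength": strength_of[ci],
                     "focal_region": focal[ci]}
                    for ci in strength_of],
    }
    return volumes, manifest


def _random_seq(rng, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGU"), size=n, p=p))


def _orf_seq(rng, n_codons: int) -> str:
    """AUG + (n_codons-1) random non-stop codons + UAA."""
    bases = "ACGU"
    codons = ["AUG"]
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(bases), size=3))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons) + "UAA"


# genomic layout of one gene slot (lengths in nt)
_UTR_A, _CDS1, _INTRON, _CDS2, _UTR_B = 150, 200, 300, 175, 200
_GENE_LEN = _UTR_A + _CDS1 + _INTRON + _CDS2 + _UTR_B
_PROBE_KINDS = ("three_utr", "five_utr", "cds", "intronic")


def simulate_genome(config: SyntheticConfig):
    """Gene models, probes, structures and sequences with planted truth.

    Each gene occupies a disjoint slot (5'UTR exon, CDS split by one
    intron, 3'UTR exon; strands alternate) and carries one probe whose
    truth class cycles through 3'UTR / 5'UTR / CDS-only / intronic; every
    inter-slot gap carries one intergenic probe.  Structures are planted so
    that alternate probes are structured (inside the gene part mapped to
    the probe, exercising the 1-nt mapping rule) while decoy structures sit
    in gaps away from every probe.  One long intergenic probe carries a
    planted ORF (coding potential, hence not an ncRNA candidate).

    Returns ``(genes, probes, structures, sequences, truth)`` where
    ``probes`` is a list of dicts with interval + truth labels, and
    ``sequences`` maps transcript/probe ids to ACGU strings.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    gap = (config.genome_length - config.n_genes * _GENE_LEN) // (config.n_genes + 1)
    if gap < 700:
        raise ValueError("genome_length too small for n_genes with workable gaps")
    chrom = "chrS"
    genome = list(_random_seq(rng, config.genome_length))
    genes, probes, structures, sequences = [], [], [], {}
    struct_id = 0
    for gi in range(config.n_genes):
        start = gap + gi * (_GENE_LEN + gap)
        strand = "+" if gi % 2 == 0 else "-"
        a = start
        bounds = {}
        for name, ln in (("utrA", _UTR_A), ("cds1", _CDS1), ("intron", _INTRON),
                         ("cds2", _CDS2), ("utrB", _UTR_B)):
            bounds[name] = (a, a + ln)
            a += ln
        if strand == "+":
            kinds = {"utrA": "five_utr", "utrB": "three_utr"}
        else:
            kinds = {"utrA": "three_utr", "utrB": "five_utr"}
        parts = [
            (GenomicInterval(chrom, *bounds["utrA"], strand), kinds["utrA"]),
            (GenomicInterval(chrom, *bounds["cds1"], strand), "cds"),
            (GenomicInterval(chrom, *bounds["intron"], strand), "intron"),
            (GenomicInterval(chrom, *bounds["cds2"], strand), "cds"),
            (GenomicInterval(chrom, *bounds["utrB"], strand), kinds["utrB"]),
        ]
        gene = GeneModel(f"gene{gi:03d}", parts)
        genes.append(gene)
        # CDS carries a real ORF (sense = gene strand)
        orf = _orf_seq(rng, (_CDS1 + _CDS2) // 3 - 1)
        if strand == "+":
            genome[bounds["cds1"][0]:bounds["cds1"][1]] = list(orf[:_CDS1])
            genome[bounds["cds2"][0]:bounds["cds2"][1]] = list(orf[_CDS1:])
        else:
            rc = orf.translate(_RC)[::-1]
            genome[bounds["cds1"][0]:bounds["cds1"][1]] = list(rc[:_CDS1])
            genome[bounds["cds2"][0]:bounds["cds2"][1]] = list(rc[_CDS1:])

        kind = _PROBE_KINDS[gi % len(_PROBE_KINDS)]
        structured = (gi // len(_PROBE_KINDS)) % 2 == 0
        pid = f"probe_g{gi:03d}_{kind}"
        if kind in ("three_utr", "five_utr"):
            seg = "utrA" if kinds["utrA"] == kind else "utrB"
            s0, s1 = bounds[seg]
            p_iv = GenomicInterval(chrom, s0 + 20, s0 + 120, ".")
            t_classes = {kind}
            if structured:
                # in the mapped UTR exon but only 1 nt inside the probe's
                # exon: anywhere in the exon works via part mapping
                st = GenomicInterval(chrom, s1 - 60, s1 - 10, ".")
        elif kind == "cds":
            s0, s1 = bounds["cds1"]
            p_iv = GenomicInterval(chrom, s0 + 10, s0 + 110, ".")
            t_classes = {"cds"}
            if structured:
                st = GenomicInterval(chrom, s0 + 120, s0 + 180, ".")
        else:  # intronic
            s0, s1 = bounds["intron"]
            p_iv = GenomicInterval(chrom, s0 + 50, s0 + 150, ".")
            t_classes = {"intronic"}
            if structured:
                st = GenomicInterval(chrom, s0 + 200, s0 + 260, ".")
        if structured:
            structures.append(StructurePrediction(st, f"struct{struct_id:03d}"))
            struct_id += 1
        probes.append({"probe_id": pid, "interval": p_iv,
                       "classes": t_classes, "structured": structured})
        tx = "".join(genome[bounds["utrA"][0]:bounds["utrA"][1]]
                     + genome[bounds["cds1"][0]:bounds["cds1"][1]]
                     + genome[bounds["cds2"][0]:bounds["cds2"][1]]
                     + genome[bounds["utrB"][0]:bounds["utrB"][1]])
        if strand == "-":
            tx = tx.translate(_RC)[::-1]
        sequences[gene.gene_id] = tx

        # one intergenic probe in the gap before this gene
        gpid = f"probe_ig{gi:03d}"
        g_structured = gi % 2 == 0
        g0 = start - gap + 50
        ig_iv = GenomicInterval(chrom, g0, g0 + 100, ".")
        probes.append({"probe_id": gpid, "interval": ig_iv,
                       "classes": {"intergenic"}, "structured": g_structured})
        if g_structured:
            # >= 1 nt overlap with the probe itself (1-nt rule)
            structures.append(StructurePrediction(
                GenomicInterval(chrom, g0 + 99, g0 + 160, "."),
                f"struct{struct_id:03d}"))
            struct_id += 1
        else:
            # decoy structure in the gap, clear of the probe
            structures.append(StructurePrediction(
                GenomicInterval(chrom, g0 + 300, g0 + 360, "."),
                f"decoy{struct_id:03d}"))
            struct_id += 1
    # one long intergenic probe with a planted ORF: coding, so not an ncRNA
    tail = config.n_genes * (_GENE_LEN + gap) + gap // 2
    if tail + 600 < config.genome_length:
        orf = _orf_seq(rng, 150)
        cp_iv = GenomicInterval(chrom, tail, tail + 600, ".")
        genome[tail + 50:tail + 50 + len(orf)] = list(orf)
        probes.append({"probe_id": "probe_ig_coding", "interval": cp_iv,
                       "classes": {"intergenic"}, "structured": False,
                       "coding": True})
    for p in probes:
        iv = p["interval"]
        sequences[p["probe_id"]] = "".join(genome[iv.start:iv.end])
    truth = {p["probe_id"]: {"classes": sorted(p["classes"]),
                             "structured": p["structured"],
                             "coding": bool(p.get("coding", False))}
             for p in probes}
    return genes, probes, structures, sequences, truth


def simulate_interaction_pairs(config: SyntheticConfig):
    """Query/target sequence pairs, a fraction with planted duplex sites.

    Planted pairs carry a GC-rich site (default GC fraction 0.8, length 15)
    in the query and its exact reverse complement in the target, at
    recorded coordinates; the rest are unrelated random pairs.  Under the
    default pair-additive energies a planted perfect duplex scores at most
    -(3*nGC + 2*nAU) kcal/mol, i.e. <= -42 for the default site.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n = config.n_interaction_pairs
    L = config.interaction_site_length
    sl = config.pair_seq_length
    n_planted = int(round(config.planted_pair_fraction * n))
    pairs = []
    for i in range(n):
        q = _random_seq(rng, sl)
        t = _random_seq(rng, sl)
        rec = {"query_id": f"ncrna{i:04d}", "target_id": f"utr{i:04d}",
               "planted": i < n_planted, "query_site": None,
               "target_site": None}
        if i < n_planted:
            n_gc = int(round(config.interaction_site_gc * L))
            site = list("G" * (n_gc // 2) + "C" * (n_gc - n_gc // 2)
                        + "A" * ((L - n_gc) // 2)
                        + "U" * (L - n_gc - (L - n_gc) // 2))
            site = "".join(rng.permutation(site))
            qa = int(rng.integers(0, sl - L + 1))
            ta = int(rng.integers(0, sl - L + 1))
            q = q[:qa] + site + q[qa + L:]
            t = t[:ta] + site.translate(_RC)[::-1] + t[ta + L:]
            rec["query_site"] = (qa, qa + L)
            rec["target_site"] = (ta, ta + L)
        rec["query_seq"] = q
        rec["target_seq"] = t
        pairs.append(rec)
    return pairs
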