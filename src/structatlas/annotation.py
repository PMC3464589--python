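"""Probe classification and structure mapping against gene models.

Riboprobes are classified by how much of their length falls in annotated
gene parts: a probe gets an exonic class (5' UTR, 3' UTR, CDS) when at
least ``min_frac`` (default 10%) of the probe is covered by parts of that
kind.  Probes with no exonic overlap at all are intergenic and/or intronic.
Predicted RNA structures are strandless and map to a probe when they share
at least one nucleotide with the probe itself (intergenic probes) or with
any gene part mapped to the probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import EXONIC_KINDS, GeneModel, GenomicInterval

#: Probe class labels.
CLASS_LABELS = ("intergenic", "intronic", "five_utr", "three_utr", "cds")

STOP_CODONS = {"UAA", "UAG", "UGA"}
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


@dataclass
class StructurePrediction:
    """A predicted conserved RNA secondary structure locus (strandless)."""

    interval: GenomicInterval
    source_id: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if self.interval.strand != ".":
            # structure predictions never carry a trusted strand
            self.interval = GenomicInterval(
                self.interval.chrom, self.interval.start, self.interval.end, "."
            )


@dataclass
class ProbeRecord:
    probe_id: str
    interval: GenomicInterval
    classes: set[str] = field(default_factory=set)
    structured: bool = False
    expressed: bool = False
    known_rna_labels: list[str] = field(default_factory=list)
    coding_potential: bool = False
    mapped_structures: list[StructurePrediction] = field(default_factory=list)

    @property
    def is_utr(self) -> bool:
        return bool(self.classes & {"five_utr", "three_utr"})

    @property
    def is_putative_ncrna(self) -> bool:
        """Entirely intergenic/intronic and without coding potential."""
        return (
            bool(self.classes)
            and self.classes <= {"intergenic", "intronic"}
            and not self.coding_potential
        )


def _covered_len(probe: GenomicInterval, parts: list[GenomicInterval]) -> int:
    """Bases of ``probe`` covered by the union of ``parts``."""
    segs = sorted(
        (max(p.start, probe.start), min(p.end, probe.end))
        for p in parts
        if p.chrom == probe.chrom and p.start < probe.end and p.end > probe.start
    )
    total = 0
    cur_s = cur_e = None
    for s, e in segs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def classify_probe(
    probe: GenomicInterval,
    genes: list[GeneModel],
    min_frac: float = 0.10,
) -> set[str]:
    """Class set of a probe against gene models.

    Exonic classes (``five_utr``, ``three_utr``, ``cds``) require the union
    of same-kind parts (across genes) to cover >= ``min_frac`` of the probe
    length.  When the probe overlaps *no* exonic base it is classified
    ``intronic`` (>= 1 nt inside an intron) and/or ``intergenic`` (>= 1 nt
    outside every gene part).  An empty gene list makes every probe
    intergenic.  A probe whose only exonic contact is below ``min_frac``
    receives an empty class set.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    classes: set[str] = set()
    for kind in EXONIC_KINDS:
        parts = [iv for g in genes for iv in g.parts_of_kind(kind)]
        if _covered_len(probe, parts) >= min_frac * len(probe):
            classes.add(kind)
    all_exonic = [iv for g in genes for k in EXONIC_KINDS for iv in g.parts_of_kind(k)]
    if _covered_len(probe, all_exonic) == 0:
        introns = [iv for g in genes for iv in g.parts_of_kind("intron")]
        if _covered_len(probe, introns) > 0:
            classes.add("intronic")
        all_parts = [iv for g in genes for iv, _ in g.parts]
        if _covered_len(probe, all_parts) < len(probe):
            classes.add("intergenic")
    return classes


def map_structures(
    probe: ProbeRecord,
    structures: list[StructurePrediction],
    genes: list[GeneModel],
    min_frac: float = 0.10,
) -> list[StructurePrediction]:
    """Structures mapped to an (already classified) probe by the 1-nt rule.

    Intergenic/intronic probes take structures overlapping >= 1 nt of the
    probe itself; gene-mapped probes take structures overlapping >= 1 nt of
    any gene part that was itself mapped to the probe (>= ``min_frac``
    overlap for exonic parts, >= 1 nt for introns of mapped-intronic
    probes).  Strand is ignored throughout.  Sets ``probe.structured``.
    """
    targets: list[GenomicInterval] = []
    if probe.classes <= {"intergenic", "intronic"}:
        targets.append(probe.interval)
    for kind in probe.classes & set(EXONIC_KINDS):
        for g in genes:
            for iv in g.parts_of_kind(kind):
                if iv.overlaps(probe.interval):
                    targets.append(iv)
    if "intronic" in probe.classes:
        for g in genes:
            for iv in g.parts_of_kind("intron"):
                if iv.overlaps(probe.interval):
                    targets.append(iv)
    mapped = [
        s for s in structures if any(s.interval.overlaps(t) for t in targets)
    ]
    probe.mapped_structures = mapped
    probe.structured = bool(mapped)
    return mapped


def annotate_known(
    probe: GenomicInterval,
    known: list[tuple[GenomicInterval, str]],
    min_frac: float = 0.10,
) -> list[str]:
    """Known-RNA labels whose feature the probe covers by >= ``min_frac``.

    The denominator is the *reference* feature's length (a probe is called
    a known microRNA when it covers at least 10% of that microRNA), unlike
    probe classification where the denominator is the probe.
    """
    labels = []
    for iv, label in known:
        if probe.overlap_len(iv) >= min_frac * len(iv):
            labels.append(label)
    return labels


def _orf_max_codons_and_len(seq: str) -> list[tuple[int, int]]:
    """All forward ORFs of ``seq`` as (codon count, nt length).

    An ORF starts at AUG and runs to the first in-frame stop; the codon
    count excludes the stop.  ORFs with no in-frame stop extend to the last
    complete codon.
    """
    orfs = []
    n = len(seq)
    for start in range(n - 2):
        if seq[start : start + 3] != "AUG":
            continue
        codons = 0
        i = start
        while i + 3 <= n:
            if codons > 0 and seq[i : i + 3] in STOP_CODONS:
                break
            codons += 1
            i += 3
        orfs.append((codons, 3 * codons))
    return orfs


def coding_potential(
    transcript: str, min_codons: int = 120, min_fraction: float = 1.0 / 3.0
) -> bool:
    """True if the transcript carries a long ORF relative to its length.

    Detects ORFs of more than ``min_codons`` codons that also span at least
    ``min_fraction`` of the transcript length.  Both strands are scanned
    because probe/structure strand is not trusted.
    """
    seq = transcript.upper().replace("T", "U")
    if len(seq) < 3:
        raise ValueError("transcript shorter than one codon")
    if set(seq) - set("ACGU"):
        raise ValueError("transcript contains non-nucleotide symbols")
    rc = seq.translate(_COMPLEMENT)[::-1]
    for s in (seq, rc):
        for codons, nt_len in _orf_max_codons_and_len(s):
            if codons > min_codons and nt_len >= min_fraction * len(seq):
                return True
    return False


def utr_relative_position(
    structure: GenomicInterval, utr: GenomicInterval, strand: str
) -> float:
    """Relative position (0 = 5' end) of a structure within a UTR.

    Midpoint of the structure/UTR overlap as a fraction of UTR length,
    measured from the UTR's 5' end, so the value is strand-aware.
    """
    ov = structure.overlap_len(utr)
    if ov == 0:
        raise ValueError("structure does not overlap the UTR")
    lo = max(structure.start, utr.start)
    hi = min(structure.end, utr.end)
    mid = (lo + hi) / 2.0
    if strand == "-":
        return (utr.end - mid) / len(utr)
    return (mid - utr.start) / len(utr)
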