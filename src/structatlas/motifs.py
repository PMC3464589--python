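"""PWM scanning of UTR-structure neighborhoods for RNA-binding proteins.

Predicted UTR structures plus 50 nt of flanking sequence are scanned with
position weight matrices (e.g. RBPDB-style motifs in JASPAR text format).
Scores are log2 odds against a background composition, with matrix cells
floored at a small pseudocount so zero cells stay finite; a hit requires a
relative score (min-max normalized over the PWM's score range) of at least
0.8.  RNA is single-stranded, so only the sense strand is scanned.

Motif enrichment against chance uses the same dinucleotide-shuffling null
as the interaction module: the number of sequences with at least one hit is
compared to the same statistic on shuffled copies of every sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .interaction import dinuc_shuffle

logger = logging.getLogger(__name__)

_IDX = {b: i for i, b in enumerate("ACGU")}


@dataclass
class PWM:
    """Per-position nucleotide probabilities (columns A, C, G, U)."""

    id: str
    matrix: np.ndarray  # L x 4
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or \
                self.matrix.shape[0] < 1:
            raise ValueError("PWM matrix must be L x 4 with L >= 1")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, pseudocount: float = 0.01) -> np.ndarray:
        """log2 odds matrix; cells floored at ``pseudocount``."""
        p = np.maximum(self.matrix, pseudocount)
        return np.log2(p / self.background)

    @classmethod
    def from_counts(cls, id: str, counts: np.ndarray, **kw) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(id, counts / counts.sum(axis=1, keepdims=True), **kw)


@dataclass
class MotifHit:
    pwm_id: str
    seq_id: str
    position: int
    score: float      # bits
    rel_score: float  # in [0, 1]


def read_jaspar(path_or_handle) -> list[PWM]:
    """Read JASPAR-format count matrices into PWMs (T treated as U)."""
    from Bio import motifs as bio_motifs

    close = False
    if isinstance(path_or_handle, (str, bytes)):
        handle = open(path_or_handle)
        close = True
    else:
        handle = path_or_handle
    try:
        records = bio_motifs.parse(handle, "jaspar")
        out = []
        for m in records:
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
            counts += 1e-9  # guard empty columns
            out.append(PWM.from_counts(m.matrix_id or m.name, counts))
        return out
    finally:
        if close:
            handle.close()


def extract_flanked(structure_interval: tuple[int, int], utr_sequence: str,
                    flank: int = 50) -> str:
    """Structure subsequence plus up to ``flank`` nt on each side.

    ``structure_interval`` is 0-based half-open in UTR-sequence
    coordinates; flanks are clipped at the UTR boundaries (clipping is
    logged).
    """
    s, e = structure_interval
    if not (0 <= s < e <= len(utr_sequence)):
        raise ValueError("structure interval outside the UTR sequence")
    lo = max(0, s - flank)
    hi = min(len(utr_sequence), e + flank)
    if lo == 0 and s - flank < 0 or hi == len(utr_sequence) and e + flank > len(utr_sequence):
        logger.info("flank clipped at UTR boundary for interval (%d, %d)", s, e)
    return utr_sequence[lo:hi]


def pwm_scan(seq: str, pwm: PWM, rel_threshold: float = 0.8,
             pseudocount: float = 0.01, seq_id: str = "") -> list[MotifHit]:
    """Sense-strand log-odds scan; hits where rel_score >= threshold.

    rel_score = (score - min) / (max - min) over the PWM's achievable
    score range.
    """
    s = seq.upper().replace("T", "U")
    L = len(pwm)
    if len(s) < L:
        raise ValueError("sequence shorter than the PWM")
    lo = pwm.log_odds(pseudocount)
    smin, smax = lo.min(axis=1).sum(), lo.max(axis=1).sum()
    span = smax - smin
    idx = np.fromiter((_IDX[c] for c in s), dtype=int, count=len(s))
    hits = []
    for off in range(len(s) - L + 1):
        sc = float(lo[np.arange(L), idx[off:off + L]].sum())
        rel = (sc - smin) / span if span > 0 else 1.0
        if rel >= rel_threshold:
            hits.append(MotifHit(pwm.id, seq_id, off, sc, rel))
    return hits


def motif_enrichment(sequences: list[str], pwm: PWM, n_shuffles: int = 100,
                     seed: int = 0, rel_threshold: float = 0.8) -> float:
    """Empirical p for motif presence vs dinucleotide-shuffled chance.

    Statistic: number of sequences with >= 1 hit.  Null: the same
    statistic on dinucleotide-shuffled copies of every sequence.
    p = (1 + #{null >= observed}) / (n_shuffles + 1).
    """
    if not sequences:
        raise ValueError("empty sequence set")

    def stat(seqs):
        return sum(1 for s in seqs if len(s) >= len(pwm)
                   and pwm_scan(s, pwm, rel_threshold))

    obs = stat(sequences)
    if obs == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_shuffles):
        shuffled = [dinuc_shuffle(s, rng) for s in sequences]
        if stat(shuffled) >= obs:
            ge += 1
    return (1 + ge) / (n_shuffles + 1)


def match_bound_sequences(seq: str, bound_seqs: dict[str, str],
                          max_mismatches: int = 1) -> list[str]:
    """Ids of experimentally bound sequences found in ``seq`` near-exactly.

    A bound sequence matches when some window of ``seq`` equals it with at
    most ``max_mismatches`` substitutions (a deliberately light stand-in
    for local alignment against single-sequence binding experiments).
    """
    s = seq.upper().replace("T", "U")
    out = []
    for bid, b in bound_seqs.items():
        b = b.upper().replace("T", "U")
        k = len(b)
        if k == 0 or k > len(s):
            continue
        for off in range(len(s) - k + 1):
            mism = sum(1 for x, y in zip(s[off:off + k], b) if x != y)
            if mism <= max_mismatches:
                out.append(bid)
                break
    return out
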