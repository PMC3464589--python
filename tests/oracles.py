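"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration / per-base set
arithmetic, deliberately avoiding the code paths of the implementation it
checks.
"""

from __future__ import annotations

import math

import numpy as np

from structatlas.intervals import EXONIC_KINDS


def bases(iv) -> set:
    """Genomic positions of an interval as a set of (chrom, pos)."""
    return {(iv.chrom, p) for p in range(iv.start, iv.end)}


def classify_oracle(probe, genes, min_frac=0.10) -> set:
    """Per-base reimplementation of the probe classification rule."""
    pb = bases(probe)
    classes = set()
    for kind in EXONIC_KINDS:
        cov = set()
        for g in genes:
            for iv in g.parts_of_kind(kind):
                cov |= bases(iv) & pb
        if len(cov) >= min_frac * len(pb):
            classes.add(kind)
    exonic = set()
    for g in genes:
        for kind in EXONIC_KINDS:
            for iv in g.parts_of_kind(kind):
                exonic |= bases(iv)
    if not (pb & exonic):
        intron = set()
        allparts = set()
        for g in genes:
            for iv, _ in g.parts:
                allparts |= bases(iv)
            for iv in g.parts_of_kind("intron"):
                intron |= bases(iv)
        if pb & intron:
            classes.add("intronic")
        if pb - allparts:
            classes.add("intergenic")
    return classes


def map_structures_oracle(probe_iv, classes, structures, genes) -> set:
    """Per-base structure mapping (returns the set of mapped source_ids)."""
    targets = set()
    if classes <= {"intergenic", "intronic"}:
        targets |= bases(probe_iv)
    for kind in classes & set(EXONIC_KINDS):
        for g in genes:
            for iv in g.parts_of_kind(kind):
                if bases(iv) & bases(probe_iv):
                    targets |= bases(iv)
    if "intronic" in classes:
        for g in genes:
            for iv in g.parts_of_kind("intron"):
                if bases(iv) & bases(probe_iv):
                    targets |= bases(iv)
    return {s.source_id for s in structures if bases(s.interval) & targets}


def annotate_known_oracle(probe, known, min_frac=0.10) -> list:
    pb = bases(probe)
    return [label for iv, label in known
            if len(bases(iv) & pb) >= min_frac * len(bases(iv))]


def bh_oracle(pvals) -> np.ndarray:
    """min-over-tail step-up adjustment, computed per element."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for pos, idx in enumerate(order):
        tail = [m * p[order[j]] / (j + 1) for j in range(pos, m)]
        out[idx] = min(1.0, min(tail))
    return out


def fisher_oracle(a, b, c, d) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(0, c1 + 1)
               if pmf(x) <= p_obs * (1 + 1e-9))


def pwm_scan_oracle(seq, pwm, rel_threshold=0.8, pseudocount=0.01):
    """Window-by-window log-odds scoring with explicit loops."""
    idx = {b: i for i, b in enumerate("ACGU")}
    lo = np.log2(np.maximum(pwm.matrix, pseudocount) / pwm.background)
    smin = sum(min(row) for row in lo)
    smax = sum(max(row) for row in lo)
    hits = []
    L = len(pwm)
    for off in range(len(seq) - L + 1):
        sc = sum(lo[k][idx[seq[off + k]]] for k in range(L))
        rel = (sc - smin) / (smax - smin) if smax > smin else 1.0
        if rel >= rel_threshold:
            hits.append((off, round(sc, 9)))
    return hits


_PAIR_E = {("G", "C"): -3.0, ("C", "G"): -3.0, ("A", "U"): -2.0,
           ("U", "A"): -2.0, ("G", "U"): -1.0, ("U", "G"): -1.0}


def duplex_oracle(query: str, target: str, bulge: float = 4.0):
    """Exhaustive enumeration of all ungapped / single-bulge duplexes.

    A duplex is a chain of pairs (q[i], r[j]) over the query and the
    reversed target advancing by (1,1) steps plus at most one (2,1) or
    (1,2) step (a single-nt bulge costing ``bulge``).  Returns the minimum
    energy, or None when no duplex scores below 0.
    """
    r = target[::-1]
    n, m = len(query), len(r)
    best = [0.0]

    def extend(i, j, acc, used_bulge):
        e = _PAIR_E.get((query[i], r[j]))
        if e is None:
            return
        acc += e
        best[0] = min(best[0], acc)
        if i + 1 < n and j + 1 < m:
            extend(i + 1, j + 1, acc, used_bulge)
        if not used_bulge:
            if i + 2 < n and j + 1 < m:
                extend(i + 2, j + 1, acc + bulge, True)
            if i + 1 < n and j + 2 < m:
                extend(i + 1, j + 2, acc + bulge, True)

    for i in range(n):
        for j in range(m):
            extend(i, j, 0.0, False)
    return None if best[0] >= 0 else best[0]


def orf_oracle(seq: str, min_codons=120, min_fraction=1 / 3) -> bool:
    """Frame-based ORF scan over both strands."""
    comp = str.maketrans("ACGU", "UGCA")
    stops = {"UAA", "UAG", "UGA"}
    n = len(seq)
    for s in (seq, seq.translate(comp)[::-1]):
        for frame in range(3):
            codons = [s[k:k + 3] for k in range(frame, n - 2, 3)]
            k = 0
            while k < len(codons):
                if codons[k] == "AUG":
                    length = 0
                    j = k
                    while j < len(codons) and (j == k or codons[j] not in stops):
                        length += 1
                        j += 1
                    if length > min_codons and 3 * length >= min_fraction * n:
                        return True
                k += 1
    return False
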