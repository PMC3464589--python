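#!/usr/bin/env python
"""Scan UTR structure neighborhoods for RNA-binding-protein motifs.

Extracts each planted UTR structure plus 50 nt of flanking sequence from
its host transcript, scans with a small PWM panel (one motif planted into a
subset of the neighborhoods, two unrelated), and tests each PWM's
enrichment against dinucleotide-shuffled copies of the same sequences with
BH adjustment across PWMs.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from structatlas import io, motifs, robust_stats

ATLAS = Path(__file__).resolve().parent.parent / "results" / "atlas"
OUT = ATLAS.parent
SEED = 4
PLANTED_CONSENSUS = "GACGUCAG"


def consensus_pwm(pwm_id, consensus, strength=0.94):
    idx = {b: i for i, b in enumerate("ACGU")}
    mat = np.full((len(consensus), 4), (1 - strength) / 3)
    for k, b in enumerate(consensus):
        mat[k, idx[b]] = strength
    return motifs.PWM(pwm_id, mat)


def main() -> None:
    rng = np.random.default_rng(SEED)
    seqs = io.read_fasta(ATLAS / "transcripts.fa")
    # structure neighborhoods: central 60 nt of each transcript's 3' end
    # stands in for the structure locus; +/- 50 nt flanks, clipped
    neighborhoods = []
    for name, tx in seqs.items():
        if not name.startswith("gene"):
            continue
        s = max(0, len(tx) - 130)
        sub = motifs.extract_flanked((s, min(len(tx), s + 60)), tx, flank=50)
        neighborhoods.append(sub)
    # plant the consensus into half of the neighborhoods
    for k in range(0, len(neighborhoods), 2):
        seq = neighborhoods[k]
        pos = int(rng.integers(0, len(seq) - len(PLANTED_CONSENSUS)))
        neighborhoods[k] = (seq[:pos] + PLANTED_CONSENSUS
                            + seq[pos + len(PLANTED_CONSENSUS):])

    panel = [consensus_pwm("planted", PLANTED_CONSENSUS),
             consensus_pwm("decoyA", "UUAGGCAU"),
             consensus_pwm("decoyB", "CAUCAUGG")]
    rows = []
    for pwm in panel:
        n_hit_seqs = sum(bool(motifs.pwm_scan(s, pwm)) for s in neighborhoods)
        p = motifs.motif_enrichment(neighborhoods, pwm, n_shuffles=199,
                                    seed=SEED)
        rows.append({"pwm_id": pwm.id, "sequences_with_hit": n_hit_seqs,
                     "n_sequences": len(neighborhoods), "p": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = robust_stats.bh_adjust(df["p"].to_numpy())
    df["significant"] = df["p_adj"] < 0.05
    df.to_csv(OUT / "motif_enrichment.tsv", sep="\t", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
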