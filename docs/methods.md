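# Methods

This note records the models, parameter choices and numerical decisions
behind `structatlas`, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinates and sequences

All genomic intervals are 0-based, half-open (BED convention). Predicted
RNA structures are strandless ("." strand): comparative structure
prediction does not resolve the transcribed strand, so a prediction on
either strand is treated as a candidate on both, and coding-potential
scanning covers both strands for the same reason. Sequences are handled
internally over ACGU; FASTA input containing T is mapped to U on read.

## Probe classification

A probe receives an exonic class (5′ UTR, 3′ UTR, CDS) when the union of
same-kind gene parts covers at least `min_frac` (default 0.10) of the
*probe's* length. A probe overlapping zero exonic bases is `intronic` (≥ 1
nt inside an intron) and/or `intergenic` (≥ 1 nt outside every gene part);
these are the only classes that may co-occur with each other exclusively. A
probe whose only exonic contact is below threshold gets an empty class set
and is excluded from analysis groups, as are probes whose only class is
CDS. Known-RNA annotation deliberately uses the opposite denominator — the
probe must cover ≥ 10 % of the *reference* RNA — because calling a probe "a
known microRNA" is a statement about how much of the microRNA it captures.
Both denominators are exposed as options.

Structure mapping uses the 1-nt rule: a structure maps to an intergenic or
intronic probe when it overlaps the probe itself (or an intron mapped to
the probe), and to a gene-mapped probe when it overlaps ≥ 1 nt of any gene
part mapped to that probe. Mapping through parts rather than transcripts
avoids double-counting splice variants; it will miss structures in UTR
portions no probe touches.

Coding potential: an ORF is AUG to the first in-frame stop (codon count
excludes the stop; an ORF with no stop extends to the last complete
codon). A transcript is coding when some ORF exceeds 120 codons *and* spans
at least one third of the transcript length.

## Expression statistics

Expression energy is intensity × expressing-cell density per voxel. Region
means are arithmetic means over a region's voxels; `spatial_divergence` is
the sample SD (ddof = 1) of a probe's fine-region means. The
spatial-enrichment score of domain d is
(v_d(E≥e_min)/v_d)/(v_b(E≥e_min)/v_b) with `e_min = 2` by default; the
threshold is treated as unit-free and exposed, since energy units depend on
upstream image processing. Voxels outside every annotated region are
excluded from both numerator and denominator. The score is invariant under
any energy relabeling that preserves the E ≥ e_min indicator — this is
property-tested.

## Robust two-group machinery

Group comparisons use γ-trimmed means (default γ = 0.2, i.e. the largest
and smallest ⌊γn⌋ observations dropped) because ISH measurement errors are
heavy-tailed and not independent. Significance comes from a two-sided
percentile-t bootstrap: each group is centred at its own trimmed mean
(imposing the null), resampled within groups B times (default 2000; 500 in
the scaled runs), and the studentized trimmed-mean difference — with the
Yuen winsorized-variance standard error, the standard choice for trimmed
means — is recomputed per replicate; p = 2·min(tail fractions), capped at
1. A zero observed standard error yields p = 1 when the difference is also
zero and is an error otherwise. Region sweeps BH-adjust across the region
family (11 or 115) and flag adjusted p < 0.25. Measured calibration at
n = 30 per group: type-I error 0.043–0.053 at α = 0.05 over 1000 null
replicates, null p-values uniform (KS p ≈ 0.4).

## Correlation networks and modules

Probe pairs are compared by Pearson correlation of their voxel energy
vectors, brain-wide or restricted to one region's voxels; pairs with a
constant vector are dropped and logged. The working threshold ρ_T is chosen
from the survivor-fraction curve: the smallest 0.05-grid value ≥ 0.8 (the
smallest threshold in practical use; spatial analyses conventionally use
0.9 and brain-wide 0.85) whose surviving-pair fraction drops below
`q_target` (default 1 %); thresholds remain directly settable. Network
edges require strict ρ > ρ_T; components and maximal cliques (size ≥ 3) are
reported — "clique" here is graph-theoretic. Modules come from average-
linkage agglomerative clustering of probes × fine-region mean profiles at
distance 1 − ρ, cut at a height (default 0.5) or at a fixed module count;
this is a deliberate simplification of weighted co-expression module
methods, adequate for planted-structure recovery but not a reimplementation
of them. Each module's focal region is the region with the highest
module-mean energy.

## Motif scanning

PWM columns are probabilities over ACGU; scores are log₂ odds against the
background composition with matrix cells floored at a pseudocount of 0.01
(flooring, rather than additive smoothing, keeps hand-computable scores for
well-determined cells while bounding zero cells). A hit requires relative
score (min-max normalized over the PWM's achievable range) ≥ 0.8, the
common convention for this scanning approach. RNA is single-stranded, so
only the sense strand is scanned. Enrichment of a motif in a sequence set
is tested against dinucleotide-shuffled copies of every sequence: the
statistic is the number of sequences with ≥ 1 hit and
p = (1 + #{null ≥ observed})/(n_shuffles + 1), which is super-uniform under
the null by construction (verified by simulation). The significance
construction is a declared stand-in — field practice varies and is rarely
specified precisely.

## RNA–RNA interactions

The default energy engine is deliberately simple and swappable: antiparallel
local duplexes scored pair-additively (GC −3, AU −2, GU −1 kcal/mol) with
at most one single-nucleotide bulge per duplex at +4 kcal/mol, found by a
two-layer dynamic program (exactly the space its enumeration oracle
explores). Optional per-position opening penalties model target
accessibility and are added for every covered position. Real
nearest-neighbor engines can be adapted in behind the same interface
without touching the statistics. Site length and GC content are measured on
the query side of the duplex.

Significance follows the extreme-value recipe: both sequences of every pair
are dinucleotide-shuffled (Eulerian-walk shuffle preserving exact
dinucleotide counts and terminal bases) `n_shuffles` times (default 100),
the shuffled pairs are re-scored, and each (site length × GC) quantile bin
— 7 × 7 = 49 by default, bins under 50 samples merged into their nearest
populated neighbor — gets a censored maximum-likelihood fit of the
minimum-type Gumbel law P(S ≤ s) = 1 − exp(−e^{λ(s−μ)}), with samples at or
above the censor cutoff (−10 kcal/mol by default) entering only through
their survival probability. A hit's p-value is that law at its bin's
(λ, μ). Reported interactions must satisfy site > 9 nt, MFE < −40 kcal/mol
and p < 1e-5, all strict. Measured calibration on 500 null pairs: KS
uniformity p ≈ 0.03 with conservative small-p tails (P(p < 0.05) ≈ 0.03).

**A ceiling worth knowing about.** Under the default pair energies the best
possible 15-nt site is 15 GC pairs = −45 kcal/mol, while the shuffled
background in the matching covariate bin has λ ≈ 0.3–0.45 and μ ≈ −20 to
−24 even when built purely from unrelated pairs, putting the calibrated
p-value of a −45 hit at ~1e-4 rather than below 1e-5. Planted 15-nt sites
therefore separate perfectly from null pairs by rank (and null pairs
essentially never survive the triple filter), but they cannot clear the
p < 1e-5 bar itself; sites of roughly 18 nt or more, or a steeper energy
model, would be needed. This is a property of the toy energy scale, not of
the calibration machinery.

## The synthetic atlas

The generator defines the study conditions; its defaults are fixed:
20 × 16 × 12 voxel lattice (nominally 200 µm per side), 11 coarse and 115
fine regions, 60 + 60 structured/unstructured UTR probes and 20 + 20
ncRNA probes, baseline energy 5, i.i.d. Gaussian voxel noise with SD 1
clipped at 0, a +2 mean-energy shift for structured groups, one planted
clique of 5 structured-UTR probes at latent strength 0.95, a 20-gene
genome on 200 kb, and 40 interaction pairs of 100 nt with half carrying a
planted 15-nt site of GC fraction 0.8 (GC-rich because under the toy
energies a ~50 % GC 15-mer cannot reach the −40 kcal/mol reporting
threshold at all). These sizes are desk-scale stand-ins for an atlas of
~16,000 probes; calibration runs scale some of them up (e.g. 500 null
pairs, 1000 probes per group) where a property demands it.

Regions are grown by seeded round-robin accretion: each region claims one
random unclaimed neighboring voxel per round, guaranteeing contiguity,
exhaustive coverage, exact nesting of fine inside coarse regions, and
near-balanced sizes. Expression volumes are baseline + group effect +
clique latent + noise, clipped at zero. Clique members share a latent voxel
field (standard normal plus a +2 mean boost in the clique's focal coarse
region) weighted by s·σ against √(1−s²)·σ independent noise, so
within-clique voxel correlations are ≈ s² while marginal variance stays
σ². Note the clique latent itself shifts the structured group's region
means — a configuration with effect_size = 0 is a true null only when
cliques are also disabled. The "expressed above background" flag is mean
energy > 0.5; the real atlas's criterion is upstream of this analysis and
unspecified, so this flag is a stand-in, not an inference of that rule.

The genome generator plants one probe per gene (cycling 3′ UTR, 5′ UTR,
CDS-only, intronic truth classes) plus one intergenic probe per gap, with
structures placed inside the targeted gene part (or overlapping the
intergenic probe by ≥ 1 nt) for alternate probes and decoy structures
placed clear of all probes; one long intergenic probe carries a planted
150-codon ORF so the coding-potential exclusion is exercised. Disjoint
gene slots make the planted truth exact by construction.

What passing tests on this generator do **not** show: realism of brain
geometry (regions are accretion blobs, not anatomy), spatial noise
correlation (noise is i.i.d. per voxel; the bootstrap's robustness to the
real atlas's correlated errors is asserted by the method's design, not
tested here), ISH image artifacts (QC flags are consumed, not simulated),
and real duplex thermodynamics (the pair-additive engine has no stacking or
loop entropy).

## Numerical details

- Bootstrap resampling is vectorized (B × n index matrices); seeds are
  explicit everywhere and derived per stage from the run seed.
- The censored Gumbel fit optimizes over (μ, log λ) with Nelder–Mead from
  Gumbel moment estimates of the uncensored part; it requires ≥ 30
  uncensored samples and errors on degenerate (constant) input, naming the
  offending bin when called through the binning layer.
- BH adjustment is the standard step-up with monotonicity enforced by a
  reverse cumulative minimum, capped at 1.
- Threshold grids in `select_threshold` are rounded to 10 decimals to avoid
  float-accumulation artifacts; if no grid value meets the survivor target
  the top grid value (1 − step) is returned with a warning.
- Duplex tracebacks compare energies with an absolute tolerance of 1e-9;
  ties in module assignment and clique listings are resolved by sorted
  order for determinism.
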