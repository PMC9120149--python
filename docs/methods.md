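# Methods

This note documents the models, conventions and numerical choices behind
`paralintron`, the assumptions they rest on, and what the synthetic test
bed does and does not establish about real data.

## Coordinate conventions

GFF3 coordinates (1-based, inclusive) are converted once, at parse time,
to 0-based half-open intervals; every internal type uses the latter. The
GFF3 phase column is ignored: intron phases are recomputed from CDS
coordinates, since annotation phase fields are frequently wrong. A
transcript whose concatenated CDS length is not a multiple of three is
flagged unmappable and contributes `?` (missing) downstream; a trailing
stop codon is trimmed before protein-length checks.

An intron's phase is its coding offset modulo 3. The **anchor
convention**: an intron is attached to the residue whose codon contains
the first coding nucleotide 3′ of the intron — the residue following the
intron for phase 0, the interrupted residue for phases 1 and 2. The
analyses only ever ask whether two introns occupy the *same* (alignment
column, phase) pair, and any consistent anchor convention preserves that
equality; this one is applied uniformly, including in the simulator's
emission path, so round-trips are exact. Positions are compared as exact
(column, phase) pairs; near-misses (±1 column) are never merged, because
no principled sliding-window rule exists and merging would manufacture
spurious sharing.

Relative intron position in a gene is computed after masking alignment
columns with a gap fraction ≥ 0.9 (only `-` counts as a gap; `X` and
ambiguity codes are residues). The position is the intron column's rank
among kept columns divided by the number of kept columns; an intron
falling in a masked column takes the rank of the nearest kept column 5′
of it (0 if none exists). Masking removes ragged alignment edges that
would otherwise compress the relative scale.

## Ancestral reconstruction

Each intron position evolves on the rooted species tree as an
independent two-state (absent/present) Markov chain with per-branch
transition probabilities: gain `g_b = P(0→1)` and loss `l_b = P(1→0)`
on branch `b`, plus a root prior π. Parameterising by per-branch
probabilities rather than rate × branch length keeps the model usable on
topology-only trees; branch lengths, when present, are not consumed by
the reconstruction. A single rate category is shared by all positions —
no rates-across-sites variation. This is a deliberate simplification;
its main visible consequence is discussed under *Limitations*.

Likelihoods use Felsenstein pruning over the two states, vectorised
across positions, with per-node rescaling against underflow. `?`
observations contribute a partial likelihood of 1 for both states.
Multifurcations (including the unresolved-root species-tree variant) are
handled by taking products over all children; collapsing a zero-effect
branch provably leaves likelihoods unchanged and is tested.

**Observability.** An intron table cannot contain a position absent in
every species, so the estimation likelihood is conditioned on
observability: each pattern's likelihood is divided by `1 − p0`, where
`p0` is the all-absent pattern's probability. Unconditioned ML would
bias gain rates downward.

**Estimation.** Rates are estimated by expectation–maximisation. The
E-step computes, with the up–down recursion, each branch's posterior
joint distribution over (parent state, child state); the M-step sets
`g_b` and `l_b` to the expected transition fractions and π to the mean
root posterior. The observability conditioning is implemented exactly by
augmenting each iteration with a phantom all-absent pattern of weight
`N·p0/(1 − p0)` — the expected number of unobservable positions — which
makes the EM fixed point the conditional MLE. Multi-start with seeds
1..5 (uniform random initial probabilities in [0.02, 0.5]), best final
conditional log-likelihood wins, ties broken by the first seed;
convergence at a relative log-likelihood change below 1e-8, capped at
2000 iterations. All of this is deterministic.

**Identifiability and estimation modes.** With fully free per-branch
gains and losses the root prior is *not identifiable*: lowering π while
raising the gain probabilities on the root's edges leaves the leaf
distribution unchanged, and on simulated data the conditional likelihood
of such a tilted solution can exceed the truth's. Root-state inferences
under that parameterisation are therefore arbitrary along a ridge. The
estimator hence offers three modes: `tied` (one gain, one loss),
`loss` (per-branch losses, one shared gain — the default, and the
identifiable analogue of "loss-dominated" intron evolution) and `full`
(both per-branch, with the caveat above documented on the function). The
pipeline defaults to `tied`, which is the statistically sane choice at
the data volumes a synthetic or desk-scale run produces; `loss` is
exercised by the parameter-recovery experiments (median relative error
of per-branch loss probabilities ≈ 4% at 5000 positions on a 20-leaf
tree).

**LECA calls.** A position is called a LECA intron when its posterior
presence at the LECA node is at least 0.5 (inclusive). The LECA node is
the species-tree root under the Opimoda–Diphoda rooting; under the
unresolved-root variant the root of the multifurcation plays the same
role. The threshold is configurable but 0.5 is the default everywhere.

**Ancestral counts.** The expected intron count at a node sums the
posterior presence over observed positions and then adds the
unobservable mass: `N·p0/(1 − p0)` phantom positions, each weighted by
the posterior presence *conditional on the all-absent pattern*. An
alternative correction — dividing the observed sum by `1 − p0` — was
rejected: it credits never-present positions with the observed
positions' high posteriors and overestimated the ancestral density by
an order of magnitude on mixed synthetic data (LECA introns plus
post-LECA novel gains), whereas the implemented estimator tracks the
simulated truth within a few percent.

## Paralog analysis

A family's orthogroups descend from pre-LECA duplications of one or more
*acquisitions* (genes that entered the proto-eukaryotic lineage
independently). The paralogy map is read off the annotated gene tree:
each leaf's acquisition is its nearest ancestral acquisition node (the
root acts as an implicit acquisition if none is annotated); OG pairs
under one acquisition are paralogous, pairs under different clean
acquisitions are separate acquisitions. An acquisition with a
duplication or another acquisition among its ancestors is *ambiguous* —
its OGs could descend from an already-duplicated ancestor — and is
excluded from both the paralog and the control sets. (Trees with
prokaryotic interleaving would also support a sister-group adjacency
rule; in trees without outgroups, such as the simulator's, adjacency
carries no signal, so ancestry is the criterion used.)

LECA introns are transferred to merged-alignment coordinates through any
OG row with a residue in the anchor column (gap-only edits provably do
not move a position, and this invariance is tested). An intron is
**shared** when an equivalent (merged column, phase) LECA intron exists
in at least one paralogous OG; introns shared *only* with separate
acquisitions are parallel-gain evidence and are excluded from both the
numerator and denominator of the shared fraction; introns of OGs with no
paralogous partner at all are excluded likewise.

The **parallel-gain control** pools, over families, a 2×2 table of
[shared, unshared] × [paralogs, separate acquisitions] and applies a
two-sided Fisher exact test. Sharing is only ever evaluated within a
family. Note a statistical caveat inherited from the counting rule (the
fraction is over introns, not positions): shared introns arrive in
pairs, one in each carrier OG and always in the same arm of the table,
so the per-table counts are overdispersed roughly twofold relative to
the hypergeometric null. The Fisher p value is therefore conservative as
evidence *for* paralogous sharing in the real analysis (where the effect
is enormous), but it is anticonservative as an exact null calibration:
under a perfectly label-symmetric simulated null, per-seed Fisher p
values are not uniform (≈16% fall below 0.05). The calibration test in
the suite asserts strict uniformity and documents this; the substantive
claim — equal shared fractions in both arms — holds to three decimal
places over 1200 simulated families per arm.

**Dollo parsimony.** On a gene tree, each intron is gained exactly once
— on the branch entering the root of the minimal subtree spanning its
carrier OGs — and lost once on every branch leaving that subtree toward
a carrier-free clade. Reconstructed loss counts equal the exhaustive
minimum over all single-gain placements (tested against an independent
oracle on 200 random trees). A duplication node "has pre-duplication
introns" when the spanning subtree of at least one intron passes through
it; a secondary flag records whether a more ancestral duplication was
intron-bearing. Multifurcations are used as-is. Event totals distinguish
branches entering internal nodes (gains/losses before duplications) from
branches entering leaves (events on the branches leading to the LECA
families).

**U12 annotation.** A position is annotated U12 when at least three
distinct species predict U12 at it; otherwise U2 (including positions
with no prediction). The threshold is configurable.

**Group fractions.** Units (LECA introns or duplications) may belong to
several functional categories and contribute to each; categories with
fewer than 10 units are dropped from reporting and testing (the same
threshold applies to pairs and duplications groupings). Heterogeneity
across categories uses a χ² contingency test; all pairwise comparisons
use Fisher tests with Benjamini–Hochberg adjustment. For the
three-main-group test, units whose categories span more than one main
group are excluded.

## Statistics

All tests are two-sided. χ² contingency tests carry no continuity
correction (classical degrees of freedom); Fisher's exact test uses the
probability-mass two-sided rule; the two-sample Kolmogorov–Smirnov test
uses the exact p value when `n·m ≤ 10⁴` and the asymptotic Kolmogorov
distribution otherwise; multiple comparisons are adjusted with
Benjamini–Hochberg (the default reading of "false discovery rate"
control; BY was the alternative); binomial fractions get Wilson score
intervals. The implementations are thin wrappers over scipy and
statsmodels, validated against independent oracles: full hypergeometric
enumeration for every 2×2 table with N ≤ 12, an explicit ECDF scan for
the KS statistic, and hand-computed closed forms. One spec-level
correction surfaced here: BH adjustment is *not* idempotent (p =
[0.1, 0.5] adjusts to [0.2, 0.5], which re-adjusts to [0.4, 0.5]); the
property suite asserts monotonicity and capping instead.

## The synthetic test bed

The simulator generates the history the pipeline is built to recover,
with a complete event-level truth log (replaying the log reproduces
every node state bit-exactly, and this is tested).

*Stem phase.* Each family enters as `n_acquisitions` independent genes
(default 1); each acquisition undergoes `n_duplications` duplications
(default 2) at times drawn uniformly on the stem (or pinned via
`duplication_times`, e.g. at t = 0 for post-duplication-only gain
experiments). Between events each lineage performs a Gillespie walk:
intron gains as a Poisson process (`gain_rate_stem`, default 12 per
lineage per stem; phases drawn from `phase_weights`, default
(0.48, 0.30, 0.22) — the genome-wide phase bias with phase 0 most
common and phase 2 rarest; positions uniform over residues), and losses
at `loss_rate_stem` per present intron (default 1.0) with victim
selection proportional to `exp(bias · relative position)` (default bias
2.0) — the simplest monotone 3′ bias consistent with loss by reverse
transcription of the intronless mRNA followed by recombination, which
preferentially erases 3′ introns. Fresh gains never re-use a position;
with `parallel_gain_rate = 0` every history is therefore
Dollo-consistent. Parallel gains re-insert at a position already used
elsewhere in the family (probability `parallel_gain_rate` per gain,
default 0), which is what the separate-acquisition control is calibrated
against. These defaults yield LECA densities around 8–10 introns per OG
and shared fractions in the 20–35% range, the regime the analyses
operate in.

*Post-LECA phase.* Every LECA intron of every OG evolves down the
species tree (default: balanced 8-leaf tree) as a two-state chain with
per-branch gain/loss probabilities (defaults 0.01 / 0.2 — loss-dominated
evolution; scalars or per-branch mappings). Novel post-LECA introns
arise on branches at `post_leca_gain_rate` per branch per OG (default
0.3) and evolve below their gain branch. Positions absent from every
extant species are dropped, mirroring the observability of real tables.

*Emission.* Proteins are random sequences per family with per-species
substitutions (rate 0.05/residue); genes are realised genomically by
seeded uniform back-translation, GT…AG introns of 60–120 nt inserted at
the exact coding offsets, random strand per gene, and GFF3/FASTA output.
Alignments are written as the *true* alignments (no aligner runs):
gap-free in the default substitution-only mode, so the merged column of
a residue is its index; an optional indel mode inserts all-row gap
columns (different ones per OG and for the merged alignment) to exercise
column-transfer bookkeeping with known truth. All randomness derives
from the single config seed through named streams (per family, per
stage), so subsets are independently reproducible.

*What the simulator does not emulate:* realistic sequence evolution (no
codon models, no rate heterogeneity, no real indel processes), aligner
error (true alignments are emitted, so tests say nothing about
MAFFT-induced column noise or merged-alignment misalignment between
paralogs), annotation error (no retained introns, fused genes, or wrong
gene models beyond the deliberate unmappable-transcript paths), gene
loss on the stem, and rates-across-sites variation. Green tests
therefore establish the correctness of the *bookkeeping and inference
machinery* under a faithful generative model, not robustness to the
noise sources of real genome annotations.

## Problem sizes

The default test suite and the acceptance script are sized to run
single-threaded in well under a minute each of pure computation per
experiment: enumeration oracles on 200 random trees of ≤ 6 leaves
(likelihoods and posteriors agree to < 1e-10), Dollo oracles on 200
trees of ≤ 8 leaves, coordinate round-trips over ~1400 planted introns,
rate recovery on 5000 positions × 20 leaves, and 50–200-seed Monte Carlo
calibrations. The acceptance script's pipeline run uses 8 families × 2
acquisitions × 2 duplications on an 8-species tree.

## Known limitations

- The two-state model assigns one category to all positions. On data
  mixing root-present LECA introns with sparse post-LECA novel gains,
  the fitted root prior compensates downward; per-position posteriors
  (and hence LECA calls at the 0.5 threshold) remain data-dominated and
  robust in simulation, but the fitted π should not be read as the
  fraction of positions present in LECA.
- Per-branch gain estimation (`full` mode) cannot pin the root prior
  (see identifiability above).
- The Fisher control test is anticonservative as an exact calibration at
  intron-level counting (see the pairing discussion above).
- Intron positions are matched by exact (column, phase) equality; local
  misalignment between paralogs in a merged alignment translates
  directly into missed sharing. The merged coordinates are trusted as
  given.
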