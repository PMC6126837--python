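# Methods

## The two-slice transition model

Along a phased nucleosome array the mark state of consecutive nucleosomes is
modeled as a stationary process: a transition network on 2n nodes — the n
mark variables X at the "before" nucleosome (slice t−1) and the same n at
the "after" nucleosome (slice t) — repeated along the array. Stacking every
ordered neighbor pair into rows (X[t−1] ‖ X[t]) reduces transition-network
learning to ordinary Bayesian-network structure learning on 2n-dimensional
data under tier constraints: no edges among before-slice nodes (the before
slice is the conditioning context, its internal structure is not modeled),
and no edges from the after slice back to the before slice. Only
before→after and intra-after edges are admissible, and any admissible graph
is acyclic exactly when its intra-after subgraph is.

The direction of "time" along the array is a modeling choice per anchor
kind: outward from the center on each side of TSSs, CTCF sites and enhancer
centers (for enhancers, toward the nearest TSS), and upstream→downstream in
the transcription direction on both sides of TTSs. Minus-strand genes are
evaluated on the flipped axis throughout.

## Pair selection

Regularly phased nucleosomes are those with inflection-point width within
70–90 bp (inclusive), both summit-to-summit neighbor distances within
160–400 bp, and — by default — MainPeak shape class. The width and spacing
criteria are mandatory and the MainPeak criterion is a flag; an `any_two`
mode retains nucleosomes meeting any two of the three, since the looser
reading is also defensible. Chromosome-terminal calls lack a neighbor and
always drop.

Nucleosomes are indexed into slots by distance from the anchor (−1, +1
nearest the center; CTCF/enhancer flanks indexed 1, 2, … outward on each
side). Adjacent slots form candidate pairs; a pair is excluded when the two
summits are closer than 160 bp or further than 400 bp apart (slot adjacency
can bridge a gap left by a filtered-out nucleosome, and such a pair is not
a phased neighboring pair). Center-inclusion levels control pairs touching
the anchor: level 1 requires both members strictly on one side; level 2
additionally admits pairs with one footprint overlapping the anchor point;
level 3 admits all adjacent pairs including the one spanning the center.
For cross-center pairs at TSS/CTCF/enhancer anchors the member whose summit
is nearer the center is "before" (ties: genomic left). Pairs with either
member inside the ±2 kb window of two or more anchors are excluded against
the union of the anchor sets in play, to avoid signal spillover.

## Signal assignment

Each ChIP tag is reduced to a point: start + 73 bp on the plus strand,
end − 73 bp on the minus strand (half the canonical 147-bp nucleosome,
centering single-end MNase-ChIP tags on the dyad), unshifted midpoint when
the strand is unknown; an unshifted-midpoint rule is available behind a
flag. A point counts toward the nucleosome whose footprint [start, end)
contains it. Counts are scaled to tags-per-ten-million by default for
cross-library comparability; raw counts are available. Occupancy
normalization divides each nucleosome's signals by its MNase occupancy,
with 0/0 → 0 and signal-without-occupancy flagged and zeroed.

## Scoring and search

The per-node score is a λ-weighted Gaussian BIC,

    score(v | Pa) = −(m/2)·ln(RSS/m) − λ·(|Pa|+1)·ln(m)/2,

with RSS from the least-squares regression of v on its parents with
intercept, λ = 2.0 by default (the penalty weight governing sparsity), and
at most 4 parents per node (the consensus networks of interest have small
in-degrees, and the cap bounds the exhaustive oracle used in testing).
RSS is floored at machine epsilon times the node's total variance, so a
perfect fit scores finitely yet above any noisy alternative. A
nonparametric alternative replaces RSS by the leave-one-out residual sum of
a Nadaraya–Watson regression (Gaussian kernel, median-heuristic bandwidth
on standardized parents); it captures saturating links the linear score
misses, at O(m²) cost, and is selectable via `ScoreConfig(score=
"kernel_regression")`. The Gaussian BIC is the reference score and is what
all quantitative checks run on.

Search is deterministic: hill climbing from the empty graph over
add/delete/reverse moves restricted to admissible acyclic graphs, applying
the single best improving move, ties broken lexicographically by (source
label, target label, move kind). Plain hill climbing has a reproducible
failure mode here: when an intra-after dependency is near-deterministic,
the two orientations of its edge score almost identically at the moment the
edge is introduced, and a wrong early choice can only be repaired by a
reverse followed by a delete — two moves, so a strictly-improving climber
never takes the first. The search therefore finishes with a short tabu
phase: up to 10 consecutive non-improving steps taking the best move that
leads to a not-yet-visited graph, returning the best-scoring graph ever
visited. The procedure remains deterministic (no randomness is drawn) and
row-order invariant; on strong-signal three-mark instances it attains the
exhaustive maximum over all admissible DAGs in 20/20 test instances,
where plain hill climbing managed 7/20.

## Compelled edges

The learned DAG is reported as a PDAG. Every before→after edge is compelled
outright — the tier constraint is background knowledge fixing its
direction. Within the after slice, v-structures (a→c←b with a, b
non-adjacent) seed orientations, and Meek's rules R1–R4 propagate them to
closure; remaining intra-after edges are reversible (undirected). The
implementation is validated exhaustively: for every DAG on 2 before + 4
after nodes (139,008 graphs) the compelled/reversible labeling equals the
orientation intersection over the constraint-respecting equivalence class
(same skeleton, same v-structures, tier-consistent), enumerated by brute
force.

## Stability and consensus

Ten networks are learned on independent uniform 90% subsamples (without
replacement; per-fold subsamples drawn from one seeded generator). Edge
records — a compelled edge with its direction, or an undirected skeleton
edge — recurring in ≥ 7 of 10 PDAGs form the cross-validated network.
Stability is summarized by sweeping the recurrence threshold from 10 to 0
against the full-data PDAG as reference over the universe of admissible
edge records, giving an ROC curve and its trapezoid AUC. The reference is
the full-data network because the notion being measured is resampling
agreement, not truth recovery.

Consensus across settings keeps records present, with compatible
orientation (same direction, or undirected matching either), in at least
⌈fraction·N⌉ of N networks (fraction 0.5 by default). If both directions
of a skeleton edge independently reach the threshold the edge is reported
undirected, since its direction is not consensual.

## Chromatin-pattern metrics

**NFR geometry.** Length is the summit-to-summit distance between the −1
and +1 nucleosomes; depth is 1 − NFR/(0.5·(up + down)), where NFR is the
mean 10-bp-bin occupancy of the summit-to-summit interior and up/down are
the mean occupancy over the two flanking nucleosome footprints; size is
length × depth. Records are invalid when a flanking nucleosome is missing,
the summits are more than 250 bp apart, or the flanking signal is zero.
The interior and footprint windows overlap by construction (the formula's
regions are not disjoint); bins are selected by midpoint. Depth can be
negative when the interior exceeds the flank mean; such records stay valid
and flagged by sign.

**Phasing index.** The +1…+4 template marks peak bins at +100–159,
+290–349, +480–529 and +660–719 bp and valley bins at +210–269, +390–439
and +560–619 bp (10-bp bins; the 20–50 bp spacers between a peak and the
neighboring valley are gaps and excluded from both vectors). An observed
profile is binarized on the same frame: a bin is 1 when its midpoint lies
inside a called nucleosome footprint. Both 0/1 vectors are normalized to
distributions P₀, P₁ and the index is 1 − [H((P₀+P₁)/2) − (H(P₀)+H(P₁))/2]
with base-2 logarithms, so the divergence term is bounded by 1, the
template scores 1 against itself and 0 against its complement. An
alternative literal reading, 1 − H(mix) − (H₀+H₁)/2, is kept behind a flag;
it is not bounded in [0, 1] and is not used by default. All-zero profiles
are skipped (normalization undefined).

**Profile clustering.** Spherical k-means (L2-normalized profiles, so
Euclidean k-means acts on cosine geometry) for each k in range, selecting k
by the BIC of a spherical Gaussian-mixture approximation (k·d centroid
parameters plus one shared variance). Deterministic given the seed;
all-identical input degenerates to k = 1.

**Binned correlations.** For an inferred Mark-A→Mark-B edge, pairs with
both Mark-A(before) and Mark-B(after) zero are excluded; the rest are
ranked by Mark-A(before) descending (stable ties), grouped into
consecutive bins of 100 pairs (final partial bin dropped), and Pearson's r
is computed across bin means. The nonlinear variant log-transforms Mark-A
as log₁₀(x+1) before ranking and averaging — base and zero-handling are
implementation choices, zeros being admissible after the either-nonzero
filter. With bin size 1 the statistic reduces to the plain pairwise
coefficient. The on-site variant reads Mark-B at the same before
nucleosome, as the within-nucleosome baseline. Cross-group regression
ranks anchors by a conditioning variable (e.g. expression), splits them
into 10 equal groups (remainder spread over leading groups), and fits
per-group means by OLS, reporting slope, adjusted R² = 1−(1−R²)(g−1)/(g−2),
and the two-sided slope p-value.

## Synthetic data

The landscape generator emulates the canonical promoter architecture: per
anchor, a −1 nucleosome, an NFR of sampled summit-to-summit length
(default 200 ± 20 bp, within the 250 bp validity bound and the 160–400 bp
phasing window), and arrays on both sides at a sampled repeat length
(default 190 ± 5 bp — the nucleosomal repeat typical of phased arrays)
whose jitter grows 2 bp per slot away from the anchor, emulating phasing
decay. Widths are 80 ± 3 bp, 95% of calls are MainPeak, anchors sit 20 kb
apart on one synthetic chromosome, and the occupancy track is a sum of
40-bp Gaussian bumps at the summits. Signals follow a planted transition
model: each (anchor, side) chain of pairs is walked outward; chain heads
and parent-free marks draw i.i.d. log-normal baselines (right-skewed,
nonnegative, mimicking tag counts; the field's data offer no canonical
signal distribution), and each dependent after-mark is intercept + linear
or log-saturating link contributions + Gaussian noise (default sd 0.3),
floored at 0 to respect count nonnegativity. Walking chains — rather than
sampling each pair independently — keeps the per-nucleosome matrix
single-valued where one pair's after nucleosome is the next pair's before.

What the generator does *not* emulate: sequence-dependent positioning,
overlapping/fuzzy nucleosomes, copy-number and mappability artifacts,
antibody efficiency differences between marks, and between-mark baseline
correlations. Tests passing on this material demonstrate the machinery —
selection logic, score consistency, orientation identification, stability
and metric arithmetic — not biological recovery on real chromatin.

## Problem sizes and reproducibility

The shipped study conditions use 380 anchors (≈ 3,800 nucleosomes,
≈ 2,000 level-1 pairs), 3–4 marks, 10×90% resampling, and 10–20 replicate
seeds per claim; structure learning on such an instance takes well under a
second, and the complete verification run a few minutes. Every stochastic
step takes an explicit seed; the pipeline derives per-stage seeds from one
master seed, writes a provenance record (config hash, seeds, row counts),
and identical configurations produce byte-identical outputs.

## Known limitations

- The Gaussian BIC score assumes linear links with additive noise;
  saturating links are detectable via the kernel score but at quadratic
  cost, and neither models count noise (a negative-binomial likelihood
  would).
- Compelled-edge semantics are relative to the tier constraints and the
  learned skeleton; they identify orientation within the equivalence
  class, not causality against latent confounders.
- The stability AUC measures resampling agreement with the full-data
  network, so a consistently wrong network can still look stable.
- Pair selection assumes non-overlapping calls after phased filtering;
  heavily overlapping deconvolved calls would need upstream resolution.
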