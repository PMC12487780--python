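# Methods

## Dynamical model

Each of the N genes carries a binary activity x_i; the signed adjacency
A_ij ∈ {−1, +1} encodes activation or inhibition of gene *i* by gene *j*.
The update rule is the integer threshold rule: a gene switches on when its
input sum Σ_j A_ij x_j is positive, off when negative, and keeps its
current value at zero input. Dynamics are asynchronous: at each step one
gene is drawn uniformly at random among the *unstable* genes (those whose
bit disagrees with the rule) and flipped. Restricting the draw to unstable
genes means every accepted step is exactly one flip, and the step counter
counts accepted flips; this is the convention used for all step statistics.
A state with no unstable genes is a fixed point.

The all-zero state is always a fixed point of this rule (zero input keeps
the bit), and in practice all sampled trajectories on the networks studied
here converge. Because asynchronous threshold networks *can* cycle in
general, relaxation carries a guard of `100·N` flips and raises a
non-convergence error (carrying the last state) rather than looping;
ensemble sampling can optionally tolerate and count a configured fraction
of such chains.

Perturbations (overexpression = clamp to 1, knockdown = clamp to 0) are
applied to the start state before relaxation, remove the clamped genes from
the unstable-candidate set, and are never released.

### Random numbers

Ensembles are processed in fixed-size chunks of 4096 chains; each chunk's
initial states and update draws come from a child stream spawned
deterministically from the master seed, so a given seed reproduces an
ensemble bit-for-bit and chunks could be processed in parallel without
shared state. Screens key a child stream per (gene, protocol); the assay
spawns one stream per trajectory.

## Observables

* **Phenotype scores** Φ_PS, Φ_EM: active positive markers minus active
  negative markers per axis. The built-in panel holds 11 somatic, 7
  pluripotency, 10 mesenchymal and 5 epithelial genes (33 total). Marker
  genes absent from a roster (common after intersecting with an expression
  matrix) are dropped from the sums with a logged warning rather than an
  error.
* **Pseudo-energy** E = −Σ A_ij s_i s_j over each directed edge once
  (s = 2x − 1); a mutual pair j⇄i contributes two terms. The single-site
  version sums a gene's incoming edges only, so site terms add exactly to
  the global value. The quantity scores regulatory consistency of a
  nongradient system; it is not a thermodynamic energy and the "barrier"
  below is not a rate-limiting activation barrier.
* **Driving force** counts genes mandated to flip; zero input contributes
  nothing, so DF = 0 exactly at fixed points. Clamped genes are excluded by
  default (they cannot respond); a flag includes them for expression data,
  where no clamp exists.
* **Distances**: Hamming distance over a gene subset (full roster = the
  screen displacement Δ); population heterogeneity is the mean pairwise
  distance over all unordered pairs, computed in closed form from per-gene
  ON counts.

## Landscape analysis

Steady states are embedded by PCA on the raw 0/1 matrix *with multiplicity*
(each sampled relaxation contributes one row). Component indices are
1-based and configurable; the default (2, 3) matches the curated-network
convention of the original study, while on the synthetic stand-in the
somatic↔pluripotent split carries ~54% of the variance and lives on PC1,
so the stand-in analyses select components (1, 2). The explained-variance
ratios are exposed so users can audit the choice. The PS-correlated
component is the reaction coordinate; its sign is oriented so the
coordinate *anti*-correlates with Φ_PS (SM states right, PE states left —
reprogramming progresses right to left), and the second axis is oriented
against Φ_EM the same way.

States are "phenotypically significant" when both scores rank in the joint
top/bottom q (default 0.20) fractions: SM (bottom/bottom), PE (top/top),
SE, PM. Ranks are averaged at ties, so an all-equal score vector yields no
extremes. KNN smoothing (default k = 5, self included) is available for
landscape colouring; analyses use raw values unless stated.

Profiles along the reaction coordinate use equal-width bins (default 30)
and report a bin's mean only when it holds at least `min_count` (default
10) points. Barrier statistics compare a perturbed profile with a reference
profile on shared bin edges: ΔE1 is the perturbed-minus-reference value at
the initial-end bin (first populated bin from the SM side), ΔE2 the
reduction in barrier height (profile maximum minus initial-end value), and
ΔPC the absolute shift of the profile argmax, flagged with whether it moved
toward the initial end.

Capacity C(x) of a steady state is the number of sampled initial states
relaxing to it. Its tail is fitted as a discrete power law by maximum
likelihood with Hurwitz-zeta normalisation; when no cutoff is fixed, x_min
is scanned over the smallest distinct values and chosen by minimal
Kolmogorov–Smirnov distance (tails under 10 points are skipped). An
all-equal capacity vector yields an explicitly undefined fit, not an error.

## Screens

The reprogramming assay clamps a factor (default Pou5f1 = 1) in every state
of a start pool (canonically the SM-class fixed points, repeated to sample
the stochastic update order), relaxes, and labels a trajectory productive
when ΔΦ_PS exceeds the threshold (default 6, strict: a change of exactly 6
is unproductive and logged). The OE/KD screen clamps every gene to 1 and to
0 from every start state and records the full-roster displacement Δ; genes
are ranked by the Poisson maximum-likelihood rate (the sample mean of Δ,
used purely as a ranking statistic), with report filters Δ ≥ 32 occurrences
> 10 and mean Δ > 1. High-susceptibility genes are those flipping in at
least half (configurable) of the productive start/final pairs.

## Expression binarization

Single-cell matrices are first filtered to cells whose expressed-gene count
(entries > 0) lies inside the closed [5th, 95th] percentile band (linear
interpolation); bulk matrices skip this filter. Each gene is then
binarized by a two-component Gaussian mixture on log2(x+1) values. Exact
zeros do not enter the fit and are assigned silent: in sparse single-cell
data zeros are dominated by dropout, and including them hands the mixture a
zero-inflation mode instead of the on/off split. The higher-mean component
is active; a sample scores 1 iff its posterior for that component exceeds
0.5 (a tie is inactive). Genes whose positive values are (near-)constant
binarize to zeros-vs-positive when exact zeros exist and to all-silent
otherwise. Because of the +1 pseudo-count, binarization is only
approximately invariant to rescaling a gene by a positive constant; the
test suite checks ≥95% label agreement under a 16× rescale. Consequently,
bit-recovery accuracy on synthetic data is evaluated on observed
(non-dropped) entries — a dropped entry carries no recoverable signal.

Network observables for expression samples are computed on the sub-network
induced by the genes common to the matrix and the model roster (edges with
a missing endpoint are dropped and counted in the log), and the embedding
used for experimental trajectories is fitted on simulated states of that
same sub-network.

## Synthetic data

The generators emulate the study's inputs so that every stage is testable
offline:

* **Random signed networks** — ordered edges sampled uniformly without
  replacement (self-loops off by default; accepted when present in files),
  each activating with probability `p_act`.
* **Planted bistable networks** — every sampled edge j→i gets the sign
  s_i·s_j of the anchor state, which satisfies the edge; complementary
  anchors (the default, mirroring the binary-opposite somatic/pluripotent
  expression pattern) are then both fixed points with single-site
  pseudo-energy exactly −(in-degree) at every gene, and a fraction `f_c` of
  signs is flipped to inject frustration. The anchor energy rises by
  exactly 2 per flipped edge, giving a clean frustration dial.
* **Bimodal expression** — entries draw from Normal(μ_off, σ) or
  Normal(μ_on, σ) by the ground-truth bit, truncated at zero (expression is
  nonnegative), with independent dropout zeroing. Defaults μ_off = 1,
  μ_on = 6, σ = 1 give the ≥5σ separation typical of a clearly bimodal
  log-scale gene.

### The reprogramming stand-in

`reprogramming_network` is a planted bistable network shaped like a curated
reprogramming network: 88 genes (the 33 marker genes plus auxiliary genes,
split evenly between the two programs) and 387 edges. Topology follows the
two-program architecture of such networks rather than a uniform random
graph, because threshold dynamics make two structural facts decisive:

1. a gene whose inputs are all activating can never switch off, so every
   periphery gene receives 1–3 activators from its own program core *and*
   1–2 inhibitors from the opposite core;
2. a program core whose every member is directly repressed can never be
   nucleated by a single overexpressed factor (+1 can never beat ≥1 active
   repressors), so all direct somatic repression converges on the master
   triad Pou5f1/Sox2/Nanog, which densely activates the secondary core
   factors (Esrrb, Klf4, Myc, Sall4); secondaries feed back onto the
   masters and are silenced indirectly via sparse mesenchymal-periphery
   repression.

With `f_c = 0.1` (≈39 flipped signs) the two anchors are low- but not
zero-frustration attractors in a rugged landscape. This reproduces the
regime of interest: random starts settle into two program basins; clamping
a single master factor ON from somatic-mesenchymal fixed points reprograms
only a few percent of trajectories; and those events start preferentially
from *frustrated* SM states whose repressors are incompletely engaged —
the mechanism the analysis pipeline is designed to expose.

What the stand-in does not emulate: the specific curated wiring of any real
network (its step statistics, group energies and barrier magnitudes differ
from published values for the real 88-gene network), combinatorial
regulation beyond additive thresholds, and expression-level noise in the
Boolean dynamics. Tests passing on the stand-in therefore validate the
*pipeline* — the dynamics, observables, screens and statistics — not the
biology of any particular curated network, which users supply as a TSV edge
list.

## Problem sizes

Default analysis sizes: 10^5 random starts for ensemble statistics
(Monte-Carlo SEM of the mean step count ≈ 0.1), SM-class fixed points × 10
stochastic repeats for the assay (~3·10^3 trajectories), 400 unique fixed
points × 88 genes × 2 protocols for the screen (~7·10^4 relaxations), and
30 bins with min_count 10 for profiles. The batched simulator relaxes ~10^4
88-gene chains per second on one CPU, so the full analysis completes in
well under a minute.

## Known limitations

* Additive threshold logic only; no per-gene Boolean functions.
* The pseudo-energy landscape is descriptive: barrier heights are not
  transition rates.
* The discrete power-law fit reports a point estimate (no goodness-of-fit
  p-value or bootstrap CI).
* The GMM binarizer is univariate per gene; it ignores cross-gene
  covariance and batch structure, and assumes roughly symmetric components
  on the log scale.
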