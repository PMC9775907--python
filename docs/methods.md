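# Methods

## The model

`motifres` studies how two canonical cell-fate decision motifs — the toggle
switch (TS: two mutually inhibiting genes A ⊣ B, B ⊣ A) and the toggle triad
(TT: three genes with all six ordered inhibitions) — behave when they are not
isolated but wired into a larger random gene regulatory network.  Each node
T follows

    dT/dt = G_T · Π_i Hs(P_i; P_i0, n, λ⁺) · Π_j Hs(N_j; N_j0, n, λ⁻) − k_T · T

where the product runs over T's activating inputs P_i and inhibiting inputs
N_j and Hs is the shifted Hill function

    Hs(B; B0, n, λ) = B0ⁿ/(B0ⁿ + Bⁿ) + λ · Bⁿ/(B0ⁿ + Bⁿ),

a regulation multiplier that equals 1 with no regulator present and
saturates at the fold change λ (λ > 1 activation, λ < 1 repression); at
B = B0 it is (1+λ)/2.  Nothing about a single parameterization is claimed;
instead the *generic* dynamics of a topology are characterized by an
ensemble of thousands of randomized kinetic parameter sets (the random
circuit perturbation, RACIPE, formalism), each integrated from many random
initial conditions to collect its stable steady states.

## Parameter randomization

Per node: production G ~ U[1, 100] (molecules/time), degradation
k ~ U[0.1, 1] (1/time).  Per edge: integer Hill coefficient n ~ U{1..6};
activation fold change λ⁺ ~ U[1, 100]; inhibition fold change λ⁻ = 1/u with
u ~ U[1, 100], so fold-repression is distributed symmetrically to
fold-activation.  Thresholds follow the half-functional rule: for an edge
from regulator R, the median attainable level M_R of R is estimated by Monte
Carlo (10,000 draws of G_R/k_R, each multiplied by one factor per incoming
edge of R that is equally likely 1 — regulator absent — or its λ — regulator
saturating), and the edge threshold is drawn uniformly from
[0.02·M_R, 1.98·M_R].  This gives each regulation roughly even odds of being
functional and couples threshold scales to network context through the
regulator's in-degree.  The reference implementation of this formalism was
not reachable from the build environment, so the rule was validated against
reported ensemble statistics instead (see "Fidelity" below).

## Random networks

A motif is embedded in a background of N ∈ {5, 10, 15, 20} extra nodes by
adding x·N random signed edges (x ∈ {2, 4, 6}, mean connectivity E:xN).
Random edges are placed uniformly over the empty off-diagonal cells of the
adjacency matrix — so they can target motif nodes (the mechanism that
raises motif in-degree), cannot duplicate an existing ordered pair, and
cannot create self-loops — and are activating or inhibiting with
probability 1/2 each (a maximum-entropy choice; downstream analyses confirm
metric trends track the *number* of incoming edges, not their signs).
Candidates whose undirected graph is disconnected, and exact duplicates
within a batch, are regenerated (bounded by 10,000 attempts).  The `-SA`
and `-SI` motif variants add one self-activation or self-inhibition per
motif node; these are the only self-loops permitted.  Networks round-trip
through the standard `.topo` text format (`Source Target Type`, 1 =
activation, 2 = inhibition).

## Integration and steady-state identification

Fixed-step Euler with dt = 0.1 up to t_max (default 1000 time units;
presets use 300, see below), from initial conditions log-uniform per node on
[10⁻², (G/k)·Πλ⁺].  A trajectory is converged when its max-norm relative
change over 10 consecutive steps falls below 10⁻⁶.  Trajectories whose
10-step relative change still exceeds 3·10⁻² at t = 100 are cut early and
counted as non-convergent: with degradation-bounded decay rates a
contracting trajectory has flattened far below that level by then, so these
are limit cycles (dense random networks oscillate in roughly half of their
parameter sets), and integrating them to t_max only burns the step budget.
Shortening t_max from 1000 to 300 changes per-network metrics by ≲0.01 —
well inside sampling noise — because the trajectories that converge between
t = 300 and t = 1000 are a fraction of a percent.  Converged endpoints of
one model are deduplicated at relative Euclidean distance 10⁻² in
G/k-normalized coordinates; a model reporting more than 10 distinct stable
states is truncated to the 10 most-visited (logged; it essentially never
happens at the sampled depths).

## State processing and metrics

Steady states are normalized per model to S·k/G (the node's level relative
to its unregulated steady state) and pooled across all models of one
network's ensemble, one row per (model, stable state), unweighted.

Two scales serve two purposes, and this is a deliberate design choice:

* **Distribution and rank statistics** — Sarle's bimodality coefficient
  BiC = (m₃² + 1)/(m₄ + 3(n−1)²/((n−2)(n−3))) with population-style skew m₃
  and excess kurtosis m₄, and Spearman correlations — are computed on
  **log2-scale** normalized values, the convention of ensemble-simulation
  output tables.  Spearman is invariant to the monotone transform; BiC is
  not, and the log2 scale is the one that reproduces the reported isolated
  motif coefficients (see below).
* **ON/OFF binarization** — z-scoring each node across the pooled rows and
  calling z > 0 "ON" (z ≤ 0 "OFF") — is done on the **linear** normalized
  scale.  On the log scale, states repressed by several saturated
  inhibitors reach log2 values of −10 to −20; these long tails drag the
  node mean far down, so mildly low states reclassify as ON and the
  double-positive fraction inflates even at minimal embedding.  Both stages
  accept a switch (`log2_values`, `log2_binarize`) for users who want a
  single-scale pipeline.

From binarized motif states: F1 (single-positive fraction; {01, 10} for TS,
{001, 010, 100} for TT), and for TT also F2 (double-positive), F3 (all
ON/all OFF; F1+F2+F3 = 1 exactly) and F1/F2.  The B:M ratio of a TS divides
the fraction of bistable parameter sets whose two *distinct motif* states
are exactly {01, 10} by the fraction of monostable sets showing 01 or 10;
classes are counted on distinct motif strings so that background-node
multistability, which duplicates motif states across network states, does
not misclassify models.  Pairwise Spearman CCs give MaxCC/MinCC for the TT,
and an ordinary least squares regression of C on A and B yields ACoeff,
BCoeff and R².  BiC > 5/9 (the exact uniform-distribution value) is the
bimodality call.

## Experiments and meta-analysis

An experiment plan sweeps the 12 (order × connectivity) classes — 4 for the
SA/SI variants: (5N, 20N) × (E:2N, E:6N) — with a seed hierarchy master →
per-class topology seed → per-replicate parameter seed, all recorded.
Records are compared across groups with two-sided Mann-Whitney U tests
(star categories at p ≤ 0.05/0.01/0.001/0.0001, unadjusted), correlated
against raw and normalized in-degree descriptors (in_X, in_motif,
in_X/in_motif, in_XY/in_motif) with Spearman tests, binned by (in_A, in_B)
with asymmetry log-ratios log2(in_A/in_B) and log2(BiC_A/BiC_B), and
checked against a control that recomputes all metrics on randomly chosen
background nodes under identical pooling.

## Problem sizes

The full study design is 100 networks/class × 3 replicates × 10,000
parameter sets × 100 initial conditions.  The package ships three presets:

| preset       | networks/class | replicates | models | inits | t_max |
|--------------|----------------|------------|--------|-------|-------|
| full         | 100            | 3          | 10,000 | 100   | 1000  |
| scaled_down  | 40             | 1          | 1,000  | 20    | 300   |
| acceptance   | 20             | 1          | 400    | 10    | 300   |

The bundled acceptance checks use: isolated motifs at the full per-network
depth (10,000 × 100, single network, under a minute each); the embedded TS
batch at 40 networks/class × 200 models × 10 inits (40/class keeps the
rare (in_A, in_B) = (1,1) bin populated — about 7 networks across the 12
classes); the embedded TT batch at 20 networks/class × 800 models × 10
inits (deeper per-network sampling reduces attenuation of the per-network
MaxCC and state-fraction correlations toward their full-depth values); and the self-regulation comparison at 6 networks/class × 250 models over
the 4-class grid, run in the *matched* design
(`run_self_regulation_comparison`): the plain motif and its SA/SI variants
are embedded in the same background networks with the same parameter seeds,
so variant contrasts are paired and free of background-to-background
variability.  These sizes are the package's own trade-off
between sampling noise and desk-scale runtime; rank correlations at these
depths sit within a few hundredths of deeper pilot runs, except where noted
below.

## Fidelity to reported ensemble statistics

With the defaults above the pipeline reproduces, from scratch: isolated-TS
Spearman CC(A,B) ≈ −0.83; isolated-TT mean BiC ≈ 0.44 with all three
pairwise CCs ≈ −0.42; the (1,1) in-degree bin of embedded TS at mean CC ≈
−0.83 with monotone decay of |CC| and F1 across E:2N → E:6N; and embedded
TT meta-correlations ρ(MaxCC, in_TT) ≈ 0.44 and ρ(MaxCC, F1) ≈ −0.4 to
−0.5.

Known residual discrepancies, documented rather than absorbed:

* Isolated-TS BiC comes out 0.810–0.814 against a reported 0.78 ± 0.03.
  The value is stable under convergence/deduplication-tolerance sweeps and
  under the sampling depth, so it reflects a small difference in the
  low-expression tail relative to the original C implementation (whose
  looser convergence bookkeeping we could not consult).
* The TS B:M ratio in the (1,1) bin measures 0.98 ± 0.04 — at, rather than
  above, the reported "greater than one" boundary.  The ratio is exquisitely
  sensitive to the handful of binarized states that fall on the wrong side
  of a node's pooled mean, i.e. to the same low-tail placement as the BiC
  point above.
* The self-regulation contrasts split by metric class.  Value-based
  orderings reproduce on both scales: self-activation strengthens and
  self-inhibition weakens the TS correlation (median CC ≈ −0.70 / −0.68 /
  −0.47 for SA / plain / SI) and the node bimodality (BiC ≈ 0.54 / 0.44 /
  0.35), and TT MaxCC is highest for SI.  The state-fraction orderings are
  threshold-scale sensitive: with log2-scale thresholding the TS F1
  ordering (SI < plain < SA) and the TT F3 ordering (SA < plain < SI)
  reproduce, while with linear thresholding neither does (self-activation
  raises the high branch and with it the linear pooled mean, flipping
  ON-calls).  The TT F1/F2 ordering does not reproduce on either scale: in
  these ensembles self-activation *increases* the double-positive fraction
  (log2-threshold median F2 ≈ 0.61 for TT-SA vs 0.47 for TT), so TT-SA has
  the lowest F1/F2 rather than the highest.  The self-regulation analyses
  therefore default to log2-scale thresholding, and the F1/F2 ordering is
  flagged as not reproduced.
* ρ(F1/F2, in_TT) does not reproduce under any single defensible
  binarization: on the linear scale F2 is a small fraction whose
  between-network variation is unrelated to in-degree (the correlation
  converges to ≈ −0.1 as per-network sampling deepens), while on the log2
  scale the tail-drag inflates F2 immediately upon embedding and the
  correlation is weakly positive.  The package reports the linear-scale
  value and flags it as not reproducing the reported −0.51; F1 alone
  correlates with in_TT at ρ ≈ −0.93, so the scientific claim (single
  positives are replaced as in-degree grows) is robust even though this
  particular ratio statistic is not.

## What the generator does and does not emulate

Backgrounds are uniform random simple digraphs: no scale-free degree
structure, no modularity, no sign correlations, and edge signs carry no
biological annotation.  Kinetic ranges are the generic RACIPE ranges, not
gene-specific measurements.  Passing tests therefore show that the
*pipeline* reproduces the ensemble phenomenology of the study design —
they do not certify behavior on any real regulatory network.

## Degenerate inputs and numerical edges

Zero-variance nodes abort z-scoring with the node named; constant inputs
make Spearman CC missing (NaN) rather than raising; B:M with no qualifying
monostable sets is missing, and 0 when no bistable sets exist at all;
MLR rejects rank-deficient designs; fractions on an empty table reject.
Ensembles are reproducible bit-for-bit from their seed on a fixed platform;
per-model failures inside an experiment are logged and excluded, never
fatal.
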