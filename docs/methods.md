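# Methods

## Model and inference procedure

Metabolite pools fluctuating around a steady state of a metabolic network
are modeled as a stationary Ornstein–Uhlenbeck process: the deviation
ξ = M − M* obeys dξ = J ξ dt + noise, where J is the biochemical Jacobian
J = N ∂r/∂M at the steady state. The stationary covariance C then satisfies
the continuous Lyapunov equation J C + C Jᵀ = −2 D, with D the diagonal
matrix of noise intensities. Inference inverts this relation: C is
estimated from biological replicates (unbiased n−1 sample covariance,
replicate rows with missing cells dropped and logged, optional linear
shrinkage toward the diagonal for very small n, off by default), the
allowed sparsity of J is taken from the network (entry (i, j) allowed when
pools i and j share at least one interaction), and the masked entries of J
are solved from the linear system A·x = −2 vec(D), where A stacks the
vectorizations of E_ij C + C E_ji over allowed entries.

**Total least squares.** The solver uses the classical SVD-of-augmented-
system TLS construction on [A | b]. When the restricted operator is rank
deficient, the smallest augmented singular value is (near-)degenerate, or
the TLS denominator vanishes, it falls back to the minimum-norm ordinary
least-squares solution and flags the fallback in the result; the operator's
effective rank (tolerance 1e−10 relative to its largest singular value),
null-space dimension and the Lyapunov residual ‖JC + CJᵀ + 2D‖_F are
reported with every solve. On consistent full-column-rank instances both
routes recover the exact solution; on the rank-deficient fully-masked
identity example (C = D = I) the fallback returns the symmetric
representative −I of the solution family J + Jᵀ = −2I.

**Stochastic ensemble.** D is unobservable, so the inverse solve is
repeated (default 10⁵ iterations; desk-scale studies here use 10³–10⁴) with
the diagonal of D drawn independently each iteration. Draws are standard
normal in magnitude; since a stationary process requires positive noise
intensities, absolute values are taken (half-normal) by default, with a
flag (`d_sign="signed"`) for literal signed draws. Each iteration uses an
independent child of the ensemble seed (numpy `SeedSequence.spawn`), making
ensembles bit-reproducible. Failed solves are excluded and counted. The
ensemble is summarized elementwise by median and interquartile range
(linear-interpolation quantile rule) as normalized = median / IQR² —
normalizing by the squared IQR damps entries whose estimates scatter
wildly. Entries with IQR below 1e−12, and everything outside the mask, are
flagged undefined (NaN), never infinite.

**Differential Jacobian and significance.** Two states a and b are
compared entrywise as dJ = |log₂|a| − log₂|b|| on the normalized matrices —
algebraically |log₂|a/b||, written as a difference of logs so that swapping
the states is bit-exactly symmetric. Entries undefined in either state, or
with a zero in either state, are undefined. Per-entry significance uses
Welch's unequal-variance t-test; because raw tests on 10⁵-member ensembles
declare negligible differences significant, the default procedure
partitions each ensemble into 100 batches and tests the batch medians
(effective n = 100 per group), with a flag for the literal full-ensemble
test and optional Benjamini–Hochberg correction (off by default; the
workflow reports uncorrected p < 0.05). Two-condition workflows run both
ensembles from one seed (common random fluctuation matrices, a paired
design): identical inputs then give an exactly zero differential, and
Monte-Carlo noise in dJ is substantially reduced for unchanged entries.

## Network reduction

SBML models (Level 3 preferred, Level 2 accepted) are parsed with libsbml;
reactant coefficients are negative, products positive, reversible reactions
are kept as single signed columns (the Jacobian formalism needs net
connectivity, not flux directionality). The interaction matrix orders
species deterministically by (compartment, id). Projection onto a measured
subset retains measured species (plus, optionally, first neighbors —
included for interpretation only, since they carry no covariance data);
interactions whose participants are all retained keep their original
column, and chains through removed intermediates are collapsed by bounded
depth-first enumeration of simple paths (default maximum 6 interaction
steps) into superpathway columns with −1 on the source and +1 on the sink.
Interior stoichiometric scaling of collapsed chains is deliberately
discarded — a superpathway asserts connectivity, not mass balance — and
effective coefficients of multi-step chains are not well defined without
kinetics. All original reactions along every collapsed path are recorded as
the column's provenance; parallel superpathways with identical signed
patterns merge (union of provenance), and a superpathway duplicating a kept
column is absorbed into it. Path enumeration follows each reaction's stated
direction; a chain that would require traversing a reversible reaction
backwards is not collapsed.

## Synthetic ground truth

The generator builds mass-action models whose steady state and Jacobian are
known analytically, then draws replicates *exactly* from the stationary
Gaussian of the linearized dynamics — mean x*, covariance solving
J C + C Jᵀ = −2 D_true — rather than integrating a stochastic trajectory.
Biological replicates are independent organisms, so independent stationary
draws are the right emulation, and exact sampling removes integrator bias
from every downstream check. D_true = (noise_scale²/2)·diag(x*)
(concentration-proportional intrinsic noise, default noise_scale 0.05, i.e.
roughly 5%-of-pool fluctuation intensity) keeps signal-to-noise comparable
across pools. Negative draws are floored at 1e−9·x* and counted (rare at
the default noise level). What the generator does *not* emulate: technical
measurement error on top of biological fluctuation, non-Gaussian or
non-stationary dynamics, and correlated noise between pools — so passing
tests demonstrate correctness of the inference machinery under the model's
own assumptions, not robustness to their violation.

Presets: `chain3`, a 3-pool linear chain with closed-form steady state;
`random`, a seeded random stable 5-pool first-order network (chain backbone
plus random extra conversions, per-pool effluxes guarantee a compartmental,
hence Hurwitz-stable, system); and `carb13`, thirteen carbohydrate pools —
sucrose, raffinose, glucose, fructose in cytosol and vacuole; sucrose,
raffinose, glucose, fructose and starch in the plastid — with tonoplast and
envelope transport, sucrose synthesis (the single bilinear step:
glc + frc → suc), invertases in all three compartments, cytosolic hexose
consumption by glycolysis, raffinose synthesis and turnover, and starch
turnover. Raffinose is given a plastidial pool (as observed in
cold-acclimated Arabidopsis) alongside the cytosolic and vacuolar ones;
starch is plastid-only. Rate constants are order-1 values fixed so the
slowest Jacobian eigenvalue exceeds 0.05 in magnitude (well-conditioned
Lyapunov solves); cytosolic glycolytic consumption is required — without an
asymmetric hexose sink the glucose-minus-fructose moiety difference is
conserved and the Jacobian is only marginally stable.

## Identifiability of the differential statistic

The detection experiment (two simulated conditions differing in one doubled
transport constant; differential entries ranked) was characterized with
*oracle* covariances — the analytic Lyapunov covariance of each condition,
no sampling noise, near-converged ensembles — before fixing its default
perturbation. The ensemble statistic resolves perturbations of hexose
export steps sharply (vacuolar fructose export and plastidial fructose
export rank 1st, vacuolar glucose export 3rd), but *not* sucrose or
raffinose import steps (ranks 8–31), although the true differential ranks
each perturbed entry first: a perturbed sucrose import shifts the steady
state, and that shift propagates through the bilinear sucrose-synthesis
step into comparable normalized-Jacobian changes across many entries. This
is a property of the median/IQR² ensemble functional, not of the solver
(forward–inverse round trips with the true D are exact to 1e−13). The
shipped experiment therefore perturbs `tonoplast_frc_out` (vacuolar
fructose export — matching reported cold-acclimation biology of vacuolar
hexose transport) and runs in the large-n covariance regime (10⁵ replicates
per condition, the same size as the generator-closure study): at 100
replicates, covariance sampling noise — not the inversion — dominates the
ranking, a practical caution for small-sample applications of the method.

## Problem sizes and numerical choices

Validation studies use: 50 random stable systems (dim ≤ 8) for
forward-solver and round-trip checks; 10⁵ stationary draws for generator
closure (3 SE criterion); 10³- vs 10⁴-iteration ensembles on the 13-pool
covariance for median-stability (two pooled IQRs); 20 repeats × 10³
iterations for detection. Forward solves use the Bartels–Stewart solver
(scipy) with a 1e−9 relative residual certificate; Hurwitz stability is
checked before every forward solve and at synthetic-model construction.
Steady states of purely first-order models are solved linearly; otherwise a
hybrid root finder from several positive starting points, verified to
‖dM/dt‖∞ ≤ 1e−10 × flux scale. Covariance matrices are validated symmetric
(1e−12), PSD (eigenvalue floor −1e−9 relative) with non-negative diagonal.

## Known limitations

* Magnitudes of inferred Jacobians are relative (unknown fluctuation
  scale); only signs, rankings and between-condition ratios are
  interpretable, never absolute rates.
* Superpathway collapse is an automated, bounded-path substitute for what
  is in practice expert curation; it does not attempt effective
  stoichiometry and does not traverse reversible reactions backwards.
* The significance procedure's effective sample size is a design choice
  (100 batch medians); the literal full-ensemble test is provided but
  overstates certainty.
* Detection power depends strongly on which interaction is perturbed (see
  identifiability above) and on replicate count.
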