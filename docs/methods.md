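# Methods

`pairflight` infers directed coupling between two simultaneously moving
agents from their 3D trajectories alone, with no behavioral model.  The
pipeline mirrors the standard design of field studies of paired flight:
per-pair kinematic preprocessing, ensemble construction across pairs, two
complementary coupling estimators (transfer entropy and convergent cross
mapping), a shuffled-partner null, and a combined leadership decision.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic test bed does and does not establish.

## Kinematics

Raw trajectories are timestamped 3D positions per agent.  Each coordinate
is fitted with an interpolating cubic spline and resampled on a uniform
grid (default 180 Hz); velocity and acceleration are the spline's analytic
first and second derivatives, never finite differences.  We use not-a-knot
boundary conditions: unlike a natural spline (which forces zero curvature
at the ends), the not-a-knot interpolant reproduces cubic paths — and
their derivatives — exactly, which anchors the curvature unit tests and
avoids artificial end-flattening of short flights.  A smoothing spline is
deliberately not used by default; smoothing strength would be an
additional unreported tuning knob (the spline fit is interpolating, and
resampling a series already on the target grid reproduces it exactly).

Curvature is computed per sample from velocity `v` and acceleration `a`:

    a_t = (a·v / ‖v‖²) v,   a_n = a − a_t,   ρ = ‖a_n‖ / ‖v‖²   [1/m]

so ρ = 1/R on a circle of radius R.  Samples with speed below a floor
(default 1e-6 m/s) get invalid curvature and are dropped from ensembles;
flying animals never stall to zero speed, but synthetic edge cases must
not produce infinities.

A pair is analyzable only during its co-presence window.  Both agents are
resampled onto one shared grid anchored at the overlap start, so the two
series are sample-aligned, which the coupling estimators require.

Per analysis group, the per-pair curvature (or 3D velocity) series are
concatenated in ascending pair-id order — agent 1's segments in the same
order as agent 2's — and standardized to zero mean, unit sample variance
(globally by default; per-segment normalization is available).  Segment
start indices are kept: a transition between the last sample of one pair
and the first of the next is not a dynamical transition, and every
estimator masks such transitions out.  Concatenation rather than per-pair
analysis is used because both estimators are data hungry; the effective
sample size is the total number of time steps, not the number of pairs.

## Transfer entropy

Transfer entropy from X to Y with first-order histories and zero
source lag,

    T_{X→Y} = Σ p(y⁺, y, x) ln [ p(y⁺ | y, x) / p(y⁺ | y) ]   [nats]

measures how much the source's present reduces uncertainty about the
destination's next sample beyond the destination's own present.  Two
estimators are provided:

* **Binning** — equal-width bins per variable over its observed range,
  plug-in probabilities.  The implementation satisfies, to 1e-12 on every
  input, the identity T = H(Y⁺|Y) − H(Y⁺|Y,X), which the tests verify
  against an exhaustive tuple-count oracle.  Binned TE is nonnegative by
  construction.
* **KSG (Kraskov algorithm 1)** — TE as the conditional mutual
  information I(Y⁺; X | Y) with max-norm neighbor statistics: the distance
  to the K-th neighbor in the joint space sets a local resolution, and
  strictly-within-that-radius counts in the (Y⁺,Y), (Y,X) and (Y)
  marginal spaces enter ψ(K) + ⟨ψ(n_y+1) − ψ(n_{y⁺y}+1) − ψ(n_{yx}+1)⟩.
  The default K is 8, with a sensitivity sweep over K = 2..15.  Series
  may be multivariate (e.g. 3D velocity).  Tie-breaking noise of relative
  amplitude 1e-10 × per-dimension standard deviation (seeded) is added
  before neighbor searches; making the amplitude relative rather than
  absolute keeps the estimator exactly invariant under common rescaling,
  which is also a property of the mathematical quantity.  Negative
  finite-sample estimates are reported as computed — significance is
  judged only against the shuffle null, never by sign or magnitude.

## Convergent cross mapping

CCM asks whether the delay embedding of one series can recover the other.
The shadow manifold of a series is the set of E-dimensional delay vectors
(x(t), x(t−τ), …, x(t−(E−1)τ)), τ = 1 sample throughout; vectors whose
lag window would span two concatenated pairs are never created.  The
embedding dimension E is chosen per series by simplex projection: one-step
forecasts from the E+1 nearest embedded neighbors (leave-self-out,
exponential weights u_i = exp(−d_i/d_1)), maximizing the Pearson
correlation between forecast and observation over E = 1..10, smallest E
on ties.

The cross-map estimate of series A at time t is the weighted average of A
at the times of the E+1 nearest neighbors of the query point on B's
manifold.  Skill is the Pearson correlation between A and its estimate,
clipped below at zero (a negative correlation carries no cross-map
information), so skill ∈ [0, 1].

**Direction convention.** `C[A→B]` denotes the skill of estimating A from
the shadow manifold of B — the putative cause recovered from the putative
effect, as in the CCM literature: when A drives B, A's dynamics are
imprinted on B, so B's manifold reconstructs A.  A high `C[2→1]` reads
"agent 2 drives agent 1".  Every output record carries this convention
string.

Convergence with library size L is the evidence criterion.  For each L,
skill is averaged over all sequential windows of L consecutive samples
(n − L + 1 windows; uniformly subsampled with a seeded generator above a
cap, default 200, for tractability); the headline value is the mean skill
at the largest library, which for the full series is the single
whole-library window.  A sweep is classified *converged* when the last
two mean skills differ by less than a tolerance (default 0.02) with a
nondecreasing trend within that tolerance, *increasing* when still rising
at L_max, else *flat*.  Neighbor exclusion is self-only by default; a
Theiler-style temporal exclusion radius is available as config.

## Shuffled-partner control

Two agents flying through the same space look alike without interacting.
The control condition isolates direct interaction from that shared-
environment similarity: each agent-1 series is paired with the agent-2
series of a *different* pair — a uniformly sampled derangement over pair
ids (rejection sampling from uniform permutations, seeded, derangements
drawn with replacement across shuffles) — the longer member of each
pseudo-pair is tail-truncated to the shorter one's length, and the entire
ensemble pipeline (concatenate → normalize → estimate) is re-run.  One
hundred shuffles (default) give an empirical null; the 95% interval is
the 2.5/97.5 percentile interval (no distributional assumption at n=100;
a normal-approximation interval is available).  An observed value is
*significant* only if it strictly exceeds the interval's upper edge;
values inside the interval are conservatively insignificant.  A
time-shuffled surrogate is deliberately not offered: destroying temporal
order collapses the null to nearly zero variance and certifies everything
as significant.

One economy: the embedding dimension used for the cross-map control is
the one selected on the observed ensemble, held fixed across shuffles. E
is an analysis hyperparameter rather than a statistic of the data under
test, and re-selecting it per shuffle would multiply the control's cost
roughly tenfold without changing its meaning.

## Leadership decision

Agent i is called the leader only when the two methods agree:

1. transfer entropy significant i→j **and** insignificant j→i, and
2. `C[i→j]` significant against its control **and**
   `C[i→j] − C[j→i] ≥ δ` (dominance margin, default 0.2).

Bidirectional TE significance always yields "none": mutual information
flow is the signature of a mutually coupled pair, not of a leader.  The
margin δ = 0.2 separates a clearly dominant direction (e.g. 0.75 vs 0.35)
from a pair of comparable skills where the smaller one merely reaches
significance; it is configurable and every verdict records the value
used.

## Synthetic test bed

The simulator exists to give every pipeline stage a ground truth; it is a
test harness with plausible flight statistics, not a biological model.
Each agent is a constant-speed (4 m/s) self-propelled particle whose unit
heading is steered by three influences, integrated by Euler–Maruyama at
the working rate (180 Hz) with renormalization:

* **Colored turning noise.**  Default: an Ornstein–Uhlenbeck turning-rate
  vector with correlation time 0.2 s and stationary RMS 0.5 rad/s (the
  `heading_noise` knob), initialized in steady state.  White heading
  noise at 180 Hz would produce jagged, implausible curvature; the OU
  choice also makes a lone agent's curvature first-order Markov at the
  sample scale, so the uncoupled direction of transfer entropy is
  genuinely null under the estimator's first-order conditioning.  An
  alternative jerk-limited model (`noise_model="smooth"`, an OU angular
  jerk driving a damped turning rate) is provided; it yields smoother
  paths but lets *any* correlated companion series disambiguate the
  slope of a smooth curvature series, which renders TE bidirectional
  even under one-way coupling — useful precisely to demonstrate that
  failure mode.
* **Shared corridor.**  Headings relax (gain 2.5 1/s) toward the local
  tangent of a gently sinuous centerline (amplitude 0.3 m, wavelength
  4 m) with a pull back toward the centerline.  Both agents fly the same
  corridor, so their curvature series are positively correlated
  (≈ +0.3 within pairs) with **no** information exchanged — the
  environmental similarity the control condition must reject.
* **Directed coupling.**  In a coupled direction, the influenced agent's
  heading relaxes (gain 35 1/s in the strong-coupling regime) toward the
  partner's heading at a 10 ms sensorimotor delay, only while the partner
  is airborne.  Modes: none, front→rear, rear→front, bidirectional.
  Coupling enters through turning — exactly the variable the analysis
  reads.  The delay default is deliberately short: for Markov steering
  the information visible to a lag-one estimator at sample spacing dt
  decays like dt/(2·delay), so a 10 ms delay keeps the strong-coupling
  condition well above the shuffle null at the study's ensemble scale,
  while longer delays remain available via config.

Agent 1 enters the volume first; agent 2 follows 0.55 s later, so with
1.3 s flights (±20% per-pair jitter) the co-presence window is ≈ 135
samples and a 10-pair group concatenates to ≈ 1.3×10³ samples — the scale
of the smallest field group, which is the hard case.  Flights start from
the corridor entrance with a 0.5 m lateral stagger.

What passing tests on this generator do show: the estimators recover a
known coupling direction at field-realistic sample sizes, and the control
correctly refuses to certify similarity that comes only from shared
environment.  What they do not show: anything about sensory mechanism,
about real animals' noise spectra or speed variation (speed is constant
here), or about couplings weaker than the simulated regime.

## Numerical choices and degenerate inputs

* Spline fitting needs ≥ 4 samples; fewer is an unusable-trajectory
  error.  Non-monotone timestamps are an input error.
* KSG neighbor counts use radii `nextafter(ε, 0)` so "strictly within ε"
  is exact in floating point; duplicate-heavy inputs are regularized by
  the seeded tie noise.
* Simplex weights collapse onto zero-distance neighbors when the nearest
  neighbor coincides with the query.
* Constant series: entropy 0 (single occupied bin); normalization raises
  a zero-variance error naming the offending segment.
* Percentile intervals use linear interpolation (numpy default); an
  observed value exactly at the upper edge is insignificant.
* All stochastic steps (tie noise, derangements, window subsampling,
  simulation) take explicit seeds; a group analysis derives independent
  child streams from one master seed, and repeated runs are byte-identical.

## Problem sizes used in validation

The test suite validates estimators against closed forms at n = 10⁴–2×10⁴
(Gaussian linear systems), cross mapping on logistic maps at n = 10³, and
the full pipeline on 50-world batches of 10-pair groups (~1.3×10³-sample
ensembles) with 100-shuffle controls; control calibration uses 200
uncoupled worlds with 50 shuffles each (seeds recorded in the tests).
The acceptance script reports the same quantities at 20-world batches.

## Known limitations

* First-order TE only (`history_k` is configurable but the default
  analysis conditions on one sample of destination history); no
  time-lagged source variants, no active information storage.
* CCM is univariate; multivariate coupling is probed only through TE on
  3D velocity.
* The kernel-width TE estimator is not implemented (the KSG estimator
  supersedes it); time-shuffled surrogates are intentionally absent.
* Behavior labels (NM/MC/MT) are metadata supplied with the input, not
  derived from geometry; the synthetic corridor has no actual maze.
* Groups larger than pairs are out of scope.
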