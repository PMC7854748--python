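# Methods

## The kinetic model

The package models the reversible (in)activation of an adsorbed
[FeFe]-hydrogenase film as a linear three-state scheme over the species
A1 (active, uncapped), A2 (active intermediate conformer) and H_inact
(inactive, cysteine-capped, O2-protected):

    A1  ⇄(k1 / k−1)  A2  ⇄(k_inact / k_react)  H_inact

All four rate constants are first order (s⁻¹). The populations
p = (a1, a2, h) obey the master equation dp/dt = G p with the
column-zero-sum generator

    G = [ −k1        k−1              0      ]
        [  k1       −(k−1 + k_inact)  k_react ]
        [  0         k_inact         −k_react ]

There is no direct A1 ↔ H_inact edge: capping proceeds through the A2
conformer. The catalytic current is

    i(t) = A(E) · (a1(t) + α2 · a2(t)),

where A(E) is a per-potential amplitude (the turnover frequency at that
electrode potential times film coverage) and α2 is the activity of A2
relative to A1, fixed at 0.5 by default (A2 is experimentally about half
as active) and optionally a fit parameter. H_inact carries no current.
After a potential step the state vector is continuous while A(E) jumps,
which produces the instantaneous current peaks followed by bi-exponential
relaxations characteristic of these experiments.

Only k_react depends on electrode potential (and pH): that is the
experimental observation this model encodes, and it is also why the fit
shares k1, k−1, k_inact across a whole multi-step trace while freeing
one k_react per distinct potential.

### Propagation

Propagation under piecewise-constant conditions is exact: the 3×3
generator is eigendecomposed once per rate set and populations at all
sample times are computed from the spectral representation. If two
eigenvalues coincide to a relative gap below 1e−9 the code falls back to
scaling-and-squaring matrix exponentials. Populations are clipped at 0
and renormalized to unit sum to remove eigen-solver roundoff; total
population is conserved to better than 1e−9 (property-tested).

For a fully reversible chain the stationary state is proportional to
(1, k1/k−1, k1·k_inact/(k−1·k_react)). The implementation clears the
common denominator, using weights (k−1·k_react, k1·k_react, k1·k_inact),
so absorbing limits (zero backward rates) emerge naturally; the fully
degenerate cases fall back to an SVD null-space computation, and the
all-zero chain is an error (no unique stationary state).

### Potential dependence of k_react

The functional form of k_react(E) is not established; the default for
fitting is therefore a free value per distinct protocol potential
(`per_step_table`). Where a law is wanted (CV simulation, profile fits)
a minimal Tafel-like exponential is used,

    k_react(E) = k0 · exp(−slope · (E − E_ref)),

because reactivation is a reduction-coupled step, so its rate should
grow exponentially as the potential is lowered. Defaults: k0 = 0.17 s⁻¹
at E_ref = −0.196 V, slope = 23.03 V⁻¹ (one decade per 100 mV, the scale
of a one-electron coupled step at 5 °C with a transfer coefficient near
0.55). The same decade-per-100-mV rule sets the synthetic-data truth for
the reductive step (−0.31 V) of the reference protocol, where no
tabulated value exists; the tabulated k_react applies at the oxidative
step.

## Fitting

`ThreeStateCurrentModel` and `TwoStateCurrentModel` are scikit-learn
style regressors mapping X = (time_s, potential_V) to current. The step
program is reconstructed from the potential column, so a trace is
self-describing. Rate constants are optimized on a log scale (bounds
1e−6 … 1e3 s⁻¹) with `scipy.optimize.least_squares` (trust-region
reflective); the per-potential amplitudes enter the model linearly and
are profiled out analytically at every residual evaluation (variable
projection), which removes them from the nonlinear search entirely and
makes the fit exactly invariant to current-unit rescaling.

Multistart (default n = 8) draws log-uniform initial rates from
[1e−3, 10] s⁻¹ from a seeded generator. Exploration runs are capped at
120 residual evaluations; the best start is then polished to full
convergence. The three-state multistart additionally includes two
deterministic starts in the pooled two-state limit (k1 = k−1 fast, the
effective inactivation rate doubled), one of them seeded from a quick
two-state fit of the same data — this guarantees in practice that the
three-state SSR never exceeds the nested two-state SSR.

Initial condition: pure A1 at t = 0, because step protocols begin with a
long reductive hold that fully activates the film. Weighting: unweighted
least squares. Capacitive step transients are handled either by
subtracting a measured blank or, by default, by masking the first 2 s
after each potential step (`mask_after_step`). The recovery-study driver
turns masking off because its synthetic traces contain no capacitive
component; masking there only discards the fast-relaxation information.

Uncertainties come from the Gauss–Newton covariance
(J'J)⁻¹ · SSR/(n−p) of the log-parameters, delta-method-mapped back to
the rate scale.

### Model comparison

The two-species (bound/unbound) model predicts mono-exponential
relaxations; it is fitted with the same machinery (k_inact shared,
k_react per potential, amplitudes profiled). Because the two-state model
is the fast-pre-equilibrium limit of the three-state one (with pooled
active state), the fits are nested in flexibility and compared with both
an F-test, F = ((SSR2 − SSR3)/(p3 − p2)) / (SSR3/(n − p3)), and
ΔAIC = n·ln(SSR2/SSR3) + 2(p2 − p3). The three-state model is declared
preferred only when the F-test is significant at 0.05 *and* ΔAIC > 0.
Parameter counts include the profiled amplitudes.

One subtlety: both models start fully active, but the three-state model
starts as pure A1 whereas its pooled fast-pre-equilibrium limit carries
the activity weight (1 + α2)/2 < 1. The single t = 0 sample therefore
cannot be matched simultaneously with the relaxation amplitudes, so on
data generated from the two-state model the three-state SSR can exceed
the two-state SSR by a few parts in 10⁵; the nesting is asserted with a
1e−4 relative tolerance.

## Synthetic experiments

The generator emulates the statistical structure the analysis assumes:

- **Chronoamperograms** — exact three-state current plus an optional
  signed capacitive transient ±peak·exp(−Δt/τ) after each potential
  change, plus additive Gaussian noise with sd = relative_sd × max |i|
  (default 1%). Sampling 10 Hz. Optional single-exponential film loss
  (off by default).
- **Blanks** — capacitive transients and noise only.
- **O2 exposure** — the five-phase protocol (reductive reference hold at
  −0.8 V from t = 0, step to 0 V at 200 s, 50 µM O2 injection at 480 s,
  exponential washout from 900 s with τ = 60 s, return to −0.8 V at
  1300 s). The state is extended to (A1, A2, H_inact, Dead): O2 converts
  the two active states to Dead with a second-order rate constant
  (default 200 M⁻¹s⁻¹, chosen so that a film held fully active through
  the exposure loses >99% of its activity) while the capped H_inact
  state is immune and Dead never recovers. Integrated with LSODA at
  rtol 1e−10 / atol 1e−12; four-species conservation holds to 1e−9. The
  washout time constant is a modelling choice; the experimental buffer
  exchange has no published time constant.
- **Cyclic voltammograms** — the three-state populations are integrated
  along the potential ramp on a piecewise-constant midpoint grid
  (dt = 0.1 s) with k_react(E) from the exponential law; the current is
  a sigmoidal reversible-catalysis waveshape
  i_lim·tanh(steepness·(E − E_eq)) scaled by the weighted active
  population. This is deliberately qualitative: it reproduces the
  hysteresis and the peak-then-decay forward branch, not measured wave
  magnitudes (no mass transport or interfacial electron-transfer
  kinetics). The sweep starts from the stationary state at E_start.

What the generators do **not** emulate: electrode fouling and film loss
beyond a single exponential, mass-transport limitation, instrument
filtering, correlated (1/f) noise, chloride inhibition, partial H-cluster
occupancy. Passing recovery tests therefore demonstrate the estimator is
correct and well-conditioned under the stated noise model, not that
every real trace yields 6–8% accuracy.

## Residual activity and CV onset

Residual activity is 100 × mean |i| over the last 50 s (configurable) of
the final reductive phase divided by the same readout at the end of the
first reductive phase; it is scale-invariant. The CV onset summary
splits the sweep into branches by the sign of a 5-point-median-filtered
dE/dt and reports the potential of the (boxcar-smoothed, default window
11 samples) forward-branch current maximum.

## Parameter recovery

`recovery_study` generates seeded replicate traces, fits each, and
reports per-rate medians, relative bias and relative RMSE. With the
reference protocol (alternating −0.31/−0.21 V holds of 50 s, 3 cycles,
10 Hz, 1% noise, 25 replicates) the wild-type pH 7 parameter set is
recovered with sub-percent median bias — comfortably inside the
published determination-accuracy bounds (8% for k1, 28% for k−1, 7% for
k_inact, 6% for k_react) — and five of the seven tabulated parameter
sets pass those bounds. The exceptions are the two sets with
k_react ≫ k_inact at the oxidative step (P386L-like: 1.50 vs 0.15 s⁻¹;
the double-exchange set: 2.09 vs 0.13 s⁻¹, compounded by k1 ≪ k−1):
under these step potentials their stationary inactive fraction at the
oxidative step is only ~1–9%, the inactivation signal sits at the noise
floor, and the fitted SSR falls below the SSR at the true parameters —
the k_inact/k_react pair is genuinely weakly identified under this
protocol rather than poorly optimized. Resolving those sets requires
steps at more oxidizing potentials, which is how such variants are
measured in practice.

## Structure metrics

PDB/mmCIF files are read through gemmi (model 1, highest-occupancy
altloc). The capped-state diagnostic is the distance from the cap
cysteine SG to the distal iron of the diiron subsite, reported at 0.1 Å
(≈3.1 Å capped vs ≈5.9 Å uncapped). Fe_d is identified as the diiron
iron farther from the [4Fe-4S] centroid; because diiron ligand naming
varies between depositions the hetero-group is found by a residue-name
allowlist with a config override and an explicit atom-serial escape
hatch, and a symmetric tie is an error rather than an arbitrary pick.
Superposition is a Kabsch least-squares fit on a user-chosen subset of
an explicit atom mapping (≥3 non-collinear pairs required), with the
RMSD reported both over the fit subset and over the full mapping.

## Numerical choices and problem sizes

- Eigen-degeneracy threshold for the expm fallback: relative gap 1e−9.
- Optimizer tolerances 1e−10 (xtol/ftol/gtol); exploration cap 120
  residual evaluations, final polish uncapped.
- Recovery studies use 25 replicates; the propagation oracle check uses
  1000 random rate/time instances against a vectorized fixed-step RK4
  integrator sized so the stiffest instance has |λ|h ≤ 0.03.
- Potential-step boundaries: a sample at a boundary belongs to the step
  that begins there (current jumps exactly at step times).
- Ties/degenerate inputs: all-zero rate chains raise on steady state;
  duration-0 steps, non-increasing trace time, and fits with fewer than
  10 usable points per step raise immediately.
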