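# Methods

This note records the models, conventions and numerical choices behind
gatingkit, and what the synthetic-data studies do and do not demonstrate
about real recordings.

## Gating model and rate law

Channels are continuous-time Markov chains over conformational states.  Each
reversible transition carries a gating charge `z` (units of e₀) and has
Eyring-form rates

    k_f(V) = k0f · exp( z·δ·V / (RT/F) ),   k_b(V) = k0b · exp( −z·(1−δ)·V / (RT/F) ),

with V in mV, rates in ms⁻¹ and δ = 0.5 (symmetric barrier) by default.  The
ratio k_f/k_b carries the full valence, so the per-transition equilibrium
midpoint is V_d = (RT/zF)·ln(k0b/k0f) and a two-state scheme has an exact
Boltzmann open probability.  The recording temperature defaults to 295.15 K
(22 °C, typical room-temperature oocyte work) and is configurable; RT/F is
then 25.43 mV.  Builders parameterize transitions as (z, V_d, k0) with k0
the rate at the midpoint — for the WT-like two-state truth (z = 3.4,
V_d = −25.9 mV) k0 = 0.1 ms⁻¹ puts the slowest relaxation (≈5 ms, at V_d)
well inside a 30 ms pulse and the deactivation τ at −50 mV near 2 ms, i.e.
resolvable in the 2–4 ms tail window.  The default two-step chain
R⇌I⇌A moves its charge in discrete steps; in such a chain the fraction of
charge in the first Q–V component is structurally f1 = z1/(z1+z2).

No stochastic single-channel gating is simulated: currents are macroscopic
means, with channel count and unitary conductance folded into one amplitude
(default N = 1e9, γ = 1e-13 S ⇒ ~6 µA maximal ionic current; N = 1e10 gives
the ~5 nC gating charge typical of strongly expressing nonconducting
oocytes).

## Simulated recording artifacts

The recorded current is ionic + gating + capacitive + leak + noise.  Units
are internally coherent: ms, mV, µA, so integrated charge is in nC and the
linear capacitance C_lin is carried in nC/mV (= µF; a whole oocyte is
~0.2 µF).  The clamp potential settles exponentially after each commanded
jump (τ_clamp, default 0.1 ms), producing the familiar capacitive spike
C_lin·dV/dt; state evolution and ohmic terms follow the command potential
(an idealization — the sub-100 µs settling is far faster than gating here).
A one-pole acquisition low-pass (off by default; 1 kHz typical) can be
applied before noise; it preserves total charge and defines the
physically meaningful peak-current scale used to set "x % noise" levels,
since the unfiltered peak of an instantaneous-current sample can be an
aliased microsecond transient.  Gaussian noise is added per sample from a
seeded generator; identical configurations are bitwise reproducible.

## P/N leak subtraction

The P/8 companion protocol delivers, from a subpulse holding level (default:
the test holding potential; a hyperpolarized level avoids activating
channels during subpulses), n sweeps whose every voltage excursion is 1/n of
the test sweep's.  Subtraction is baseline-aligned: each sweep's pre-pulse
mean is removed before the repeat-averaged companion, scaled by n, is
subtracted.  Without the alignment the constant holding-leak current would
be over-subtracted n-fold.  For noiseless linear cells the cancellation is
exact to machine precision; with noise the subtracted trace carries
sd·√(1+n) per sample.

## G–V analysis

Tail-current G–V: the "amplitude" is the mean current in a window 2–4 ms
after the repolarization switch, minus the fully-deactivated baseline (mean
of the final 10 % of the tail) — a window mean is robust to noise, unlike a
point sample.  Amplitudes are normalized by the largest magnitude.  Because
the channel keeps a nonzero equilibrium open probability at the tail
potential (Po(−50) ≈ 0.04 for the WT-like truth), the baseline subtraction
leaves the normalized curve offset by a small constant; the Boltzmann fit
therefore supports an additive offset term (enabled by the pipeline for
tail-method curves), analogous to the y0 term in common fitting software.
Without it the recovered parameters are biased (V_d by ≈ +0.8 mV, z by
≈ +9 % for the WT-like truth).  Chord G–V divides steady-state current by
the driving force (V − V_rev), excluding steps within 5 mV of V_rev
(V_rev defaults to 0 mV, a high-K⁺ bath); it is the right readout for
fast-deactivating variants whose tails decay before the window.

Fits are unweighted least squares (optional per-point weights), initialized
from the interpolated half-maximum and the maximum slope
(z ≈ 4·(RT/F)·max dG/dV), with non-convergence flagged rather than raised.
Recovery studies average the normalized G–V over recordings before fitting,
mirroring how experimental G–V data are averaged across oocytes; at 1 %
noise single-recording fits are unbiased in V_d but show a convexity bias in
z of several percent that the averaged-curve fit removes.

ΔΔG = (zFV_d)aa − (zFV_d)ah with F = 23.061 kcal·mol⁻¹·V⁻¹ and V_d in
volts; uncertainty, when fit sds are available, is first-order (delta
method) propagation summed in quadrature — a convention choice, flagged as
such.

## Gating-charge (Q–V) analysis

OFF transients are integrated by the trapezoid rule after subtracting a
baseline estimated from the final 20 % of the tail (the estimator is a
package choice).  No post-switch blank is applied by default: the linear
capacitive spike is removed downstream by the regression, whereas blanking
0.3 ms of an OFF transient with τ ≈ 1.5 ms would discard ~18 % of genuine
gating charge.  The blank remains an exposed parameter; because the OFF
relaxation happens at the common tail potential, a blank scales all steps'
gating charge by nearly the same factor and leaves the normalized Q–V and
its fitted midpoints/valences essentially unchanged (only Qmax drops).

Linear capacitance is the OLS slope of integrated OFF charge vs step voltage
over +50..+70 mV, where sensor charge must have saturated; a drift of the
local slope by >1 % across the window (quadratic term) triggers an
unsaturated-charge warning.  This precondition is physical, not cosmetic: a
component with z = 2.5 centered at +20 mV is only ~95 % activated at
+50 mV, and the resulting slope contamination tilts the isolated Q–V by
tens of percent of Qmax.  Recovery studies therefore use a chain saturating
below +50 mV (z1 = 1.0 @ −120 mV, z2 = 2.5 @ −20 mV, f1 = 2/7).

The double-Boltzmann fit includes an additive offset Q0 because OFF charge
is measured relative to the holding-potential equilibrium (−100 mV), where a
shallow hyperpolarized component is already partially activated; without Q0
the model forces Q(−∞) = 0 onto data that are not referenced there.
Components are reported with V1 < V2; valences are bounded at 8 e₀
(physical); seven quantile-spaced multistarts guard against local optima;
f1 collapsing to 0 or 1 yields a flagged single-component result.  Noisy
recovery fits the recording-averaged Q–V, as with G–V.

Sampling: the Eyring law produces sub-10 µs relaxations at potentials far
from a transition midpoint, so Q–V studies sample at 500 kHz to keep
trapezoidal integration faithful (≲0.5 % on the fast component), and the
ON/OFF conservation check runs at 2 MHz to verify the master-equation
physics at the 0.1 % level.  Real amplifiers band-limit instead; ionic/tail
analyses keep 10 kHz sampling.  Conservation holds per step only when the
tail returns to the holding potential (V_tail = V_hold), since charge that
remains displaced at a depolarized tail is not an error.

## Secondary structure and ester semantics

H-bonds use the DSSP electrostatic criterion
E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a −0.5 kcal/mol
cutoff; missing amide hydrogens are reconstructed 1.01 Å from N along the
normalized sum of the N−C(prev) and N−O(prev) unit vectors.  Pairs closer
than two residues in sequence are excluded.  Minimal helices need two
consecutive k-turns (k = 3 → G, 4 → H, 5 → I) and cover residues i+1..i+k,
with overlap priority H > G > I; isolated turns label their bracketed
residues T; the rest is coil.  On ideal fixtures these labels agree exactly
with an independent DSSP implementation (mdtraj) and with a brute-force
pair-enumeration oracle.

An amide-to-ester (α-hydroxy acid) substitution at residue X removes X's own
backbone N–H donor — nothing else: every carbonyl acceptor, including X's,
is untouched, so esterifying X deletes exactly the H-bond(s) donated by X
(one, in an ideal helix interior).  Trajectory input is multi-model PDB
(binary trajectory formats are upstream conversion concerns); a small lookup
maps the Shaker S4 sites V363/V369 to I291/I297 of the Kv1.2/2.1 chimera
numbering.

The ideal-helix builder extends a poly-alanine backbone by internal
coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å, standard
angles); (−57°, −47°) reproduces textbook α geometry (rise ≈ 1.55 Å,
≈3.6 res/turn), (−49°, −26°) the 3₁₀ geometry (≈2.0 Å, ≈3.0 res/turn).

## What the synthetic studies show — and don't

The generator emulates protocol structure, linear artifacts, clamp settling,
band-limiting and stationary Gaussian noise.  It does not emulate series
resistance, endogenous conductances, rundown, temperature drift,
single-channel stochasticity, Cole–Moore shifts or multi-exponential
deactivation.  Passing recovery tests therefore demonstrates that the
analysis chain is a faithful inverse of the stated model at realistic SNR —
not that any particular experimental dataset would yield the same numbers.
Published-scale quantities (fit tables, MD helical occupancies, Q1/Q2
fractions) require raw recordings and trajectories that are not deposited;
the package instead verifies the arithmetic on printed fit parameters and
the qualitative site ordering (a 369-like perturbation costs far more gating
energy than a 363-like one) in end-to-end runs.

## Degenerate inputs and tie-breaks

Flat G–V or Q–V curves are flagged, not raised; all-zero tail amplitudes
raise a no-expression error; a negative-control Q–V (residual charge below
0.01 nC) is flagged negligible; chord points at the reversal potential are
excluded, never divided; constant tails yield a non-converged exponential
fit; a defective generator matrix falls back from eigendecomposition to
expm stepping.  All randomness flows from explicit seeds (derived seeds stay
below 2³¹), and end-to-end runs write a config-hash + seed + version
provenance header into every CSV.
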