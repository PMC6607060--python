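# Methods

## Cell model

The membrane equation is `Cm dV/dt = I_stim − ΣI_ion` with `Cm = 1
μF/cm²` (so μA/cm² and μA/μF coincide; currents are reported in μA/cm²).
The six currents follow Hodgkin–Huxley products of a maximal conductance,
gating variables and a linear driving force:

    I_Na  = g_Na · m³ h² · (V − E_Na)
    I_K1  = g_K1 · z∞(V) · (V − E_K)
    I_to  = g_to · r∞(V) · s · (V − E_K)
    I_CaL = g_CaL · d∞(V) · f · (V − E_Ca)
    I_Kr  = g_Kr · x_r · y∞(V) · (V − E_K)
    I_Ks  = g_Ks · x_s · (V − E_K)

Gate steady states are sigmoids `Y∞(V) = (1 + exp(∓(V − E_Y)/k_Y))⁻¹`
(− for activation gates m, r, d, x_r, x_s; + for inactivation gates h, z,
s, f, y). Gates z, r, d and y equilibrate instantaneously and are
evaluated algebraically inside the current expressions; the remaining six
gates relax as `τ_Y dY/dt = Y∞(V) − Y` with constant time constants
except

    τ_h(V) = 2 τ_h0 · exp(δ_h (V − E_h)/k_h) / (1 + exp((V − E_h)/k_h)),

which is evaluated in a numerically stable split form (it underflows to
zero only for voltages far outside the physiological range; the adaptive
solver treats the resulting wild trial steps as rejections). The state
vector is (V, m, h, s, f, x_r, x_s) — seven ODEs.

The parameter vector has 36 entries in a fixed canonical order: six
conductances, ten half-(in)activation voltages, ten slope factors, five
constant time constants, τ_h0 and δ_h, plus the three Nernst potentials
(E_Na = 65, E_K = −85, E_Ca = 50 mV). The Nernst potentials are
*environmental*: they stay in the vector (and in every sample matrix
column set) but are held fixed by the sampling law. Cm is a model
constant, not a vector entry.

Two printed-value ambiguities are resolved as follows and are
overridable in any config: E_d defaults to **+0.7 mV** (the parameter
table's sign; the uncertainty-characterization text uses −0.7 mV — we
probed both and the σ̂ = 3–5% behavior statistics differ by less than
seed noise), and τ_h0 = 6.80738 is interpreted in **ms** (a time
constant; the printed unit is a typo).

Initial conditions: V = E_K with every integrated gate at its steady
state at E_K, so all gate derivatives vanish exactly at t = 0. The
resting state is only approximately stationary (V drifts < 1 mV over 1 s
through the I_Na window current, stabilized by I_K1).

## Protocols and numerics

The 7-ODE system is integrated with an embedded Dormand–Prince RK5(4)
pair compiled with numba: rtol 1e-6, atol 1e-8, max step 1 ms, and
forced step boundaries at the square-pulse stimulus on/off edges. Output
is sampled on a uniform grid (dt_out = 0.05 ms) by cubic Hermite
interpolation of accepted steps. dV/dt for upstroke features is
evaluated from the model right-hand side on the grid, not by finite
differences, which removes grid artifacts in the maximum upstroke
velocity. Halving the tolerances moves the APD by < 0.1 ms and a 10×
refinement moves every QOI by < 0.5% (regression-tested).

* **Threshold**: the minimum 0.5 ms pulse amplitude that drives V above
  0 mV within 50 ms of onset, by bisection on [0, 200] μA/cm² to 0.5%
  relative tolerance. The 0 mV criterion cleanly separates sub- and
  supra-threshold responses for this model.
* **Single AP**: 1000 ms horizon at 1.1× the per-parameter-set
  threshold (recomputed for every sample), stimulus at t = 0, starting
  from the resting initial conditions (no conditioning beats, so that
  results remain comparable at large σ̂ where pacing is impossible).
* **Pacing**: stimuli at the cycle length with full state carry-over;
  the default analysis paces 10 conditioning beats at 1 Hz and analyzes
  the next beat.
* **Dynamic restitution**: a strictly decreasing BCL schedule, 20 beats
  per BCL with continuous state, APD95 of the final beat per BCL
  (APD95 = activation to 95% repolarization of that AP's amplitude),
  DI = BCL − APD95; loss of 1:1 capture flags the row rather than
  aborting. The schedule and beats-per-BCL are package defaults — the
  protocol's source description leaves them open.

## Quantities of interest

Threshold (μA/cm²); MaxUpstrokeVelocity (mV/ms) and its time from
stimulus onset, taken over the window from onset to the voltage peak
within 50 ms; APA = peak upstroke voltage minus the voltage at stimulus
onset; APD = time from activation (first upward −70 mV crossing,
linearly interpolated) to the next downward crossing — a fixed threshold
rather than APD90 so APD does not inherit APA's parameter
sensitivities; NotchMin/NotchMax = the post-spike local minimum and the
following local maximum when the spike-and-dome morphology is present.
Undefined quantities carry explicit flags and are excluded from moments
(with the undefined fraction reported); they are never silently zero.

## Behavior taxonomy

Classification counts interior local extrema of the post-stimulus trace
(1000 ms horizon) after a **0.5 mV prominence filter** that merges
solver- or noise-scale wiggle; "early" means within 10 ms of stimulus
onset:

1. dome without spike — one maximum, later than 10 ms, no minimum;
2. spike without dome — one maximum within 10 ms, no minimum;
3. oscillatory — two or more minima (EADs, repolarization failure), or
   exactly two maxima and one minimum with the first maximum later than
   10 ms (a late-rising variant that lacks the early spike);
4. normal — everything else, including the nominal spike-and-dome AP.

Class 3 splits by V at 1000 ms: 3A below −75 mV (returned to rest), 3B
above −25 mV (repolarization failure), 3C in between (low-voltage
oscillations); the three bands partition the class. Sub-behavior
filtering conditions on the full sample by default (conditioning within
class 3 only is available as an option). The prominence value is the one
genuinely free knob in the taxonomy; behavior probabilities shift by
fractions of a percentage point as it varies, which is the main known
source of residual disagreement in borderline statistics (see
Limitations).

## Uncertainty model

A single hyper-parameter σ̂ scales every parameter's uncertainty. The
ten half-(in)activation voltages are normal, `p ~ N(p_nom, (σ̂ R)²)`
with reference range R = 100 mV — using a common reference keeps
voltages near 0 mV (such as E_d) from being artificially pinned. All
strictly positive parameters (g, k, τ, δ_h) are lognormal,
`log p ~ N(log p_nom − σ̂²/2, σ̂²)`, whose mean is exactly p_nom and
whose sd is ≈ σ̂·p_nom. All parameters are sampled independently;
E_Na/E_K/E_Ca stay fixed. σ̂ = 0 degenerates every distribution to a
point mass. One root seed spawns an independent child stream per
parameter in canonical column order, so adding an analysis step never
shifts another parameter's draws.

Propagation summaries report per-QOI mean, sd and CoV over the defined
rows, the undefined fraction, 50-bin histograms spanning mean ± 40%
(fixed axes make spreads comparable across QOIs), and a convergence
flag: mean (sd) must agree to three (two) significant figures between
the N- and N/2-sample estimates.

## Sensitivity analysis

Sobol indices use the Saltelli pick-freeze design built from one
scrambled Sobol sequence in 2k dimensions (scipy.stats.qmc), mapped
through each parameter's quantile function: base_n·(k + 2) model runs
for k parameters. Estimators: S1 by the Saltelli-2010 form
`mean(f_B (f_ABi − f_A))/V`, ST by Jansen's `mean((f_A − f_ABi)²)/(2V)`.
Errors are half-widths of the central 95% interval over 100 bootstrap
resamples of base-sample indices. Undefined QOI values fail loudly —
variance decomposition over a censored sample is meaningless — so Sobol
runs are intended for σ̂ ≈ 1%, where no failures occur. Both estimators
are oracle-tested against analytic indices on linear and
pure-interaction functions.

Morris screening uses randomized one-at-a-time trajectories on a
4-level grid (Δ = 2/3 in unit-hypercube coordinates, 50 trajectories by
default); elementary effects are measured per unit of the hypercube
coordinate, μ* is the mean absolute effect and σ its spread. Parameters
with μ* below 1% of the largest μ* are screened out before a Saltelli
design is spent on an expensive QOI. Trajectories containing an
undefined value are discarded and counted.

## Monte Carlo filtering

For a target behavior, the per-parameter conditional distributions
(behavior vs. not) are compared with the two-sample Kolmogorov–Smirnov
test (asymptotic p-values; appropriate at M ≈ 10⁴ with both split sets
≥ 10). Categories: D_stat > 0.2 highly influential; else p < 0.01
influential; else not influential — applied per parameter without
multiplicity correction, by design. Behavior-conditioned Pearson
correlations take δ_h on the log scale (its sampling law is lognormal),
reported as `log_delta_h`.

## 1D monodomain strand

`χ(Cm ∂V/∂t + ΣI_ion) = ∂/∂x(σ ∂V/∂x)` on a 1 cm cable with no-flux
ends, χ = 1400 cm⁻¹, σ = 1.4 mS/cm, giving diffusivity σ/(χCm) =
0.001 cm²/ms. Strang splitting: Crank–Nicolson diffusion half-step
(second-order centered differences, Thomas solve), a full reaction step
(forward Euler for V, Rush–Larsen exponential updates for the gates),
then another diffusion half-step. Defaults dx = 0.005 cm, dt = 0.01 ms;
refining both by 2× moves the conduction velocity by < 1%
(regression-tested at < 2%). The wave is launched by a 1 ms pulse at 2×
the single-cell threshold in the first 0.05 cm; CV at convergence is
insensitive to this choice. Activation is the first upward −70 mV
crossing per node (interpolated in time); CV is measured between 0.25
and 0.75 cm, and tissue-level QOIs reuse the single-cell extractor on
the local trace at 0.75 cm (the threshold field is omitted — it is a 0D
protocol quantity). A failed wave flags the solution instead of raising.
At nominal parameters the strand conducts at ≈ 59 cm/s against the
60 cm/s calibration target.

## Study conditions used by the acceptance script

CoVs at σ̂ = 1% use n = 2,000 samples; behavior fractions use n = 2,000
at σ̂ = 3% and M = 10,000 at σ̂ = 5% (the same ensemble feeds the
normal-AP conditional correlation); the influential-parameter rescue
pins {E_h, δ_h, E_r, E_d, E_f} and uses n = 1,000. These sizes hold the
binomial/Monte Carlo standard errors of the reported quantities to a
few tenths of a percentage point. Each analysis derives its seed from
the single `--seed` argument through independent child streams.

## Known limitations

* The uncertainty distributions are prescribed, not empirically derived;
  all sensitivity conclusions are conditional on them.
* No intracellular ion dynamics, Markov channel models, temperature
  scaling or drug-block factors; the model is not meant to reproduce
  voltage-clamp current details.
* The post-pacing peak |I_Kr| computed from the printed parameter values
  is ≈ 0.56 μA/cm², while the peak I_Kr/I_Ks *ratio* is 4.18, exactly
  the experimental ratio used as the original calibration constraint
  (0.46/0.11). The absolute experimental peaks are therefore not
  reproduced by the printed parameter set, only their ratio.
* The behavior taxonomy's extremum counting depends on the 0.5 mV
  prominence choice; borderline statistics (behavior fractions,
  conditional correlations near their tolerance edges) shift by
  fractions of their values under that choice.
* The strand solver is 1D only; no bidomain, anisotropy or 2D/3D
  geometry.
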