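# Methods

## The model

`burstrev` simulates evoked bursting reverberation in excitatory neuronal
networks with a mean-field description of short-term synaptic plasticity.
Three state variables evolve jointly: the population firing rate *h* (Hz),
the facilitation variable *x* (a proxy for residual presynaptic calcium and
hence release probability), and the available-neurotransmitter fraction *y*
(the running state of the releasable vesicle pools).  With the rectified
rate h⁺ = max(h, 0),

    τ ḣ = −h + J·x·y·h⁺
      ẋ = (X − x)/t_f + K(1 − x)h⁺
      ẏ = (1 − y)/t_r − L·x·y·h⁺

An electrical stimulus that succeeds in recruiting the network is modelled
as an instantaneous reset h ← H ("population spike"); the hard-reset
semantics (rather than h ← h + H) follows from reading the stimulus as
*setting* the network rate to H.  The product J·x·y is the effective
recurrent gain: a burst persists for as long as facilitation keeps that
gain pinned near 1 against the depletion of *y*, and terminates when
depression wins.  The reverberation time T_R is the first time after a
stimulus at which h falls back to the threshold h_T = 10 Hz.

The model deliberately contains no inhibitory population (the recordings it
describes were made with inhibition blocked pharmacologically) and no
single-cell spiking: it starts at the population-spike level.

## Parameters

| symbol | meaning | islands | slices | unit |
|--------|---------|---------|--------|------|
| τ      | rate relaxation time | 0.01 | 0.01 | s |
| t_f    | facilitation recovery time | 1.3 | 1.3 | s |
| t_r    | depression recovery time | 2 | 20 | s |
| J      | mean synaptic connectivity | 1.98 | 2.06 | – |
| K      | facilitation rate constant | 0.004 | 0.004 | per spike† |
| L      | depletion rate constant | 0.0054 | 0.037 | per spike† |
| X      | facilitation steady state | 0.5 | 0.5 | – |
| H      | stimulus-imposed rate | 50 | 50 | Hz |
| h_T    | burst-termination threshold | 10 | 10 | Hz |
| σ      | firing-rate noise amplitude | 2 | 2 | Hz |

† K and L multiply h⁺ in Hz to give rates in s⁻¹; the published tables
label them "Hz", but only this dimensionless-per-spike reading makes the
equations consistent and reproduces the printed burst durations, so the
numeric values are used as-is with h in Hz and t in s.

Five constants (τ, K, L, X, H) are literature values; J, t_f and t_r are
the free parameters that distinguish preparations, and σ is extracted from
trial-to-trial duration fluctuations.  Presets ship as YAML under
`burstrev/presets/` and load via `preset("islands")` / `preset("slices")`.

## Numerics

Fixed-step explicit Euler at dt = 1e-4 s (dt ≪ τ), with stimuli applied as
events on grid points; the stochastic variant is Euler–Maruyama with the
increment σ√dt·𝒩(0,1) added to h only (the τσω̇ forcing divided through by
τ leaves a diffusion coefficient of σ on h).  Using the same Euler drift in
both integrators makes σ = 0 reproduce the deterministic path bit for bit.
Justification of the step: halving dt moves the measured islands T_R by
~6e-6 relative, and the trajectory agrees with an adaptive LSODA solution
at rtol 1e-10 to max|Δh| ≈ 0.005 Hz over 5 s.  h may go transiently
negative under noise; every nonlinear coupling uses h⁺ and no reflecting
boundary is imposed.  x and y provably cannot leave [0, 1] at this step
size for the parameter ranges exercised (property-tested).

Threshold crossings are located from above, starting at the first grid
point after the stimulus where h ≥ h_T (so a reset is never mistaken for an
immediate termination), with linear interpolation between the bracketing
samples; no debounce window is applied (σ = 2 Hz is small against
h_T = 10 Hz, and a debounce would add a free parameter).  A burst with no
crossing inside its window (which ends at the next stimulus or trace end)
reports the window length with `terminated=False` instead of raising, so
parameter sweeps over extreme connectivity never abort.  At intervals
shorter than the burst itself this window rule yields the truncated
duration an experimenter would actually observe.

Randomness: one seed per trajectory; ensembles derive child seeds from a
master seed through `numpy.random.SeedSequence`, so every trial is
reproducible in isolation and dataset files are byte-identical across
reruns.

## Analytic estimate

During the early burst, h is approximated by the constant H in the x and y
equations; x then relaxes to x∞ = (X/t_f + KH)/(1/t_f + KH) with rate
1/t_f + KH (closed form), and y solves a linear equation handled by its
integrating factor with a dense-Simpson quadrature (agrees with direct
integration to ~1e-13).  Because the h equation is linear in h while h > 0,

    h(t) = H exp( (−t + J ∫₀ᵗ x y ds) / τ )

is exact given the true (x, y) path — the package evaluates the integral by
composite Simpson on the stored grid, and the representation matches the
simulated h to < 1e-3 relative over the first half of the burst.  Note the
1/τ on the integral: the same expression is sometimes written with the
integral outside the 1/τ, which is dimensionally inconsistent and off by a
factor of 100 at these parameters.

Expanding the integral for short times gives the closed form implemented in
`tr_closed_form` (θ = 1 − JXτ, prefactor a = JτXH(K − LX)):

    T_R(J) = [θ − √(θ² − 2a·τ ln(H/h_T))] / a

evaluated through the algebraically identical rationalized root
2τln(H/h_T)/(θ + √disc), which is immune to the catastrophic cancellation
the literal form suffers at small J.  The estimate is exact in the J → 0
limit (τ ln(H/h_T) = 16.09 ms) and flagged invalid when the discriminant is
negative or the prefactor vanishes.  Kept in exactly this grouping, the
expression stays near the uncoupled decay scale for all J and departs from
the reduced-system oracle by more than 2× for J ≳ 1.1; `compare_estimates`
measures and records that disagreement in its output metadata rather than
silently altering the formula, and its second differences in J are small
and *positive* (~2e-9 s at ΔJ = 0.05) — the printed expression is mildly
convex, not concave.  The reduced system itself is a good oracle: its T_R
stays within 7% of the full simulation up to the islands preset J.

## Synthetic data

The generator emulates the statistical structure of the recordings, not
their waveforms: per-trial burst durations from independent
noise realizations (σ = 2 Hz), sample sizes of order n = 20 (cultures) and
n = 22 (slices), and optional Gaussian measurement jitter on the measured
durations (default sd 0.1 s, truncated at zero — a declared stand-in
loosely matching the spread of the slice durations; no per-trial noise
decomposition of the original data exists to calibrate it further).
Optional population rasters render a rate trace as independent
inhomogeneous Poisson unit trains (each unit at intensity h⁺(t); no
refractoriness, since the mean-field model constrains only the rate);
binning at 50 ms, boxcar smoothing and the same 10 Hz threshold rule
recover the generating T_R to within a few percent at 100 units.  What
passing these tests shows is that the measurement pipeline is consistent
end to end; it does not validate the model against biological voltage
traces, synaptic currents, or non-Poisson spiking statistics.

## Parameter recovery

The fit identifies (J, t_f, t_r) from summary statistics of a session:
mean first-burst duration plus paired-pulse ratios, compared by squared
*relative* error (seconds-scale and ratio-scale residuals commensurate),
minimized by a coarse grid over declared bounds followed by bounded
least-squares refinement from the best grid points.  Deterministic model
predictions (σ = 0) are fitted to the noisy summaries; σ is estimated
separately by matching the ensemble sd of first-burst durations on a σ
grid (two-step, matching how the constants were originally extracted).

An identifiability caveat drove one design choice: with only the 5 s and
35 s summaries, (t_f, t_r) trade off almost exactly (the 35 s ratio is ~1
for any plausible t_r, leaving two informative numbers for three
parameters; the residual valley reaches 4e-9 at t_f almost double its true
value).  A ratio at a 2 s interval — short enough that residual
facilitation still matters — breaks the degeneracy, so the default summary
set is (first duration, ratio@2s, ratio@5s, ratio@35s) and the synthetic
paired-condition generator includes the 2 s condition by default.  With it,
noise-free self-fits recover the truth to machine precision and noisy
n = 20 sessions recover all three parameters to within a few percent.  The
fit reports per-parameter curvature of the objective at the optimum so flat
directions are visible rather than hidden.

## Design choices and known limitations

- Default J grid for sweeps: 0.5–4.0 in steps of 0.02, covering both preset
  values and the descending branch; "close to the optimum" is
  operationalized as T_R(preset) ≥ 0.9 × the grid maximum (no published
  tolerance exists).  The islands preset sits at 100% of its maximum, the
  slices preset at 88.7%.
- K and L families are swept at ±50% around the preset values rather than
  guessing unpublished family values.
- The calcium map X(Ca) = X0 + a(Ca − Ca0) uses the slope a = 0.0075/mM
  fixed by the two anchored conditions (2 mM → 0.5, 1 mM → 0.4925); it is a
  local linearization, not a fitted dose–response curve.
- The interval-ratio curve is not exactly monotone: near the connectivity
  optimum the second burst can *overshoot* the first by up to ~1.6% around
  10 s intervals (residual facilitation of order 1e-4 in x, amplified by
  the extreme sensitivity dT_R/dX ≈ 130 s per unit at the optimum, while
  depression has already recovered).  Tests assert the rising limb plus a
  2% band around unity beyond 10 s, which is the model's real behavior.
- With the islands constants, x(t) during the baseline first burst spans
  [0.50, 0.574]; the facilitation fixed point at the observed peak rate
  (~53 Hz) is 0.61, so excursions to ~0.75 would require sustained rates
  near 190 Hz that the model never produces.  The low-calcium span
  [0.4925, 0.523] and the strong first-burst/weak second-burst calcium
  asymmetry are reproduced (second burst moves 11.6% while the first halves).
- Problem sizes used throughout (500-run ensembles, 176-point J grids,
  20-trial sessions, 600 s spontaneous-activity runs) are the study's own
  scales; all are desk-scale with the JIT-compiled integrator.
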