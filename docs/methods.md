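# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations behind `dwellscope`. Nothing here states an empirical
result the test suite does not itself compute.

## Dwell-time model

With unfolding blocked (MTX-stabilized DHFR), termination of a binding
event is a single first-order dissociation, so event lifetimes are
exponential with mean τ. Dwell times below 120 s are compiled into an ECDF
evaluated at each **unique** dwell value (tied, frame-quantized dwells are
tallied, not repeated; a per-sample ECDF differs only in point weighting and
is available by passing raw dwells). The model

    F(t) = 1 − e^(−t/τ) + c,   |c| ≤ 0.025

is fitted by least-absolute-residual regression: iteratively reweighted
least squares with weights `1/max(|r_i|, 1e-6)`, each inner step a bounded
trust-region least squares, initialized at τ₀ = ECDF mean dwell, c₀ = 0,
declared converged when Δτ/τ < 1e-8 (cap 100 outer iterations, Nelder–Mead
fallback on the raw L1 objective otherwise). The additive offset c absorbs
small ECDF baseline error; r² is computed on the ECDF points with uniform
weights. No truncation correction is applied for the 120 s cutoff: for
τ ≳ 40 s this biases τ̂ downward, exactly as in the measurement convention
the package follows.

### Quantization bias of the span-counted dwell

A trace detected in frames `first..last` is assigned the dwell
`(last − first + 1)·Δt`. Under the half-frame visibility rule the frame
count of an event of true duration T is `round(t_off) − round(t_on)`, an
unbiased rounding of T — but single-frame traces are removed (they are
indistinguishable from nonspecific sticking), and the kept frame-count
distribution is then exactly geometric with CDF `1 − e^(−(k−1)/τ)` on
k ≥ 2: the continuous exponential **shifted by one frame**. Fitting the
unshifted model therefore inflates τ̂ by roughly one frame interval. At
Δt = 1 s this is ~+12% at τ = 5 s, ~+6% at τ = 10 s and ~+5% at τ = 30 s
(partly offset at longer τ by finite-movie censoring and the 120 s cutoff,
see below). The package reproduces this convention deliberately rather than
correcting it; analyses comparing conditions at similar τ are unaffected,
but absolute τ values at τ ≲ 10·Δt should be read with this inflation in
mind. The end-to-end recovery tests document it: τ = 10 s and τ = 30 s
recover within 15% for 10/10 seeds, τ = 5 s does not.

### Selection effects of the censoring rules

Two rules thin the dwell distribution in a length-dependent way:

* **Finite movie duration.** Only completed events count (boundary traces
  are censored), and completed dwells are length-biased downward by a
  factor ≈ (1 − τ/T). Movies should span T ≳ 30–40 τ; the recovery
  benchmarks use T = 30–40 τ.
* **Concurrent-proximity exclusion.** Both members of any concurrent pair
  within 1 μm are excluded, so the probability an event survives decays
  with its dwell: the observed distribution is tilted to
  `1/τ_obs = 1/τ + λπR²`, i.e. `τ_obs = τ/(1 + π·d)` at steady-state
  density d (puncta/μm², R = 1 μm). Keeping this bias under ~3% requires
  d ≲ 0.01/μm² — two orders of magnitude below the 1/μm² crowding cap. The
  recovery benchmarks run at d = 0.01/μm².

### Estimator efficiency

The ECDF-L1 fit is consistent but less efficient than the maximum-
likelihood estimator (the sample mean): on uncensored continuous samples of
a few hundred dwells the two can disagree by more than 5% for an
appreciable fraction of seeds (the disagreement is a property of the
estimator, not an optimization failure — grid search confirms the L1
optimum). The MLE-agreement test therefore uses n = 2000, where the
disagreement concentrates well below 5%.

## Movie simulator

The generator emulates the imaging regime the analysis assumes:

* arrivals: homogeneous Poisson in time and space over the field interior;
* dwells: exponential, mean `tau_true_s`;
* rendering: symmetric 2D Gaussian PSF (σ = 1.3 px default), full
  amplitude in every frame the event covers for ≥ 50% of the frame
  interval (frame i spans `[iΔt, (i+1)Δt)`); presence is binarized at the
  half-frame — partial-exposure dimming is not modelled;
* noise: per-pixel Poisson on signal + background, then additive Gaussian
  read noise, clipped at zero;
* blinking: i.i.d. per-frame dark switch, dark runs truncated at
  `blink_max_consecutive` (≤ 3 is recoverable by the 3-frame gap rule);
* events are placed ≥ `border_margin_px` (default 8 px) from the field
  edge, emulating the analyst's crop that guarantees every PSF a full fit
  window.

Defaults: 0.065 μm/px (100× objective, 6.5 μm sensor pixels), 1 s frames,
amplitude 200 ± 10 counts over a background of 20 with 2-count read noise.
The source instrument's camera gain, background and SNR are not published;
these are declared synthetic choices that put detection comfortably above
threshold. The simulator refuses configurations whose expected steady-state
density exceeds 1 punctum/μm².

What the simulator does **not** emulate — and hence what passing tests do
not demonstrate on real data: evanescent-field depth and TIR-angle effects,
stage drift, uneven illumination, camera-specific (e.g. sCMOS patterned)
noise, fluorophore photophysics beyond simple blinking, and diffusing
background molecules.

### Benchmark problem sizes

The end-to-end recovery benchmarks (τ ∈ {5, 10, 30} s, 10 seeds each) run
at 0.26 μm/px — a coarser grid than the 0.065 μm/px default — with the PSF
still 1.3 px wide and ~1000 kept events per movie. Dwell statistics are
invariant to the pixel scale (all distance rules are specified in μm and
converted exactly); localization fidelity at the native scale is covered by
dedicated detection tests. Fields are 196–277 px across and movies
200–1200 frames, sized to hold d = 0.01/μm² and T = 30–40 τ.

## Detection

Candidates are spatial local maxima of the across-scale maximum of the
scale-normalized LoG response `−σ²∇²(G_σ * I)` (default σ ∈ [1, 2] px, 5
scales), implemented directly on `scipy.ndimage` primitives for speed and
cross-checked against `skimage.feature.blob_log` in the tests. The
threshold is `log_threshold × (frame max − min)` (default 0.1; the LoG peak
of a spot of amplitude A is ≈ A/2), floored at five robust noise sigmas
(1.4826·MAD) of the response so empty frames emit no candidates.
Overlapping maxima are merged keeping the stronger. Refinement fits the
six-parameter Gaussian in a 9×9 window by a batched Levenberg–Marquardt
(all candidates of a frame at once; analytic Jacobian, multiplicative
damping, ≤ 30 iterations, step tolerance 1e-8). A fit is rejected on
non-convergence, non-positive amplitude, σ outside [0.3, 3]× the detected
scale, or a window clipped by the image edge. Quality gates: amplitude
≤ 5× the frame's median fitted amplitude ("too bright": aggregates or
impurities) and width ratio ≤ 2 ("not circular"); both are configurable
because the source convention states the rules qualitatively.

## Tracking

Greedy nearest-neighbour linking within 2 px per frame (molecules are
surface-tethered; 2 px ≈ 0.13 μm at the default pixel size), ties broken
deterministically by (distance, trace id, detection index). A trace stays
open through ≤ 3 missing frames. The four censoring rules are each
evaluated against the full pre-filter trace set, so the kept set is
independent of rule order; order only decides which reason a
multiply-condemned trace records. Bridged gap frames count toward the dwell
by default (the punctum is deemed present while dark;
`extract_dwells(include_gap_frames=False)` gives the alternative). The
"same x-y coordinates" rule uses a tolerance (`same_site_radius_px`,
default 2 px) because sub-pixel centroids never coincide exactly; all
traces at a repeated site are removed, since the uniqueness of every event
there is compromised. Both members of a concurrent pair within 1 μm are
removed.

## Bulk kinetics

Degradation: `corrected(t) = (F_t/F_0) / (F_t^ctrl/F_0^ctrl)`, fitted with
an ordinary least-squares line over the first 20% of the time course by
default (the near-linear regime of 1 − kt; configurable window);
`k = −slope` in min⁻¹. The optional molar conversion
`k·[S]/[ClpX]` (substrates·min⁻¹·hexamer⁻¹) is parameterized by the caller —
assay concentrations are inputs, not defaults. ATPase: light path from a
0–1.2 mM NADH standard series by a through-origin least-squares slope
divided by ε = 6.22 mM⁻¹cm⁻¹; the net rate is
`(|slope_sample| − |slope_background|)/(6.22·lightpath)` in mM·min⁻¹,
clipped at zero with a warning if the PK/LDH leak exceeds the signal. ATP
cost is the plain quotient of the per-hexamer rates and is invariant to
common rescaling.

## Sequence complexity

The score is the Shannon entropy (base 2) of the residue composition —
the K1 variant of the Wootton–Federhen compositional complexity — evaluated
on the whole motif; classification uses the unrounded score against a
strict `> 2.5` bits threshold, and rounding to 2 d.p. is display-only. The
full SEG segmentation machinery (trigger/extension windows, P₀ masking) is
out of scope; `window_complexity` provides a plain sliding-window
convenience.

## Comparison utilities

Replicate τ values are compared with standard stock procedures: two-sample
t test for two groups, one-way ANOVA followed by all-pairs Tukey HSD for
three or more, and a Bonferroni-adjusted per-contrast threshold α/m when m
planned contrasts are declared. Groups with fewer than two replicates are
excluded with a warning.

## Reproducibility

All randomness in a pipeline run derives from the single config seed;
identical configs reproduce every output bit-identically (asserted by
test). Movies are exchanged as multi-page TIFF plus a JSON sidecar
(frame interval, pixel size, parameters, seed) and a truth CSV; plates as
long-format CSV with roles sample / bleach_control / background / standard.
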