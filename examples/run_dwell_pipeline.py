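"""Simulate a small TIRF binding movie and recover the mean dwell time.

Generates a ground-truth-annotated movie (puncta arriving at a Poisson rate,
exponential dwells with tau = 10 s, Gaussian PSFs over shot + read noise),
then runs the full analysis: LoG spot detection, 2D Gaussian localization,
gap-tolerant trace linking, the four trace-exclusion rules, and the robust
exponential-CDF fit of the pooled dwell ECDF.
"""

from dwellscope import MovieSimParams, RunConfig, TrackingParams, run_dwell_pipeline

TAU_TRUE = 10.0

config = RunConfig(
    seed=1,
    simulation=MovieSimParams(
        field_w_px=200,
        field_h_px=200,
        pixel_size_um=0.26,
        n_frames=300,
        tau_true_s=TAU_TRUE,
        arrival_rate_per_um2_s=0.001,  # steady-state density 0.01 puncta/um^2
        amp_mean=300.0,
        amp_sd=15.0,
    ),
    tracking=TrackingParams(same_site_radius_px=1.0),
)

report = run_dwell_pipeline(config)
fit = report.fit
print(f"true tau          : {TAU_TRUE:.1f} s")
print(f"fitted tau        : {fit.tau_s:.2f} s  (offset c = {fit.c:+.4f}, r^2 = {fit.r2:.4f})")
print(f"kept dwell events : {fit.n_events}")
print(f"trace accounting  : {report.accounting['removed_by_reason']}")
print(
    "\ntau is the mean lifetime of the substrate-ClpX complex; the offset c"
    "\n(|c| <= 0.025) absorbs small ECDF baseline error, and every removed trace"
    "\ncarries one of the four censoring reasons shown above."
)
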