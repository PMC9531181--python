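# dwellscope

Single-molecule TIRF dwell-time analysis for AAA+ protease binding assays,
with companion tools for bulk ClpXP kinetics and substrate-sequence
complexity scoring.

## The problem

ClpXP is a bacterial AAA+ protease: the hexameric unfoldase ClpX grips a
substrate's unstructured tail through its axial pore and pulls, unfolding
the substrate for degradation by ClpP. When the folded domain resists
unfolding, the machine stalls in a *preunfolding dwell* during which its
grip can slip and the substrate can dissociate. How long a substrate stays
bound — the mean dwell time τ — depends on the length and amino-acid
composition of the tail engaged by the pore loops.

In the TIRF binding assay, biotinylated ClpX hexamers are immobilized on a
passivated coverslip and fluorophore-labelled, unfoldable (MTX-stabilized
DHFR) substrates are added. Each captured molecule appears as a
diffraction-limited punctum; its appearance-to-disappearance span is one
binding event. With unfolding blocked, dissociation is a single first-order
step, so dwell times are exponentially distributed with mean τ.

`dwellscope` implements the complete measurement chain:

1. **synthetic_data** — ground-truth-annotated movie simulator (Poisson
   arrivals, exponential dwells, 2D Gaussian PSFs, shot + read noise,
   optional blinking) and plate-reader simulators for the bulk assays. Raw
   imaging data for this kind of experiment are rarely deposited; the
   simulator makes every downstream stage testable end to end.
2. **detection** — per-frame punctum candidates from scale-normalized
   Laplacian-of-Gaussian maxima, refined by a 2D Gaussian PSF fit
   `I(x,y) = A·exp(−((x−x0)²/2σx² + (y−y0)²/2σy²)) + b`, with brightness
   and circularity quality gates.
3. **tracking** — greedy nearest-neighbour trace linking with a 3-frame gap
   tolerance (fluorophore blinking), then four censoring rules: traces
   touching the first/last frame, single-frame traces, both members of any
   concurrent pair closer than 1 μm, and all traces sharing a site at
   different times.
4. **dwell_model** — dwell times under 120 s compiled into an ECDF at the
   unique dwell values and fitted with `F(t) = 1 − e^(−t/τ) + c`,
   `|c| ≤ 0.025`, by least-absolute-residual regression (IRLS with a
   simplex fallback); reports τ, c, r² and the event count, plus t-test /
   ANOVA + Tukey HSD / Bonferroni utilities for comparing τ across
   conditions.
5. **bulk_kinetics** — photobleach-corrected degradation rates
   (`F(t) = −k·t + B` on the corrected fraction), NADH-coupled ATPase rates
   (`rate = ΔAbs340/Δt / (6.22 · lightpath)`, path length calibrated from an
   NADH standard series, PK/LDH background subtracted), and the ATP cost of
   degradation (ATPase rate ÷ degradation rate).
6. **sequence_complexity** — the SEG compositional complexity
   `K = −Σ (n_i/L)·log₂(n_i/L)` in bits over the 20-letter amino-acid
   alphabet, with the conventional 2.5-bit high-complexity threshold.
7. **pipeline / CLI** — one-config, one-seed orchestration of
   simulate → detect → track → fit with full provenance and bit-identical
   re-runs (`dwellscope run --config run.json --out outdir`).

## Worked example

`examples/run_dwell_pipeline.py` simulates a 300-frame movie (τ = 10 s,
steady-state density 0.01 puncta/μm²) and runs the full analysis:

```
true tau          : 10.0 s
fitted tau        : 11.50 s  (offset c = +0.0108, r^2 = 0.9945)
kept dwell events : 491
trace accounting  : {'boundary': 24, 'single_frame': 61, 'repeated_site': 55, 'concurrent_proximity': 5}
```

τ̂ is the fitted mean dwell; the small positive deviation from the true τ is
the expected one-frame quantization inflation discussed in
`docs/methods.md`. Every censored trace is accounted for by one of the four
exclusion reasons.

`examples/score_motifs.py` scores the substrate tail motifs:

```
      name    sequence  length  score_bits classification
     Ref11 GLGARSAGITH      11        2.85           high
   polyG11 GGGGGGGGGGG      11        0.00            low
      GA11 AGAGGAAGAGG      11        0.99            low
      GS11 SGSGGSSGSGG      11        0.99            low
    SUMO11 AKPSTEDLGDK      11        3.10           high
SUMO11_rev KDGLDETSPKA      11        3.10           high
```

`examples/plate_kinetics.py` recovers bulk kinetics from simulated plates
(noise 0.2% of signal):

```
degradation k      : 0.0201 /min (true 0.0200), r^2 = 0.9998
light path         : 0.2998 cm (true 0.3000)
ATPase rate        : 0.01006 mM/min (true 0.01000)
ATP cost           : 501 ATP per substrate degraded
```

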