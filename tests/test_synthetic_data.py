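"""Statistical and contract tests of the TIRF movie / plate simulators."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dwellscope import (
    Movie,
    MovieSimParams,
    PlateSimParams,
    read_movie,
    sample_dwells,
    simulate_movie,
    simulate_plate,
    visible_frame_range,
    write_movie,
)

from tests._oracles import quantized_dwell_mean


# ---------------------------------------------------------------- parameters


@pytest.mark.parametrize(
    "kwargs",
    [
        {"tau_true_s": -1.0},
        {"frame_interval_s": 0.0},
        {"pixel_size_um": 0.0},
        {"blink_off_prob": 1.0},
        {"blink_max_consecutive": -1},
        {"arrival_rate_per_um2_s": -0.01},
    ],
)
def test_invalid_movie_params_rejected(kwargs):
    with pytest.raises(ValueError):
        MovieSimParams(**kwargs)


def test_crowding_bound_enforced():
    """Expected steady-state density above 1 punctum/um^2 is refused."""
    with pytest.raises(ValueError, match="crowding"):
        MovieSimParams(tau_true_s=20.0, arrival_rate_per_um2_s=0.06)


def test_long_blink_runs_warn():
    with pytest.warns(UserWarning, match="gap rule"):
        MovieSimParams(blink_max_consecutive=5)


# ---------------------------------------------------------------- movies


def _small_params(**over):
    base = dict(
        field_w_px=48,
        field_h_px=48,
        pixel_size_um=0.5,
        n_frames=60,
        tau_true_s=5.0,
        arrival_rate_per_um2_s=0.02,
        amp_mean=300.0,
        amp_sd=10.0,
        seed=11,
    )
    base.update(over)
    return MovieSimParams(**base)


def test_no_arrivals_gives_pure_background():
    p = _small_params(arrival_rate_per_um2_s=0.0)
    mv = simulate_movie(p)
    assert mv.truth == []
    assert abs(float(mv.stack.mean()) - p.background) < 1.0
    assert float(mv.stack.min()) >= 0.0


def test_identical_seed_bitwise_reproducible():
    p = _small_params()
    a, b = simulate_movie(p), simulate_movie(p)
    assert np.array_equal(a.stack, b.stack)
    assert [e.__dict__ for e in a.truth] == [e.__dict__ for e in b.truth]


def test_different_seed_differs():
    a = simulate_movie(_small_params(seed=1))
    b = simulate_movie(_small_params(seed=2))
    assert not np.array_equal(a.stack, b.stack)


def test_truth_dwells_are_exponential():
    """Mean within 3 SE of tau and KS test against Exponential(tau) at alpha=0.01."""
    p = MovieSimParams(
        field_w_px=32,
        field_h_px=32,
        pixel_size_um=1.0,
        n_frames=900,
        tau_true_s=20.0,
        arrival_rate_per_um2_s=0.045,
        amp_mean=300.0,
        seed=5,
    )
    mv = simulate_movie(p)
    dwells = np.array([e.dwell_true_s for e in mv.truth])
    assert len(dwells) >= 10_000
    se = p.tau_true_s / np.sqrt(len(dwells))
    assert abs(dwells.mean() - p.tau_true_s) < 3 * se
    ks = stats.kstest(dwells, "expon", args=(0, p.tau_true_s))
    assert ks.pvalue > 0.01


def test_event_counts_are_poisson():
    """Chi-square goodness of fit of event counts over 200 seeded runs, alpha=0.01."""
    p0 = dict(
        field_w_px=24,
        field_h_px=24,
        pixel_size_um=1.0,
        border_margin_px=4.0,
        n_frames=30,
        tau_true_s=4.0,
        arrival_rate_per_um2_s=0.002,
        amp_mean=300.0,
    )
    counts = np.array(
        [len(simulate_movie(MovieSimParams(**p0, seed=s)).truth) for s in range(200)]
    )
    lam = p0["arrival_rate_per_um2_s"] * MovieSimParams(**p0).area_um2 * 30.0
    assert 5 < lam < 40  # keep the chi-square binning meaningful
    # bin the Poisson support so every expected count is >= 5
    edges = [0]
    acc = 0.0
    for k in range(0, 200):
        acc += stats.poisson.pmf(k, lam) * 200
        if acc >= 5:
            edges.append(k + 1)
            acc = 0.0
    edges[-1] = 10_000
    observed, _ = np.histogram(counts, bins=edges)
    expected = np.diff([stats.poisson.cdf(e - 0.5, lam) for e in edges]) * 200
    expected *= observed.sum() / expected.sum()
    chi2 = stats.chisquare(observed, expected)
    assert chi2.pvalue > 0.01


def test_instantaneous_density_within_bound():
    """Per-frame punctum density never exceeds the configured crowding bound."""
    p = _small_params(n_frames=120, arrival_rate_per_um2_s=0.04, tau_true_s=5.0)
    mv = simulate_movie(p)
    bound_count = 1.0 * p.area_um2  # 1 punctum per um^2
    for f in range(mv.n_frames):
        alive = sum(
            1
            for e in mv.truth
            if (span := visible_frame_range(e.t_on_s, e.t_off_s, 1.0, p.n_frames))
            and span[0] <= f <= span[1]
        )
        assert alive <= bound_count


def test_blinking_respects_max_consecutive():
    p = _small_params(blink_off_prob=0.4, blink_max_consecutive=2, tau_true_s=8.0)
    mv = simulate_movie(p)
    saw_dark = False
    for ev in mv.truth:
        if not ev.dark_frames:
            continue
        saw_dark = True
        runs = np.split(np.array(ev.dark_frames), np.where(np.diff(ev.dark_frames) > 1)[0] + 1)
        assert max(len(r) for r in runs) <= 2
    assert saw_dark


def test_movie_tiff_roundtrip(tmp_path):
    mv = simulate_movie(_small_params())
    write_movie(mv, tmp_path, stem="mv")
    back = read_movie(tmp_path / "mv.tif")
    assert np.allclose(back.stack, mv.stack)
    assert back.frame_interval_s == mv.frame_interval_s
    assert len(back.truth) == len(mv.truth)
    assert back.truth[0].x_px == pytest.approx(mv.truth[0].x_px)


# ---------------------------------------------------------------- dwell sampling


def test_sample_dwells_contract():
    one = sample_dwells(10.0, 1, 1.0, seed=3)
    assert one.shape == (1,) and one[0] >= 2.0
    assert np.array_equal(one, sample_dwells(10.0, 1, 1.0, seed=3))
    with pytest.raises(ValueError):
        sample_dwells(-1.0, 10, 1.0)
    with pytest.raises(ValueError):
        sample_dwells(10.0, 0, 1.0)


def test_sample_dwells_mean_matches_quantization_oracle():
    """Frame rounding shifts the mean to E[dt*max(2, ceil(T/dt))], computed
    independently by numerical summation (about 20.55 s at tau=20, dt=1)."""
    tau, dt, n = 20.0, 1.0, 100_000
    d = sample_dwells(tau, n, dt, seed=9)
    expected = quantized_dwell_mean(tau, dt, min_frames=2)
    assert expected == pytest.approx(20.55, abs=0.02)
    se = d.std() / np.sqrt(n)
    assert abs(d.mean() - expected) < 4 * se


def test_sample_dwells_continuum_limit():
    """As the frame interval shrinks the quantization bias vanishes."""
    tau = 7.0
    assert quantized_dwell_mean(tau, 1e-4) == pytest.approx(tau, rel=1e-3)
    d = sample_dwells(tau, 20_000, 1e-4, seed=2)
    assert abs(d.mean() - tau) < 4 * tau / np.sqrt(20_000)


# ---------------------------------------------------------------- plates


def test_plate_constant_when_rates_zero():
    p = PlateSimParams(mode="degradation", k_deg_per_min=0.0, k_bleach_per_min=0.0, noise_sd=0.0)
    df = simulate_plate(p)
    assert df.groupby("well")["value"].nunique().eq(1).all()


def test_bleach_factor_cancels_in_ratio():
    """sample/control ratio equals 1 - k_deg*t exactly for noise-free wells."""
    p = PlateSimParams(mode="degradation", k_deg_per_min=0.02, k_bleach_per_min=0.01,
                       noise_sd=0.0, n_replicates=1)
    df = simulate_plate(p)
    s = df[df.role == "sample"].set_index("time_min")["value"]
    c = df[df.role == "bleach_control"].set_index("time_min")["value"]
    t = s.index.to_numpy()
    assert np.allclose((s / c).to_numpy(), 1.0 - 0.02 * t, atol=1e-9)


def test_standard_absorbance_beer_lambert():
    """Abs340 of a 1.0 mM standard at 0.3 cm path is 6.22*0.3*1.0 = 1.866."""
    p = PlateSimParams(mode="nadh_standard", lightpath_cm=0.3, noise_sd=0.0)
    df = simulate_plate(p)
    row = df[np.isclose(df.nadh_mM, 1.0)].iloc[0]
    assert row.value == pytest.approx(1.866, abs=1e-12)


def test_negative_signal_truncates_with_warning():
    p = PlateSimParams(mode="degradation", k_deg_per_min=0.05, k_bleach_per_min=0.0,
                       noise_sd=0.0, n_replicates=1,
                       t_points_min=tuple(float(t) for t in range(0, 41)))
    with pytest.warns(UserWarning, match="truncated"):
        df = simulate_plate(p)
    sample_t = df[df.role == "sample"]["time_min"]
    assert sample_t.max() <= 20.0  # 1 - 0.05 t < 0 beyond t = 20
    assert (df[df.role == "sample"]["value"] >= 0).all()


def test_plate_mode_validation():
    with pytest.raises(ValueError):
        PlateSimParams(mode="unknown")
    with pytest.raises(ValueError):
        PlateSimParams(t_points_min=(0.0, 0.0, 1.0))
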