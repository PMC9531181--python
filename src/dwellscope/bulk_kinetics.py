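"""Bulk degradation and ATPase kinetics.

Degradation of GFP-tagged substrate is followed as fluorescence loss.  The
sample trace is normalized to its initial value, corrected for photobleaching
by dividing with the matched bleach-control ratio, and fitted with a straight
line F(t) = -k*t + B, where k is the fractional fluorescence loss rate per
minute.

ATP hydrolysis is followed through the NADH-coupled relay (PK/LDH): each ATP
hydrolyzed oxidizes one NADH, read as declining absorbance at 340 nm.  The
optical path length of the plate well is calibrated from an NADH standard
series via Beer-Lambert, Abs340 = 6.22 (mM^-1 cm^-1) * lightpath (cm) * [NADH],
and the absorbance slope is converted to a molar rate by
rate = dAbs340/dt / (6.22 * lightpath), after subtracting the leak rate of
the PK/LDH mix measured in background wells.

The ATP cost of degradation is the ratio of the ATPase rate to the
degradation rate, both expressed per ClpX hexamer per minute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NADH_EXTINCTION_MM_CM",
    "DegradationFit",
    "AtpaseFit",
    "bleach_correct",
    "fit_degradation",
    "calibrate_pathlength",
    "fit_atpase",
    "atp_cost",
]

#: molar extinction coefficient of NADH at 340 nm, mM^-1 cm^-1
NADH_EXTINCTION_MM_CM = 6.22


@dataclass(frozen=True)
class DegradationFit:
    """Linear fit of the bleach-corrected fluorescence fraction."""

    k_per_min: float          # fractional fluorescence loss rate
    intercept: float
    r2: float
    rate_per_clpx: float | None = None  # substrates min^-1 hexamer^-1


@dataclass(frozen=True)
class AtpaseFit:
    """NADH-coupled ATPase rate derived from the Abs340 slope."""

    lightpath_cm: float
    slope_abs_per_min: float
    rate_mM_min: float
    rate_per_clpx: float | None = None  # ATP min^-1 hexamer^-1
    background_subtracted: bool = False


def _as_series(series: pd.Series | np.ndarray, index=None) -> pd.Series:
    if isinstance(series, pd.Series):
        return series.astype(float)
    return pd.Series(np.asarray(series, dtype=float), index=index)


def bleach_correct(sample: pd.Series, control: pd.Series) -> pd.Series:
    """Photobleach-corrected fluorescence fraction.

    corrected(t) = (F_t / F_0) / (F_t^ctrl / F_0^ctrl) on a shared time grid;
    corrected(0) = 1 exactly.  The series is truncated with a warning where
    the control reaches zero or below.
    """
    sample = _as_series(sample)
    control = _as_series(control)
    if not sample.index.equals(control.index):
        raise ValueError("sample and control must share the same time grid")
    f0, c0 = sample.iloc[0], control.iloc[0]
    if f0 <= 0 or c0 <= 0:
        raise ValueError("initial fluorescence must be positive in both series")
    bad = np.flatnonzero(control.to_numpy() <= 0)
    if bad.size:
        warnings.warn(
            f"bleach control reaches <= 0 at t={control.index[bad[0]]:g}; truncated",
            stacklevel=2,
        )
        sample = sample.iloc[: bad[0]]
        control = control.iloc[: bad[0]]
    return (sample / f0) / (control / c0)


def fit_degradation(
    corrected: pd.Series,
    window: tuple[float, float] | None = None,
    substrate_conc_uM: float | None = None,
    clpx_conc_uM: float | None = None,
) -> DegradationFit:
    """OLS line through the corrected fraction; k is the negated slope.

    ``window`` is a (t_min, t_max) range in minutes; the default is the first
    20% of the time course, the near-linear regime of (1 - k t).  When both
    substrate and ClpX hexamer concentrations are given, the fractional rate
    is converted to substrates degraded per hexamer per minute via
    ``k * [S] / [ClpX]``.
    """
    corrected = _as_series(corrected)
    t = corrected.index.to_numpy(dtype=float)
    if window is None:
        window = (t[0], t[0] + 0.2 * (t[-1] - t[0]))
    lo, hi = window
    if lo < t[0] - 1e-12 or hi > t[-1] + 1e-12:
        raise ValueError("window outside data range")
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 3:
        raise ValueError("need >= 3 points inside the fit window")
    y = corrected.to_numpy(dtype=float)[mask]
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite corrected values in window")
    res = stats.linregress(t[mask], y)
    k = -float(res.slope)
    rate_per_clpx = None
    if substrate_conc_uM is not None and clpx_conc_uM is not None:
        if clpx_conc_uM <= 0:
            raise ValueError("clpx_conc_uM must be positive")
        rate_per_clpx = k * substrate_conc_uM / clpx_conc_uM
    return DegradationFit(
        k_per_min=k,
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        rate_per_clpx=rate_per_clpx,
    )


def calibrate_pathlength(
    standards: pd.DataFrame | tuple[np.ndarray, np.ndarray],
) -> float:
    """Light path (cm) from an NADH standard series.

    Fits Abs340 = 6.22 * lightpath * [NADH] through the origin (least
    squares); ``standards`` is a DataFrame with ``nadh_mM`` and ``value``
    columns, or a (concentration, absorbance) pair of arrays.
    """
    if isinstance(standards, pd.DataFrame):
        conc = standards["nadh_mM"].to_numpy(dtype=float)
        absorbance = standards["value"].to_numpy(dtype=float)
    else:
        conc, absorbance = (np.asarray(a, dtype=float) for a in standards)
    if conc.size < 3:
        raise ValueError("need >= 3 standards")
    if np.ptp(conc) <= 0:
        raise ValueError("standards must span a positive concentration range")
    denom = float(np.sum(conc**2))
    slope = float(np.sum(conc * absorbance)) / denom
    if slope <= 0:
        raise ValueError("non-positive absorbance-concentration slope")
    return slope / NADH_EXTINCTION_MM_CM


def _slope(series: pd.Series, window: tuple[float, float] | None) -> float:
    t = series.index.to_numpy(dtype=float)
    y = series.to_numpy(dtype=float)
    if window is not None:
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
        if mask.sum() < 2:
            raise ValueError("fewer than 2 points inside the fit window")
        t, y = t[mask], y[mask]
    return float(stats.linregress(t, y).slope)


def fit_atpase(
    abs_series: pd.Series,
    lightpath_cm: float,
    background_series: pd.Series | None = None,
    clpx_conc_mM: float | None = None,
    window: tuple[float, float] | None = None,
) -> AtpaseFit:
    """ATP hydrolysis rate from the decline of Abs340.

    The net rate is (|sample slope| - |background slope|) / (6.22 * lightpath)
    in mM/min, clipped at zero (with a warning) if the PK/LDH leak exceeds
    the sample signal.  With ``clpx_conc_mM`` the rate is also expressed as
    ATP per hexamer per minute.
    """
    if lightpath_cm <= 0:
        raise ValueError("lightpath_cm must be positive")
    s_sample = abs(_slope(_as_series(abs_series), window))
    s_bg = 0.0
    if background_series is not None:
        s_bg = abs(_slope(_as_series(background_series), window))
    net_slope = s_sample - s_bg
    if net_slope < 0:
        warnings.warn("background slope exceeds sample slope; rate clipped at 0", stacklevel=2)
        net_slope = 0.0
    rate = net_slope / (NADH_EXTINCTION_MM_CM * lightpath_cm)
    rate_per_clpx = None
    if clpx_conc_mM is not None:
        if clpx_conc_mM <= 0:
            raise ValueError("clpx_conc_mM must be positive")
        rate_per_clpx = rate / clpx_conc_mM
    return AtpaseFit(
        lightpath_cm=lightpath_cm,
        slope_abs_per_min=net_slope,
        rate_mM_min=rate,
        rate_per_clpx=rate_per_clpx,
        background_subtracted=background_series is not None,
    )


def atp_cost(atpase_rate_per_clpx: float, degradation_rate_per_clpx: float) -> float:
    """ATP hydrolyzed per substrate degraded (ratio of per-hexamer rates)."""
    if degradation_rate_per_clpx <= 0:
        raise ValueError("degradation rate must be positive for a defined ATP cost")
    return atpase_rate_per_clpx / degradation_rate_per_clpx
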