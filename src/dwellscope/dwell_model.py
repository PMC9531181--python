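"""Exponential dwell-time model fitted to an empirical CDF.

For a substrate that cannot be unfolded, binding termination is a single
first-order dissociation step, so the dwell-time distribution is a single
exponential with mean tau.  Dwell times below 120 s are compiled into an
empirical cumulative distribution function evaluated at each unique dwell
value, and the model

    F(t) = 1 - exp(-t / tau) + c,      |c| <= 0.025

is fitted by least-absolute-residual (L1) regression: iteratively reweighted
least squares with weights 1 / max(|residual|, 1e-6), initialized at the
sample-mean dwell, with a derivative-free simplex fallback on
non-convergence.  The bounded offset c absorbs small baseline errors in the
ECDF.  The goodness of fit r^2 is reported on the ECDF points with uniform
weights.

No truncation correction is applied to tau: the 120 s cutoff biases the
estimate downward once tau approaches ~40 s, which is accepted as part of
the measurement definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .tracking import DwellSet

__all__ = [
    "Ecdf",
    "DwellFit",
    "ComparisonReport",
    "build_ecdf",
    "fit_exponential_cdf",
    "compare_taus",
]


@dataclass(frozen=True)
class Ecdf:
    """Empirical CDF at unique dwell values below the truncation limit."""

    t: np.ndarray
    F: np.ndarray
    n: int
    n_truncated: int = 0

    def __post_init__(self) -> None:
        if len(self.t) != len(self.F) or len(self.t) == 0:
            raise ValueError("t and F must be equal-length and non-empty")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(np.diff(self.F) < 0) or self.F[0] <= 0 or abs(self.F[-1] - 1) > 1e-12:
            raise ValueError("F must be non-decreasing in (0, 1] with F[-1] = 1")

    @property
    def mean_dwell_s(self) -> float:
        dF = np.diff(np.concatenate([[0.0], self.F]))
        return float(np.sum(self.t * dF))


@dataclass(frozen=True)
class DwellFit:
    """Result of the robust exponential-CDF fit."""

    tau_s: float
    c: float
    r2: float
    n_events: int
    n_truncated: int
    converged: bool
    n_iter: int

    def to_dict(self) -> dict:
        return {
            "tau_s": self.tau_s,
            "c": self.c,
            "r2": self.r2,
            "n_events": self.n_events,
            "n_truncated": self.n_truncated,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def build_ecdf(dwells: DwellSet | np.ndarray, max_dwell_s: float = 120.0) -> Ecdf:
    """Compile dwell times below ``max_dwell_s`` into an ECDF.

    The ECDF is evaluated at each unique dwell value (tied dwells are tallied,
    not repeated).  Dwells at or above the cutoff are dropped and counted in
    ``n_truncated``.
    """
    values = dwells.dwell_s if isinstance(dwells, DwellSet) else np.asarray(dwells, float)
    if values.size == 0:
        raise ValueError("no dwell times supplied")
    keep = values[values < max_dwell_s]
    n_truncated = int(values.size - keep.size)
    if keep.size == 0:
        raise ValueError(f"all dwells are >= {max_dwell_s} s; no fittable data")
    t, counts = np.unique(keep, return_counts=True)
    F = np.cumsum(counts) / keep.size
    F[-1] = 1.0  # guard against rounding
    return Ecdf(t=t, F=F, n=int(keep.size), n_truncated=n_truncated)


def _model(t: np.ndarray, tau: float, c: float) -> np.ndarray:
    return 1.0 - np.exp(-t / tau) + c


def fit_exponential_cdf(
    ecdf: Ecdf,
    c_bound: float = 0.025,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> DwellFit:
    """L1 fit of ``1 - exp(-t/tau) + c`` to the ECDF points.

    Minimizes the sum of absolute residuals over tau > 0, |c| <= c_bound via
    IRLS (each iteration a bounded nonlinear weighted least squares), starting
    from tau = mean dwell, c = 0.  Falls back to Nelder-Mead on the L1
    objective directly if IRLS fails to settle.
    """
    if len(ecdf.t) < 3:
        raise ValueError("need at least 3 distinct dwell values to fit")
    t, F = ecdf.t, ecdf.F
    tau = max(ecdf.mean_dwell_s, 1e-9)
    c = 0.0
    w = np.ones_like(F)
    converged = False
    n_iter = 0
    lower = [1e-12, -c_bound]
    upper = [np.inf, c_bound]
    for n_iter in range(1, max_iter + 1):
        sw = np.sqrt(w)
        sol = optimize.least_squares(
            lambda p: sw * (F - _model(t, p[0], p[1])),
            x0=[tau, np.clip(c, -c_bound, c_bound)],
            bounds=(lower, upper),
            method="trf",
        )
        tau_new, c_new = sol.x
        if abs(tau_new - tau) / max(tau, 1e-12) < tol:
            tau, c = tau_new, c_new
            converged = True
            break
        tau, c = tau_new, c_new
        resid = F - _model(t, tau, c)
        w = 1.0 / np.maximum(np.abs(resid), 1e-6)

    if not converged:
        # simplex fallback on the raw L1 objective
        def l1(p: np.ndarray) -> float:
            tt = max(p[0], 1e-12)
            cc = float(np.clip(p[1], -c_bound, c_bound))
            return float(np.sum(np.abs(F - _model(t, tt, cc))))

        res = optimize.minimize(l1, x0=[tau, c], method="Nelder-Mead")
        tau = max(float(res.x[0]), 1e-12)
        c = float(np.clip(res.x[1], -c_bound, c_bound))
        converged = bool(res.success)
        if not converged:
            warnings.warn("exponential CDF fit did not converge", stacklevel=2)

    resid = F - _model(t, tau, c)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((F - F.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DwellFit(
        tau_s=float(tau),
        c=float(c),
        r2=float(np.clip(r2, 0.0, 1.0)),
        n_events=ecdf.n,
        n_truncated=ecdf.n_truncated,
        converged=converged,
        n_iter=n_iter,
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Cross-condition comparison of fitted tau values."""

    summary: pd.DataFrame          # condition, n, mean, sd
    pairwise: pd.DataFrame         # group_a, group_b, statistic, p_value, significant
    test: str                      # "t-test" or "anova+tukey"
    anova_p: float | None
    alpha: float
    per_contrast_alpha: float


def compare_taus(
    groups: dict[str, list[float]],
    alpha: float = 0.05,
    m_contrasts: int | None = None,
) -> ComparisonReport:
    """Compare replicate tau estimates across conditions.

    Two groups are compared by a two-sample t test; three or more by one-way
    ANOVA followed by all-pairs Tukey HSD.  When ``m_contrasts`` planned
    contrasts are declared, the per-contrast significance threshold is the
    Bonferroni-adjusted ``alpha / m_contrasts``.
    """
    usable: dict[str, np.ndarray] = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            warnings.warn(f"group {name!r} has < 2 replicates; excluded", stacklevel=2)
            continue
        usable[name] = arr
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with >= 2 replicates")

    threshold = alpha / m_contrasts if m_contrasts else alpha
    names = list(usable)
    summary = pd.DataFrame(
        {
            "condition": names,
            "n": [usable[n].size for n in names],
            "mean": [usable[n].mean() for n in names],
            "sd": [usable[n].std(ddof=1) for n in names],
        }
    )

    rows = []
    if len(usable) == 2:
        a, b = names
        res = stats.ttest_ind(usable[a], usable[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
            }
        )
        test, anova_p = "t-test", None
    else:
        anova = stats.f_oneway(*usable.values())
        tukey = stats.tukey_hsd(*usable.values())
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append(
                    {
                        "group_a": names[i],
                        "group_b": names[j],
                        "statistic": float(tukey.statistic[i, j]),
                        "p_value": float(tukey.pvalue[i, j]),
                    }
                )
        test, anova_p = "anova+tukey", float(anova.pvalue)

    pairwise = pd.DataFrame(rows)
    pairwise["significant"] = pairwise["p_value"] < threshold
    return ComparisonReport(
        summary=summary,
        pairwise=pairwise,
        test=test,
        anova_p=anova_p,
        alpha=alpha,
        per_contrast_alpha=threshold,
    )
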