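"""Per-frame punctum detection.

Candidate puncta are found as local maxima of the scale-normalized
Laplacian-of-Gaussian (LoG) response over a small range of scales, then
refined by nonlinear least-squares fitting of a six-parameter 2D Gaussian

    I(x, y) = A * exp(-((x - x0)^2 / (2 sx^2) + (y - y0)^2 / (2 sy^2))) + b

in a window around each candidate.  Detections that are implausibly bright
(amplitude far above the frame median) or not circular (extreme sx/sy ratio)
are filtered out, mirroring the quality gates of single-molecule TIRF
processing.

The Gaussian refinement runs as a batched Levenberg-Marquardt over all
candidates of a frame at once, which keeps full-movie processing fast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "DetectionParams",
    "Detection",
    "detect_blobs",
    "fit_gaussian2d",
    "fit_gaussian2d_batch",
    "filter_detections",
    "detect_frame",
    "detect_movie",
]


@dataclass(frozen=True)
class DetectionParams:
    """Knobs of the LoG search, Gaussian refinement, and quality filters.

    ``log_threshold`` is relative to the frame's intensity range: a candidate
    must exceed ``log_threshold * (max - min)`` in scale-normalized LoG
    response (the response of a Gaussian spot of amplitude A peaks near A/2,
    so the default 0.1 sits well below real puncta and well above shot
    noise).
    ``fit_window_px`` is the half-width of the square fit window.
    ``max_amp_factor`` rejects detections brighter than that multiple of the
    frame's median fitted amplitude; ``circ_ratio_max`` is the largest
    allowed max(sx, sy)/min(sx, sy).
    """

    log_sigma_min_px: float = 1.0
    log_sigma_max_px: float = 2.0
    log_n_scales: int = 5
    log_threshold: float = 0.1
    fit_window_px: int = 4
    max_amp_factor: float = 5.0
    circ_ratio_max: float = 2.0

    def __post_init__(self) -> None:
        if self.log_sigma_min_px <= 0 or self.log_sigma_max_px < self.log_sigma_min_px:
            raise ValueError("LoG sigma range must be positive and ordered")
        if self.log_n_scales < 1:
            raise ValueError("log_n_scales must be >= 1")
        if not 0 < self.log_threshold < 1:
            raise ValueError("log_threshold is a relative threshold in (0, 1)")
        if self.fit_window_px < 2 * self.log_sigma_max_px:
            raise ValueError("fit_window_px must be >= 2 * log_sigma_max_px")
        if self.max_amp_factor <= 1:
            raise ValueError("max_amp_factor must exceed 1")
        if self.circ_ratio_max < 1:
            raise ValueError("circ_ratio_max must be >= 1")

    @property
    def sigmas(self) -> np.ndarray:
        if self.log_n_scales == 1:
            return np.array([0.5 * (self.log_sigma_min_px + self.log_sigma_max_px)])
        return np.linspace(self.log_sigma_min_px, self.log_sigma_max_px, self.log_n_scales)


@dataclass
class Detection:
    """A sub-pixel punctum localization in one frame."""

    frame: int
    x_px: float
    y_px: float
    amplitude: float
    sigma_x_px: float
    sigma_y_px: float
    offset: float
    fit_ok: bool
    scale_px: float = float("nan")
    reject_reason: str | None = None

    @property
    def circ_ratio(self) -> float:
        lo = min(abs(self.sigma_x_px), abs(self.sigma_y_px))
        hi = max(abs(self.sigma_x_px), abs(self.sigma_y_px))
        return float("inf") if lo == 0 else hi / lo


def detect_blobs(
    frame_image: np.ndarray, params: DetectionParams
) -> list[tuple[float, float, float]]:
    """Find candidate puncta as scale-space LoG maxima.

    Returns ``(x, y, scale)`` tuples, one per blob.  The response at each
    scale sigma is ``-sigma^2 * LoG(image)`` (scale-normalized, sign-flipped
    so bright blobs give positive peaks); candidates are spatial local maxima
    of the across-scale maximum response above ``log_threshold`` times the
    frame's intensity range.  Overlapping responses collapse to the single
    strongest pixel by construction of the maximum filter.
    """
    img = np.asarray(frame_image, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError("frame_image must be 2D")
    if np.any(img < 0):
        raise ValueError("frame_image must be non-negative")
    win = 2 * params.fit_window_px + 1
    if min(img.shape) < win:
        warnings.warn("image smaller than the fit window; no detections", stacklevel=2)
        return []
    if img.max() == img.min():
        return []

    sigmas = params.sigmas
    best = None
    best_scale = None
    for s in sigmas:
        resp = -(s * s) * ndi.gaussian_laplace(img, s, output=np.float32)
        if best is None:
            best = resp
            best_scale = np.full(img.shape, s, dtype=np.float32)
        else:
            better = resp > best
            best = np.where(better, resp, best)
            best_scale = np.where(better, np.float32(s), best_scale)
    # primary threshold: relative to the frame's intensity range; floor: five
    # robust noise sigmas of the LoG response, so empty/noise-only frames do
    # not emit candidates
    med = float(np.median(best))
    noise_sigma = 1.4826 * float(np.median(np.abs(best - med)))
    threshold = max(
        params.log_threshold * float(img.max() - img.min()), 5.0 * noise_sigma
    )
    if float(best.max()) <= threshold:
        return []
    local_max = ndi.maximum_filter(best, size=3, mode="constant")
    mask = (best == local_max) & (best > threshold)
    ys, xs = np.nonzero(mask)
    order = np.argsort(-best[ys, xs], kind="stable")
    # merge overlapping responses (plateau ties, double-detected blobs),
    # keeping the stronger candidate
    kept: list[tuple[float, float, float]] = []
    for i in order:
        x, y = float(xs[i]), float(ys[i])
        scale = float(best_scale[ys[i], xs[i]])
        r_merge = np.sqrt(2.0) * scale
        if all((x - kx) ** 2 + (y - ky) ** 2 > r_merge**2 for kx, ky, _ in kept):
            kept.append((x, y, scale))
    return kept


# --------------------------------------------------------------------------
# batched 2D Gaussian refinement
# --------------------------------------------------------------------------


def _lm_fit_windows(
    windows: np.ndarray, init: np.ndarray, max_iter: int = 30, xtol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Levenberg-Marquardt fit of A*exp(...)+b to a batch of square windows.

    ``windows`` is (N, S, S); ``init`` is (N, 6) with columns
    (A, dx, dy, sx, sy, b), dx/dy relative to the window centre.
    Returns the fitted (N, 6) parameters and a per-window convergence flag.
    """
    n, s, _ = windows.shape
    r = (s - 1) // 2
    grid = np.arange(-r, r + 1, dtype=np.float64)
    xx = np.tile(grid, s)          # flattened column coordinate
    yy = np.repeat(grid, s)        # flattened row coordinate
    data = windows.reshape(n, s * s).astype(np.float64)

    p = init.astype(np.float64).copy()
    lam = np.full(n, 1e-3)
    eye = np.eye(6)

    def model_and_jac(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A, dx, dy, sx, sy, b = (p[:, i][:, None] for i in range(6))
        sx = np.abs(sx) + 1e-12
        sy = np.abs(sy) + 1e-12
        ux = (xx[None, :] - dx) / sx
        uy = (yy[None, :] - dy) / sy
        e = np.exp(-0.5 * (ux**2 + uy**2))
        m = A * e + b
        J = np.empty((n, s * s, 6))
        J[:, :, 0] = e
        J[:, :, 1] = A * e * ux / sx
        J[:, :, 2] = A * e * uy / sy
        J[:, :, 3] = A * e * ux**2 / sx
        J[:, :, 4] = A * e * uy**2 / sy
        J[:, :, 5] = 1.0
        return m, J

    m, J = model_and_jac(p)
    resid = data - m
    cost = np.einsum("np,np->n", resid, resid)
    converged = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        g = np.einsum("npi,np->ni", J, resid)
        H = np.einsum("npi,npj->nij", J, J)
        damped = H.copy()
        diag_idx = np.arange(6)
        damped[:, diag_idx, diag_idx] += lam[:, None] * np.maximum(
            H[:, diag_idx, diag_idx], 1e-12
        )
        try:
            step = np.linalg.solve(damped, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            damped = damped + 1e-8 * eye[None]
            step = np.linalg.solve(damped, g[:, :, None])[:, :, 0]
        p_new = p + step
        m_new, J_new = model_and_jac(p_new)
        resid_new = data - m_new
        cost_new = np.einsum("np,np->n", resid_new, resid_new)
        improved = cost_new <= cost
        p = np.where(improved[:, None], p_new, p)
        lam = np.where(improved, lam * 0.3, lam * 5.0)
        lam = np.clip(lam, 1e-9, 1e6)
        step_rel = np.abs(step).max(axis=1) / (1.0 + np.abs(p).max(axis=1))
        converged |= improved & (step_rel < xtol)
        m = np.where(improved[:, None], m_new, m)
        resid = np.where(improved[:, None], resid_new, resid)
        cost = np.where(improved, cost_new, cost)
        J = np.where(improved[:, None, None], J_new, J)
        if converged.all():
            break
    p[:, 3] = np.abs(p[:, 3])
    p[:, 4] = np.abs(p[:, 4])
    return p, converged


def fit_gaussian2d_batch(
    frame_image: np.ndarray,
    candidates: list[tuple[float, float, float]],
    params: DetectionParams,
    frame_index: int = 0,
) -> list[Detection]:
    """Refine a frame's candidates with the batched 2D Gaussian fit."""
    img = np.asarray(frame_image, dtype=np.float64)
    h, w = img.shape
    r = params.fit_window_px
    dets: list[Detection] = []
    windows: list[np.ndarray] = []
    meta: list[tuple[int, int, float]] = []  # (cx, cy, scale) for fitted entries
    init: list[list[float]] = []
    for x, y, scale in candidates:
        cx, cy = int(round(x)), int(round(y))
        if cx - r < 0 or cy - r < 0 or cx + r >= w or cy + r >= h:
            dets.append(
                Detection(
                    frame=frame_index,
                    x_px=float(x),
                    y_px=float(y),
                    amplitude=float("nan"),
                    sigma_x_px=float("nan"),
                    sigma_y_px=float("nan"),
                    offset=float("nan"),
                    fit_ok=False,
                    scale_px=scale,
                    reject_reason="edge_clipped",
                )
            )
            continue
        win = img[cy - r : cy + r + 1, cx - r : cx + r + 1]
        b0 = float(win.min())
        a0 = float(win.max() - b0)
        if a0 <= 0:  # degenerate flat window, nothing to fit
            dets.append(
                Detection(
                    frame=frame_index,
                    x_px=float(x),
                    y_px=float(y),
                    amplitude=0.0,
                    sigma_x_px=float("nan"),
                    sigma_y_px=float("nan"),
                    offset=b0,
                    fit_ok=False,
                    scale_px=scale,
                    reject_reason="flat_window",
                )
            )
            continue
        windows.append(win)
        meta.append((cx, cy, scale))
        init.append([a0, x - cx, y - cy, scale, scale, b0])

    if windows:
        p, conv = _lm_fit_windows(np.stack(windows), np.array(init))
        for (cx, cy, scale), pk, ok in zip(meta, p, conv):
            A, dx, dy, sx, sy, b = pk
            x_fit, y_fit = cx + dx, cy + dy
            reason = None
            fit_ok = True
            if not np.all(np.isfinite(pk)) or not ok:
                fit_ok, reason = False, "no_convergence"
            elif A <= 0:
                fit_ok, reason = False, "nonpositive_amplitude"
            elif not (0.3 * scale <= sx <= 3.0 * scale) or not (
                0.3 * scale <= sy <= 3.0 * scale
            ):
                fit_ok, reason = False, "sigma_out_of_range"
            elif not (0 <= x_fit < w and 0 <= y_fit < h):
                fit_ok, reason = False, "centre_outside_image"
            dets.append(
                Detection(
                    frame=frame_index,
                    x_px=float(x_fit),
                    y_px=float(y_fit),
                    amplitude=float(A),
                    sigma_x_px=float(sx),
                    sigma_y_px=float(sy),
                    offset=float(b),
                    fit_ok=fit_ok,
                    scale_px=float(scale),
                    reject_reason=reason,
                )
            )
    return dets


def fit_gaussian2d(
    frame_image: np.ndarray,
    candidate: tuple[float, float, float],
    params: DetectionParams,
    frame_index: int = 0,
) -> Detection:
    """Refine a single candidate (batch of one)."""
    return fit_gaussian2d_batch(frame_image, [candidate], params, frame_index)[0]


def filter_detections(
    detections: list[Detection], params: DetectionParams
) -> list[Detection]:
    """Apply the brightness and circularity gates; return kept detections.

    A detection is kept iff its fit succeeded, its amplitude is at most
    ``max_amp_factor`` times the median fitted amplitude of its frame, and its
    width ratio is at most ``circ_ratio_max``.  Rejected detections get a
    machine-readable ``reject_reason`` (input objects are annotated in place).
    """
    if not detections:
        return []
    kept: list[Detection] = []
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    for frame_dets in by_frame.values():
        ok_amps = [d.amplitude for d in frame_dets if d.fit_ok]
        med = float(np.median(ok_amps)) if ok_amps else float("nan")
        for d in frame_dets:
            if not d.fit_ok:
                d.reject_reason = d.reject_reason or "fit_failed"
                continue
            if d.amplitude > params.max_amp_factor * med:
                d.reject_reason = "too_bright"
                continue
            if d.circ_ratio > params.circ_ratio_max:
                d.reject_reason = "not_circular"
                continue
            d.reject_reason = None
            kept.append(d)
    kept.sort(key=lambda d: (d.frame, d.y_px, d.x_px))
    return kept


def detect_frame(
    frame_image: np.ndarray, params: DetectionParams, frame_index: int = 0
) -> list[Detection]:
    """LoG search + Gaussian refinement + quality filters for one frame."""
    cands = detect_blobs(frame_image, params)
    dets = fit_gaussian2d_batch(frame_image, cands, params, frame_index)
    return filter_detections(dets, params)


def detect_movie(stack: np.ndarray, params: DetectionParams) -> list[Detection]:
    """Run the full detection stage over every frame of a stack."""
    out: list[Detection] = []
    for f in range(stack.shape[0]):
        out.extend(detect_frame(stack[f], params, frame_index=f))
    return out
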