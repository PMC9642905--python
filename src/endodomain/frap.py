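"""FRAP curve normalization and single-exponential recovery fitting."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from endodomain.roi import DiscROI, PixelImage, disc_mask

__all__ = ["FrapCurve", "FrapFit", "extract_frap_curve", "normalize_frap", "fit_recovery", "analyze_frap"]


@dataclass(frozen=True)
class FrapCurve:
    """Per-frame ROI means of a photobleaching series.

    ``bleach_frame`` is the index of the first post-bleach frame; frames
    before it are pre-bleach.
    """

    times_s: np.ndarray
    bleach_mean: np.ndarray
    reference_mean: np.ndarray
    background_mean: np.ndarray
    bleach_frame: int

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("times_s", "bleach_mean", "reference_mean", "background_mean"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arrays[name])
        n = arrays["times_s"].size
        if any(a.size != n for a in arrays.values()):
            raise ValueError("all series must have the same length")
        if not np.all(np.diff(arrays["times_s"]) > 0):
            raise ValueError("times must be strictly increasing")
        if not 0 < self.bleach_frame < n:
            raise ValueError("bleach_frame must lie strictly inside the series")


@dataclass(frozen=True)
class FrapFit:
    mobile_fraction: float
    tau_s: float
    residual_sse: float
    converged: bool

    def __post_init__(self) -> None:
        if self.converged and not 0 <= self.mobile_fraction <= 1.5:
            raise ValueError("mobile_fraction outside [0, 1.5] flags a pathological fit")


def extract_frap_curve(
    frames: list[PixelImage],
    rois: dict[str, DiscROI],
    frame_interval_s: float,
    bleach_frame: int,
) -> FrapCurve:
    """Reduce a frame series to per-ROI mean traces."""
    masks = {k: disc_mask(frames[0], rois[k]) for k in ("bleach", "reference", "background")}
    means = {k: np.array([f.values[m].mean() for f in frames]) for k, m in masks.items()}
    times = np.arange(len(frames)) * frame_interval_s
    return FrapCurve(
        times_s=times,
        bleach_mean=means["bleach"],
        reference_mean=means["reference"],
        background_mean=means["background"],
        bleach_frame=bleach_frame,
    )


def normalize_frap(curve: FrapCurve, *, double: bool = True) -> np.ndarray:
    """Background-subtracted, reference-corrected double normalization.

    ``F(t) = [(B(t) - bg) / (R(t) - bg)] / <same quantity over pre-bleach frames>``
    so the pre-bleach mean of F is 1 by construction; acquisition fade common
    to the bleach and reference regions cancels.  ``double=False`` skips the
    reference correction (single normalization).

    Requires at least two pre-bleach frames and a reference strictly above
    background at every frame.
    """
    if curve.bleach_frame < 2:
        raise ValueError("need at least 2 pre-bleach frames")
    bg = curve.background_mean
    b = curve.bleach_mean - bg
    if double:
        r = curve.reference_mean - bg
        if np.any(r <= 0):
            raise ValueError("reference intensity at or below background")
        q = b / r
    else:
        q = b
    pre = q[: curve.bleach_frame].mean()
    if pre <= 0:
        raise ValueError("non-positive pre-bleach signal")
    return q / pre


def _recovery_model(t: np.ndarray, plateau: float, tau: float, f0: float) -> np.ndarray:
    return f0 + (plateau - f0) * (1 - np.exp(-t / tau))


def fit_recovery(
    normalized: np.ndarray,
    times_after_bleach: np.ndarray,
    prebleach_level: float = 1.0,
) -> FrapFit:
    """Least-squares single-exponential fit of the post-bleach recovery.

    Fits ``F(t) = F0 + (plateau - F0) * (1 - exp(-t/tau))`` with ``F0`` fixed
    to the first post-bleach value; ``mobile_fraction = (plateau - F0) /
    (prebleach_level - F0)``.  Non-convergence is reported through the
    ``converged`` flag, not an exception.
    """
    y = np.asarray(normalized, dtype=float)
    t = np.asarray(times_after_bleach, dtype=float)
    if y.size != t.size:
        raise ValueError("series and times must have the same length")
    if y.size < 4:
        raise ValueError("need at least 4 post-bleach points")
    f0 = float(y[0])
    span_t = float(t[-1] - t[0])
    n_last = max(1, y.size // 4)
    guess_plateau = float(y[-n_last:].mean())
    guess_tau = max(span_t / 2, 1e-9)
    try:
        popt, _ = curve_fit(
            lambda tt, plateau, tau: _recovery_model(tt, plateau, tau, f0),
            t,
            y,
            p0=[guess_plateau, guess_tau],
            bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
            maxfev=20_000,
        )
    except (RuntimeError, ValueError):
        return FrapFit(mobile_fraction=np.nan, tau_s=np.nan, residual_sse=np.nan, converged=False)
    plateau, tau = float(popt[0]), float(popt[1])
    denom = prebleach_level - f0
    mobile = (plateau - f0) / denom if denom != 0 else np.nan
    sse = float(np.sum((_recovery_model(t, plateau, tau, f0) - y) ** 2))
    converged = np.isfinite(mobile) and 0 <= mobile <= 1.5
    if not converged:
        return FrapFit(mobile_fraction=mobile if np.isfinite(mobile) else np.nan,
                       tau_s=tau, residual_sse=sse, converged=False)
    return FrapFit(mobile_fraction=mobile, tau_s=tau, residual_sse=sse, converged=True)


def analyze_frap(curve: FrapCurve, *, double: bool = True) -> tuple[np.ndarray, FrapFit]:
    """Normalize a curve and fit its post-bleach recovery in one call."""
    norm = normalize_frap(curve, double=double)
    post = slice(curve.bleach_frame, None)
    t_post = curve.times_s[post] - curve.times_s[curve.bleach_frame]
    fit = fit_recovery(norm[post], t_post)
    return norm, fit
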