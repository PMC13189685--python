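"""Tofts pharmacokinetic analysis of dynamic contrast-enhanced series.

The tissue model is the standard two-parameter Tofts model,

    C_t(t) = Ktrans * int_0^t C_p(tau) exp(-(Ktrans/Ve) (t - tau)) dtau,

with ``Ktrans`` (min^-1) the volume transfer coefficient between blood plasma
and the extravascular extracellular space and ``Ve`` its fractional volume.
Signal is converted to concentration under a linear signal-concentration
assumption (baseline-subtracted, single gain).  The analysis workflow mirrors
a clinical reading: the arterial input function (AIF) comes from an aortic
ROI, lesion curves are pixel-averaged over an ROI before fitting, parameters
from two adjacent slices are averaged into one session value, and two repeat
sessions are averaged into the final parameters.

The convolution uses an exponential-kernel recursion that is exact for a
piecewise-linear AIF, which keeps the forward model stable at the coarse
(~seconds) frame spacing of dynamic radial reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .recon import DynamicImageSeries

__all__ = [
    "AIF",
    "TissueCurve",
    "PKParams",
    "RoiSet",
    "signal_to_concentration",
    "tofts_forward",
    "extract_aif",
    "fit_tofts",
    "roi_workflow",
    "finalize_repeat",
    "pixelwise_maps",
]

# physical fit bounds and the multi-start grid for the bounded solver
KTRANS_BOUNDS = (0.0, 5.0)
VE_BOUNDS = (1e-3, 1.0)
START_GRID_KTRANS = (0.01, 0.1, 0.5)
START_GRID_VE = (0.1, 0.3, 0.6)


@dataclass(frozen=True)
class AIF:
    """Arterial input function: plasma concentration ``cp`` (arbitrary linear
    units) on a strictly increasing time grid in minutes; ``cp[0] = 0``."""

    times: np.ndarray
    cp: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.cp, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and cp must be 1-D arrays of equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("AIF times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("AIF concentrations must be >= 0")
        if c.size and c[0] != 0:
            raise ValueError("AIF must start at zero (pre-contrast)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cp", c)


@dataclass(frozen=True)
class TissueCurve:
    """Tissue concentration per timepoint (minutes), optionally recording how
    many pixels were averaged to form it."""

    times: np.ndarray
    ct: np.ndarray
    n_pixels_averaged: int = 1

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.ct, dtype=float)
        if not np.all(np.isfinite(c)):
            raise ValueError("tissue curve contains non-finite values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ct", c)


@dataclass(frozen=True)
class PKParams:
    """Fitted Tofts parameters with the residual sum of squares and an honest
    convergence flag."""

    ktrans: float
    ve: float
    fit_rss: float = np.nan
    converged: bool = True

    def __post_init__(self):
        if self.ktrans < 0:
            raise ValueError("ktrans must be >= 0")
        if not (0.0 <= self.ve <= 1.0):
            raise ValueError("ve must lie in [0, 1]")


@dataclass
class RoiSet:
    """ROI definitions for the reading workflow.

    ``lesions`` maps lesion id -> ((slice_a, mask_a), (slice_b, mask_b)) with
    the two slices adjacent (|a - b| <= 1; equal indices are allowed for
    single-partition 2-D series, where the two ROIs stand in for the two
    consecutive slices of a 3-D reading).  ``aorta`` and the optional
    ``muscle`` are (slice, mask) pairs.
    """

    lesions: dict
    aorta: tuple
    muscle: tuple | None = None

    def __post_init__(self):
        for lesion_id, ((sa, ma), (sb, mb)) in self.lesions.items():
            if abs(int(sa) - int(sb)) > 1:
                raise ValueError(f"lesion {lesion_id}: ROI slices must be adjacent")
            if not np.any(ma) or not np.any(mb):
                raise ValueError(f"lesion {lesion_id}: empty ROI mask")
        if not np.any(self.aorta[1]):
            raise ValueError("empty aorta mask")


def signal_to_concentration(
    signal: np.ndarray, n_baseline_frames: int, gain: float = 1.0
) -> np.ndarray:
    """Convert signal to concentration under the linear assumption:
    ``C(t) = gain * (S(t) - S0)`` with ``S0`` the mean of the first
    ``n_baseline_frames`` (pre-contrast) frames."""
    s = np.asarray(signal, dtype=float)
    if not (1 <= n_baseline_frames < s.shape[0]):
        raise ValueError("n_baseline_frames must be >= 1 and < series length")
    s0 = s[:n_baseline_frames].mean(axis=0)
    if np.any(s0 <= 0):
        raise ValueError("non-physical baseline: S0 <= 0")
    return gain * (s - s0)


def _conv_exp(times: np.ndarray, cp: np.ndarray, kep: float) -> np.ndarray:
    """``int_0^t cp(tau) exp(-kep (t - tau)) dtau`` on the sample grid,
    exact for piecewise-linear ``cp`` (recursive exponential kernel)."""
    out = np.zeros_like(cp, dtype=float)
    acc = 0.0
    for n in range(len(cp) - 1):
        dt = times[n + 1] - times[n]
        a = cp[n]
        b = (cp[n + 1] - cp[n]) / dt
        x = kep * dt
        if x > 1e-8:
            e = np.exp(-x)
            phi1 = -np.expm1(-x) / kep  # (1 - e) / kep
            phi2 = (dt - phi1) / kep
        else:  # series limit, stable for tiny kep*dt
            e = np.exp(-x)
            phi1 = dt * (1.0 - x / 2.0 + x * x / 6.0)
            phi2 = dt * dt * (0.5 - x / 6.0 + x * x / 24.0)
        acc = acc * e + a * phi1 + b * phi2
        out[n + 1] = acc
    return out


def tofts_forward(ktrans: float, ve: float, aif: AIF) -> TissueCurve:
    """Tissue concentration predicted by the standard Tofts model.

    ``C_t = Ktrans * (C_p (*) exp(-kep t))`` with ``kep = Ktrans / Ve``;
    ``C_t(0) = 0``.  ``ktrans = 0`` yields the zero curve; ``ve = 0`` with
    positive ``ktrans`` is rejected (undefined washout rate).
    """
    if ktrans < 0:
        raise ValueError("ktrans must be >= 0")
    if ktrans == 0:
        return TissueCurve(aif.times, np.zeros_like(aif.cp))
    if not (0.0 < ve <= 1.0):
        raise ValueError("ve must lie in (0, 1] when ktrans > 0")
    kep = ktrans / ve
    ct = ktrans * _conv_exp(aif.times, aif.cp, kep)
    return TissueCurve(aif.times, ct)


def extract_aif(
    series: DynamicImageSeries,
    aorta_mask: np.ndarray,
    n_baseline_frames: int,
    gain: float = 1.0,
) -> AIF:
    """AIF from the pixel-averaged aortic signal.

    The magnitude signal is averaged over the mask per frame and converted
    via :func:`signal_to_concentration`; small negative excursions from noise
    are clipped at zero and the first frame is pinned to zero (pre-contrast).
    Times are reported in minutes.
    """
    mask = np.asarray(aorta_mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty aorta mask")
    frames = series.magnitude()
    signal = frames[:, mask].mean(axis=1)
    cp = signal_to_concentration(signal, n_baseline_frames, gain)
    cp = np.clip(cp, 0.0, None)
    cp[0] = 0.0
    return AIF(times=series.frame_times / 60.0, cp=cp)


def fit_tofts(curve: TissueCurve, aif: AIF) -> PKParams:
    """Bounded nonlinear least-squares fit of the Tofts model to a curve.

    Minimises ``sum (ct - tofts_forward(ktrans, ve))^2`` over
    ``ktrans in [0, 5]``, ``ve in [0.001, 1]`` from a 3x3 multi-start grid,
    keeping the best local solution.  An identically-zero curve returns
    ``ktrans = 0`` exactly.
    """
    ct = np.asarray(curve.ct, dtype=float)
    if ct.size < 5:
        raise ValueError("need at least 5 timepoints to fit")
    if not (np.all(np.isfinite(ct)) and np.all(np.isfinite(aif.cp))):
        raise ValueError("non-finite input")
    if not np.any(aif.cp):
        raise ValueError("AIF is identically zero")
    if not np.any(ct):
        return PKParams(ktrans=0.0, ve=0.0, fit_rss=0.0, converged=True)

    times, cp = aif.times, aif.cp

    def residuals(params):
        kt, ve = params
        if kt == 0:
            model = np.zeros_like(ct)
        else:
            model = kt * _conv_exp(times, cp, kt / ve)
        return model - ct

    best = None
    for k0 in START_GRID_KTRANS:
        for v0 in START_GRID_VE:
            res = least_squares(
                residuals,
                x0=[k0, v0],
                bounds=([KTRANS_BOUNDS[0], VE_BOUNDS[0]], [KTRANS_BOUNDS[1], VE_BOUNDS[1]]),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            if best is None or res.cost < best.cost:
                best = res
    rss = float(2.0 * best.cost)
    return PKParams(
        ktrans=float(best.x[0]),
        ve=float(best.x[1]),
        fit_rss=rss,
        converged=bool(best.success),
    )


def _roi_curve(
    series: DynamicImageSeries,
    mask: np.ndarray,
    aif: AIF,
    n_baseline_frames: int,
    gain: float,
) -> TissueCurve:
    mask = np.asarray(mask, dtype=bool)
    signal = series.magnitude()[:, mask].mean(axis=1)
    ct = signal_to_concentration(signal, n_baseline_frames, gain)
    return TissueCurve(times=aif.times, ct=ct, n_pixels_averaged=int(mask.sum()))


def roi_workflow(
    series: DynamicImageSeries,
    rois: RoiSet,
    aif: AIF,
    n_baseline_frames: int = 5,
    gain: float = 1.0,
) -> dict:
    """One reading session: fit each lesion's two ROI-averaged curves and
    average the two fits into the session (ktrans, ve).

    Returns ``{lesion_id: PKParams}`` with the session values (``fit_rss`` is
    the sum over the two slice fits; ``converged`` is their conjunction).
    """
    out = {}
    for lesion_id, slice_rois in rois.lesions.items():
        fits = []
        for _slice_idx, mask in slice_rois:
            curve = _roi_curve(series, mask, aif, n_baseline_frames, gain)
            fits.append(fit_tofts(curve, aif))
        out[lesion_id] = PKParams(
            ktrans=float(np.mean([f.ktrans for f in fits])),
            ve=float(np.mean([f.ve for f in fits])),
            fit_rss=float(np.sum([f.fit_rss for f in fits])),
            converged=all(f.converged for f in fits),
        )
    return out


def finalize_repeat(session1: PKParams, session2: PKParams) -> PKParams:
    """Average two repeat reading sessions into the final parameters."""
    if session1 is None or session2 is None:
        raise ValueError("both sessions are required")
    return PKParams(
        ktrans=0.5 * (session1.ktrans + session2.ktrans),
        ve=0.5 * (session1.ve + session2.ve),
        fit_rss=session1.fit_rss + session2.fit_rss,
        converged=session1.converged and session2.converged,
    )


def pixelwise_maps(
    series: DynamicImageSeries,
    mask: np.ndarray,
    aif: AIF,
    n_baseline_frames: int = 5,
    gain: float = 1.0,
    histogram_bins: int = 32,
) -> dict:
    """Per-pixel Tofts fits over ``mask``: parameter maps plus histograms.

    Pixels outside the mask, and pixels whose fit fails, are NaN in the maps;
    failures are flagged in ``failed`` (never silently zeroed) and excluded
    from the histograms along with masked-out pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    shape = series.frames.shape[1:]
    ktrans_map = np.full(shape, np.nan)
    ve_map = np.full(shape, np.nan)
    failed = np.zeros(shape, dtype=bool)
    signals = series.magnitude()
    for p, q in zip(*np.nonzero(mask)):
        try:
            ct = signal_to_concentration(signals[:, p, q], n_baseline_frames, gain)
            params = fit_tofts(TissueCurve(aif.times, ct), aif)
        except ValueError:
            failed[p, q] = True
            continue
        if not params.converged:
            failed[p, q] = True
            continue
        ktrans_map[p, q] = params.ktrans
        ve_map[p, q] = params.ve
    ok = mask & ~failed
    kt_hist = np.histogram(ktrans_map[ok], bins=histogram_bins)
    ve_hist = np.histogram(ve_map[ok], bins=histogram_bins)
    return {
        "ktrans_map": ktrans_map,
        "ve_map": ve_map,
        "failed": failed,
        "ktrans_hist": kt_hist,
        "ve_hist": ve_hist,
    }
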