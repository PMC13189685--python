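"""Digital perfusion phantom, simulated radial k-space, and synthetic cohort.

Stands in for the clinical inputs of a lung DCE-MRI angiogenesis study:

* a 2-D digital phantom whose regions enhance according to the standard
  Tofts model under a known parametric arterial input function (the same
  forward code path used later for fitting, so phantom truth and analysis
  model agree exactly);
* multicoil golden-angle radial k-space simulated from that phantom with the
  same non-uniform Fourier operator the reconstruction inverts, plus
  additive complex Gaussian noise;
* a synthetic lesion cohort (default 25 lesions: 15 adenocarcinoma,
  8 squamous, 2 small-cell) with tumor sizes, nodal status and microvascular
  density (MVD, vessels per 0.723 mm^2) drawn as an affine function of the
  true Ktrans so the population Ktrans-MVD correlation hits a configurable
  target (default 0.738).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from . import pk
from .radial import CoilSensitivities, MultiCoilKSpace, NufftOperator, RadialTrajectory

__all__ = [
    "Region",
    "PhantomSpec",
    "PhantomTruth",
    "LesionRecord",
    "parametric_aif",
    "generate_phantom",
    "simulate_kspace",
    "generate_cohort",
    "DEFAULT_HISTOLOGY_PARAMS",
    "DEFAULT_N_PER_HISTOLOGY",
]

HISTOLOGIES = ("adenocarcinoma", "squamous", "small_cell")

#: Per-histology (mean, SD) of true Ktrans (min^-1), Ve (fraction) and MVD
#: (vessels / 0.723 mm^2) used as generator defaults; these reproduce the
#: group structure of a 25-patient lung-cancer cohort.
DEFAULT_HISTOLOGY_PARAMS = {
    "adenocarcinoma": {"ktrans": (0.36, 0.26), "ve": (0.27, 0.13), "mvd": (49.09, 29.84)},
    "squamous": {"ktrans": (0.34, 0.17), "ve": (0.26, 0.12), "mvd": (53.85, 23.53)},
    "small_cell": {"ktrans": (0.13, 0.15), "ve": (0.14, 0.06), "mvd": (37.20, 28.28)},
}
DEFAULT_N_PER_HISTOLOGY = {"adenocarcinoma": 15, "squamous": 8, "small_cell": 2}
DEFAULT_TARGET_R = 0.738
#: Fraction of lesions larger than 3 cm (19 of 25 in the reference design).
DEFAULT_LARGE_FRACTION = 19 / 25


@dataclass(frozen=True)
class Region:
    """A circular phantom region with uniform pharmacokinetic truth.

    ``center`` is (row, col) in pixels; ``ktrans`` in min^-1; ``ve`` a
    fraction in (0, 1]; ``baseline`` the pre-contrast signal level.
    """

    name: str
    center: tuple
    radius: float
    ktrans: float
    ve: float
    baseline: float = 1.0

    def mask(self, grid_size: int) -> np.ndarray:
        yy, xx = np.mgrid[0:grid_size, 0:grid_size]
        return (yy - self.center[0]) ** 2 + (xx - self.center[1]) ** 2 <= self.radius**2


@dataclass(frozen=True)
class AIFParams:
    """Parametric population AIF: gamma-variate first-pass bolus plus a slow
    exponential washout tail, zero before the bolus arrival ``t0`` (minutes).

    The bolus term peaks at amplitude ``bolus_amp`` at ``t0 + t_peak``; the
    tail rises with rate ``beta`` and decays with rate ``gamma`` (min^-1).
    Units of concentration are arbitrary (linear gain convention).
    """

    t0: float = 50.0 / 60.0
    bolus_amp: float = 6.0
    t_peak: float = 0.25
    alpha: float = 2.5
    tail_amp: float = 1.0
    beta: float = 6.0
    gamma: float = 0.2


def parametric_aif(times_min: np.ndarray, params: AIFParams | None = None) -> np.ndarray:
    """Evaluate the parametric AIF on a time grid (minutes)."""
    p = params or AIFParams()
    t = np.asarray(times_min, dtype=float) - p.t0
    cp = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    bolus = p.bolus_amp * (tp / p.t_peak) ** p.alpha * np.exp(p.alpha * (1.0 - tp / p.t_peak))
    tail = p.tail_amp * (1.0 - np.exp(-p.beta * tp)) * np.exp(-p.gamma * tp)
    cp[pos] = bolus + tail
    return cp


@dataclass
class PhantomSpec:
    """Specification of the digital phantom.

    ``noise_sd`` is the complex-noise standard deviation used downstream by
    :func:`simulate_kspace`, expressed relative to the RMS magnitude of the
    noiseless baseline-frame k-space.
    """

    grid_size: int = 64
    region_defs: list = field(default_factory=list)
    aorta_region: Region | None = None
    n_timepoints: int = 16
    frame_interval: float = 10.0  # seconds
    noise_sd: float = 0.02
    n_coils: int = 8
    seed: int = 0
    background_baseline: float = 0.2
    gain: float = 1.0
    aif_params: AIFParams = field(default_factory=AIFParams)
    edge_smooth_px: float = 0.0

    def validate(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints")
        masks = []
        for r in self.region_defs:
            if r.ktrans < 0:
                raise ValueError(f"region {r.name}: ktrans must be >= 0")
            if r.ktrans > 0 and not (0.0 < r.ve <= 1.0):
                raise ValueError(
                    f"region {r.name}: ve must lie in (0, 1] (ve=0 with "
                    "ktrans>0 has an undefined washout rate)"
                )
            masks.append((r.name, r.mask(self.grid_size)))
        if self.aorta_region is not None:
            masks.append(("aorta", self.aorta_region.mask(self.grid_size)))
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if np.any(masks[i][1] & masks[j][1]):
                    raise ValueError(
                        f"regions '{masks[i][0]}' and '{masks[j][0]}' overlap"
                    )


@dataclass
class PhantomTruth:
    """Ground truth generated from a :class:`PhantomSpec`: per-pixel parameter
    maps, the dynamic object, the true AIF, and integer region labels
    (0 = background, 1.. = regions in definition order, last id = aorta)."""

    ktrans_map: np.ndarray
    ve_map: np.ndarray
    dynamic_object: np.ndarray  # (T, N, N) real
    aif_truth: np.ndarray
    times_min: np.ndarray
    region_labels: np.ndarray
    spec: PhantomSpec


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build the noiseless dynamic phantom object.

    Each region's signal is ``baseline + gain * C_t(t)`` with ``C_t`` from
    :func:`graspdce.pk.tofts_forward` under the spec's parametric AIF (shared
    code path with the fitting side); aorta pixels carry
    ``baseline + gain * C_p(t)``; pixels outside all regions stay at the
    background baseline for all t.  Deterministic.
    """
    spec.validate()
    n = spec.grid_size
    times_min = np.arange(spec.n_timepoints) * spec.frame_interval / 60.0
    cp = parametric_aif(times_min, spec.aif_params)
    aif = pk.AIF(times=times_min, cp=cp)

    obj = np.full((spec.n_timepoints, n, n), spec.background_baseline, dtype=float)
    ktrans_map = np.zeros((n, n))
    ve_map = np.zeros((n, n))
    labels = np.zeros((n, n), dtype=int)

    for idx, region in enumerate(spec.region_defs, start=1):
        mask = region.mask(n)
        curve = pk.tofts_forward(region.ktrans, region.ve, aif)
        signal = region.baseline + spec.gain * curve.ct
        obj[:, mask] = signal[:, None]
        ktrans_map[mask] = region.ktrans
        ve_map[mask] = region.ve
        labels[mask] = idx

    if spec.aorta_region is not None:
        mask = spec.aorta_region.mask(n)
        signal = spec.aorta_region.baseline + spec.gain * cp
        obj[:, mask] = signal[:, None]
        labels[mask] = len(spec.region_defs) + 1

    if spec.edge_smooth_px > 0:
        # soft tissue boundaries (partial-volume realism); region interiors
        # more than ~3 sigma from an edge keep their exact Tofts curves
        from scipy.ndimage import gaussian_filter

        obj = np.stack([gaussian_filter(f, spec.edge_smooth_px) for f in obj])

    return PhantomTruth(
        ktrans_map=ktrans_map,
        ve_map=ve_map,
        dynamic_object=obj,
        aif_truth=cp,
        times_min=times_min,
        region_labels=labels,
        spec=spec,
    )


def simulate_kspace(
    truth: PhantomTruth,
    trajectory: RadialTrajectory,
    coils: CoilSensitivities,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> MultiCoilKSpace:
    """Simulate multicoil radial k-space from the dynamic phantom.

    Each spoke samples the non-uniform Fourier transform of the object held
    at that spoke's acquisition time (frame ``floor(t / frame_interval)``),
    multiplied by each coil map, plus i.i.d. complex Gaussian noise with
    standard deviation ``noise_sd`` times the RMS magnitude of the noiseless
    baseline-frame (frame 0) samples.  Deterministic given ``seed``.
    """
    spec = truth.spec
    n = spec.grid_size
    if coils.grid_size != n:
        raise ValueError(
            f"coil maps ({coils.grid_size}) do not match phantom grid ({n})"
        )
    if noise_sd is None:
        noise_sd = spec.noise_sd
    if seed is None:
        seed = spec.seed

    n_frames = truth.dynamic_object.shape[0]
    frame_idx = np.clip(
        np.floor(trajectory.timestamps / spec.frame_interval).astype(int),
        0,
        n_frames - 1,
    )
    samples = np.empty(
        (trajectory.n_spokes, trajectory.n_readout, coils.n_coils), dtype=np.complex128
    )
    for f in np.unique(frame_idx):
        spoke_sel = np.nonzero(frame_idx == f)[0]
        sub = trajectory.subset(spoke_sel)
        op = NufftOperator(sub, n)
        coil_imgs = coils.maps * truth.dynamic_object[f][None]
        y = op.forward(coil_imgs)  # (C, M)
        samples[spoke_sel] = np.moveaxis(
            y.reshape(coils.n_coils, sub.n_spokes, sub.n_readout), 0, 2
        )

    if noise_sd > 0:
        baseline_rms = np.sqrt(np.mean(np.abs(samples[frame_idx == frame_idx[0]]) ** 2))
        sigma = noise_sd * baseline_rms
        rng = np.random.default_rng(seed)
        noise = rng.normal(scale=sigma / np.sqrt(2.0), size=samples.shape + (2,))
        samples = samples + noise[..., 0] + 1j * noise[..., 1]

    return MultiCoilKSpace(samples=samples, trajectory=trajectory, grid_size=n)


@dataclass(frozen=True)
class LesionRecord:
    """One synthetic lesion: histology, size (cm), nodal status, microvascular
    density (vessels / 0.723 mm^2) and the true Tofts parameters."""

    lesion_id: int
    histology: str
    size_cm: float
    nodal_positive: bool
    mvd: float
    ktrans_true: float
    ve_true: float

    def __post_init__(self):
        if self.histology not in HISTOLOGIES:
            raise ValueError(f"unknown histology {self.histology!r}")
        if self.mvd < 0:
            raise ValueError("mvd must be >= 0")
        if self.size_cm <= 0:
            raise ValueError("size_cm must be positive")


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    n_per_histology: dict | None = None,
    target_r: float = DEFAULT_TARGET_R,
    histology_params: dict | None = None,
    large_fraction: float = DEFAULT_LARGE_FRACTION,
    nodal_positive_prob: float = 0.48,
    seed: int = 0,
) -> list[LesionRecord]:
    """Draw a synthetic lesion cohort with a calibrated Ktrans-MVD correlation.

    True Ktrans and Ve are drawn per histology from truncated normals with the
    configured means/SDs.  MVD is then ``a + b * ktrans_true + eps`` with
    ``b`` and ``sd(eps)`` calibrated against the realised Ktrans spread so the
    population Pearson correlation equals ``target_r`` and the MVD mean/SD
    match the histology-mixture moments; negative draws are truncated at 0.
    Exactly ``round(large_fraction * n)`` lesions are assigned sizes > 3 cm.
    """
    if not (-1.0 < target_r < 1.0):
        raise ValueError("target_r must lie in (-1, 1)")
    n_per_histology = dict(n_per_histology or DEFAULT_N_PER_HISTOLOGY)
    params = histology_params or DEFAULT_HISTOLOGY_PARAMS
    if any(v < 0 for v in n_per_histology.values()):
        raise ValueError("histology counts must be >= 0")
    n_total = sum(n_per_histology.values())
    if n_total == 0:
        return []
    rng = np.random.default_rng(seed)

    histology = []
    ktrans = []
    ve = []
    for h in HISTOLOGIES:
        count = n_per_histology.get(h, 0)
        if count == 0:
            continue
        mk, sk = params[h]["ktrans"]
        mv, sv = params[h]["ve"]
        histology += [h] * count
        ktrans.append(_trunc_normal(rng, mk, sk, 0.02, 5.0, count))
        ve.append(_trunc_normal(rng, mv, sv, 0.02, 0.95, count))
    ktrans = np.concatenate(ktrans)
    ve = np.concatenate(ve)

    # mixture moments of MVD implied by the per-histology configuration
    weights = np.array([n_per_histology.get(h, 0) for h in HISTOLOGIES], dtype=float)
    weights /= weights.sum()
    mvd_means = np.array([params[h]["mvd"][0] for h in HISTOLOGIES])
    mvd_sds = np.array([params[h]["mvd"][1] for h in HISTOLOGIES])
    mu_m = float(weights @ mvd_means)
    var_m = float(weights @ (mvd_sds**2 + mvd_means**2) - mu_m**2)
    sd_m = np.sqrt(var_m)

    sd_k = ktrans.std(ddof=0)
    if sd_k == 0:
        if abs(target_r) > 0:
            raise ValueError(
                "cannot calibrate a nonzero correlation: ktrans has zero variance"
            )
        b = 0.0
    else:
        b = target_r * sd_m / sd_k
    sd_eps = sd_m * np.sqrt(1.0 - target_r**2)
    a = mu_m - b * ktrans.mean()
    mvd = np.clip(a + b * ktrans + rng.normal(scale=sd_eps, size=n_total), 0.0, None)

    n_large = int(round(large_fraction * n_total))
    large = np.zeros(n_total, dtype=bool)
    large[rng.permutation(n_total)[:n_large]] = True
    sizes = np.where(
        large,
        _trunc_normal(rng, 4.9, 0.9, 3.01, 12.0, n_total),
        _trunc_normal(rng, 2.4, 0.5, 0.8, 3.0, n_total),
    )
    nodal = rng.random(n_total) < nodal_positive_prob

    return [
        LesionRecord(
            lesion_id=i,
            histology=histology[i],
            size_cm=float(sizes[i]),
            nodal_positive=bool(nodal[i]),
            mvd=float(mvd[i]),
            ktrans_true=float(ktrans[i]),
            ve_true=float(ve[i]),
        )
        for i in range(n_total)
    ]
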