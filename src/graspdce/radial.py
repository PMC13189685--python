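"""Golden-angle radial sampling geometry and the non-uniform Fourier operators.

This module provides the building blocks of the radial acquisition model
``y = F C x``: the golden-angle trajectory (the sampling locations behind the
non-uniform Fourier operator ``F``), exact forward/adjoint evaluation of ``F``
on those locations, radial density compensation, and coil-sensitivity maps
(the ``C`` operator), both synthetic and estimated from data.

Conventions (asserted by round-trip tests):

* k-space coordinates are in cycles/FOV, each component in ``[-0.5, 0.5)``;
  readout sample ``i`` of a spoke sits at radius ``(i - n_readout/2) /
  n_readout`` so every spoke passes through k = 0.
* image pixel ``(p, q)`` carries spatial coordinate ``(p - N//2, q - N//2)``
  (centred Fourier convention), so the forward model is
  ``y_j = sum_{p,q} x[p,q] * exp(-2i*pi*(kx_j*(p-N//2) + ky_j*(q-N//2)))``.

The non-uniform transform is evaluated exactly by factoring the 2-D complex
exponential into two dense matrices (one per image axis).  At the grid sizes
this package targets (<= 256) that is both fast (two BLAS matmuls per
evaluation) and free of gridding/interpolation error, so the operator pair is
adjoint-consistent to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "GOLDEN_ANGLE_DEG",
    "GOLDEN_ANGLE_RAD",
    "RadialTrajectory",
    "CoilSensitivities",
    "MultiCoilKSpace",
    "golden_angle_trajectory",
    "NufftOperator",
    "nufft_forward",
    "nufft_adjoint",
    "radial_density_compensation",
    "synthetic_coil_maps",
    "estimate_coil_sensitivities",
]

#: Golden-angle increment, 180 deg * 2 / (1 + sqrt(5)) ~= 111.246 deg.
#: Consecutive spokes rotated by this angle give near-uniform angular
#: coverage for any contiguous window of spokes.
GOLDEN_ANGLE_DEG = 360.0 / (1.0 + np.sqrt(5.0))
GOLDEN_ANGLE_RAD = np.deg2rad(GOLDEN_ANGLE_DEG)


@dataclass(frozen=True)
class RadialTrajectory:
    """A set of radial spokes: angles, k-space coordinates and timing.

    ``k_coords`` has shape ``(n_spokes, n_readout, 2)`` holding ``(kx, ky)``
    in cycles/FOV; ``timestamps`` (seconds) mark the acquisition time of each
    spoke, ``n * tr_seconds * n_partitions`` for a stack-of-stars scan in
    which all partitions of a spoke angle are collected before the next
    rotation.
    """

    n_spokes: int
    n_readout: int
    angles: np.ndarray
    k_coords: np.ndarray
    timestamps: np.ndarray
    tr_seconds: float
    n_partitions: int = 1

    def subset(self, spoke_indices: np.ndarray) -> "RadialTrajectory":
        """Trajectory restricted to ``spoke_indices`` (keeps timing metadata)."""
        idx = np.asarray(spoke_indices)
        return RadialTrajectory(
            n_spokes=int(idx.size),
            n_readout=self.n_readout,
            angles=self.angles[idx],
            k_coords=self.k_coords[idx],
            timestamps=self.timestamps[idx],
            tr_seconds=self.tr_seconds,
            n_partitions=self.n_partitions,
        )

    @property
    def flat_coords(self) -> np.ndarray:
        """All sample coordinates flattened to ``(n_samples, 2)``."""
        return self.k_coords.reshape(-1, 2)


@dataclass(frozen=True)
class CoilSensitivities:
    """Complex per-coil sensitivity maps, shape ``(n_coils, N, N)``.

    Over the object support the maps are normalised so the root-sum-of-squares
    across coils equals 1; outside the support they are zero.
    """

    maps: np.ndarray

    def __post_init__(self):
        maps = np.asarray(self.maps, dtype=np.complex128)
        if maps.ndim != 3 or maps.shape[1] != maps.shape[2]:
            raise ValueError("coil maps must have shape (n_coils, N, N)")
        object.__setattr__(self, "maps", maps)

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_size(self) -> int:
        return self.maps.shape[1]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


@dataclass
class MultiCoilKSpace:
    """Measured radial k-space: ``samples`` indexed ``(spoke, readout, coil)``."""

    samples: np.ndarray
    trajectory: RadialTrajectory
    density_comp: np.ndarray = field(default=None)  # (n_spokes, n_readout)
    grid_size: int = None

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=np.complex128)
        t = self.trajectory
        if s.shape[:2] != (t.n_spokes, t.n_readout):
            raise ValueError(
                f"samples shape {s.shape} inconsistent with trajectory "
                f"({t.n_spokes} spokes x {t.n_readout} readout)"
            )
        self.samples = s
        if self.density_comp is None:
            self.density_comp = radial_density_compensation(t)
        if np.any(self.density_comp < 0):
            raise ValueError("density compensation weights must be >= 0")

    @property
    def n_coils(self) -> int:
        return self.samples.shape[2]


def golden_angle_trajectory(
    n_spokes: int,
    n_readout: int,
    tr_seconds: float = 3.40e-3,
    n_partitions: int = 1,
) -> RadialTrajectory:
    """Build a 2-D golden-angle radial trajectory.

    Spoke ``n`` lies at angle ``(n * 111.246 deg) mod 180 deg`` and is stamped
    with acquisition time ``n * tr_seconds * n_partitions`` (all partitions of
    one angle are encoded before the trajectory rotates).

    Parameters
    ----------
    n_spokes : number of spokes (>= 1).
    n_readout : samples per spoke; must be even so the centre sample sits
        exactly at k = 0.
    tr_seconds : repetition time per excitation (default 3.40 ms).
    n_partitions : partitions per spoke angle for stack-of-stars timing.
    """
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    if n_readout % 2 != 0 or n_readout < 2:
        raise ValueError("n_readout must be even and >= 2")
    n = np.arange(n_spokes)
    angles = np.mod(n * GOLDEN_ANGLE_RAD, np.pi)
    radii = (np.arange(n_readout) - n_readout // 2) / n_readout  # [-0.5, 0.5)
    kx = radii[None, :] * np.cos(angles)[:, None]
    ky = radii[None, :] * np.sin(angles)[:, None]
    k_coords = np.stack([kx, ky], axis=-1)
    timestamps = n * tr_seconds * n_partitions
    return RadialTrajectory(
        n_spokes=n_spokes,
        n_readout=n_readout,
        angles=angles,
        k_coords=k_coords,
        timestamps=timestamps,
        tr_seconds=tr_seconds,
        n_partitions=n_partitions,
    )


class NufftOperator:
    """Exact non-uniform DFT between an ``N x N`` grid and radial samples.

    Factors ``exp(-2i*pi*(kx*px + ky*py))`` into per-axis matrices ``Ex``
    (``n_samples x N``) and ``Ey`` so forward and adjoint evaluations are two
    dense matmuls each.  Exact (no gridding kernel), hence the pair satisfies
    ``<F x, y> = <x, F^H y>`` to machine precision.
    """

    def __init__(self, trajectory: RadialTrajectory, grid_size: int):
        coords = trajectory.flat_coords
        if np.any(np.abs(coords) > 0.5):
            raise ValueError("k-space coordinates must lie in [-0.5, 0.5]")
        self.trajectory = trajectory
        self.grid_size = int(grid_size)
        pos = np.arange(grid_size) - grid_size // 2
        self._ex = np.exp(-2j * np.pi * coords[:, 0:1] * pos[None, :])
        self._ey = np.exp(-2j * np.pi * coords[:, 1:2] * pos[None, :])
        self.n_samples = coords.shape[0]

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Evaluate the Fourier transform of ``image`` at the sample locations.

        ``image`` may be ``(N, N)`` or a batch ``(..., N, N)``; the result has
        shape ``(..., n_samples)``.
        """
        img = np.asarray(image, dtype=np.complex128)
        if img.shape[-2:] != (self.grid_size, self.grid_size):
            raise ValueError(
                f"image shape {img.shape[-2:]} does not match grid "
                f"{self.grid_size}"
            )
        # row transform: (..., N_p, M) then contract the p axis against Ex
        g = img @ self._ey.T
        return np.einsum("jp,...pj->...j", self._ex, g, optimize=True)

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`forward` (no density weighting applied)."""
        s = np.asarray(samples, dtype=np.complex128)
        if s.shape[-1] != self.n_samples:
            raise ValueError(
                f"got {s.shape[-1]} samples, trajectory has {self.n_samples}"
            )
        weighted = self._ex.conj().T * s[..., None, :]  # (..., N, M)
        return weighted @ self._ey.conj()


def nufft_forward(image: np.ndarray, trajectory: RadialTrajectory) -> np.ndarray:
    """Sample the Fourier transform of ``image`` along ``trajectory``.

    Returns complex samples shaped ``(n_spokes, n_readout)`` (leading batch
    axes of ``image`` are preserved).
    """
    n = image.shape[-1]
    op = NufftOperator(trajectory, n)
    out = op.forward(image)
    return out.reshape(image.shape[:-2] + (trajectory.n_spokes, trajectory.n_readout))

def nufft_adjoint(
    samples: np.ndarray,
    trajectory: RadialTrajectory,
    grid_size: int,
    density_comp: np.ndarray | None = None,
) -> np.ndarray:
    """Adjoint non-uniform transform; optionally density-compensated.

    Without ``density_comp`` this is the strict adjoint of
    :func:`nufft_forward`.  With ``density_comp`` (per-sample area weights,
    e.g. from :func:`radial_density_compensation`) it becomes the standard
    gridding *inverse*, approximately reconstructing the image from
    fully-sampled data — but it is then no longer the adjoint.
    """
    op = NufftOperator(trajectory, grid_size)
    s = np.asarray(samples, dtype=np.complex128)
    flat = s.reshape(s.shape[:-2] + (-1,))
    if density_comp is not None:
        flat = flat * np.asarray(density_comp).reshape(-1)
    return op.adjoint(flat)


def radial_density_compensation(trajectory: RadialTrajectory) -> np.ndarray:
    """Area (ramp) density weights for a radial trajectory.

    Each sample is weighted by the k-space area of its annular cell,
    ``|k| * dk * dtheta_s`` where ``dtheta_s`` is the angular cell of its
    spoke — half the gap to each angular neighbour (mod pi), which matters
    for golden-angle sets whose gaps are non-uniform.  The centre sample of
    every spoke shares the central disc in proportion to its angular cell.
    With these weights the density-compensated adjoint approximates the
    inverse transform of fully-sampled data with the correct absolute scale.
    """
    n_spokes = trajectory.n_spokes
    radii = np.abs(
        (np.arange(trajectory.n_readout) - trajectory.n_readout // 2)
        / trajectory.n_readout
    )
    dk = 1.0 / trajectory.n_readout
    if n_spokes == 1:
        dtheta = np.array([np.pi])
    else:
        order = np.argsort(trajectory.angles)
        sorted_angles = trajectory.angles[order]
        gaps = np.diff(np.concatenate([sorted_angles, [sorted_angles[0] + np.pi]]))
        cells = 0.5 * (gaps + np.roll(gaps, 1))
        dtheta = np.empty(n_spokes)
        dtheta[order] = cells
    w = radii[None, :] * dk * dtheta[:, None]
    w[:, trajectory.n_readout // 2] = dtheta * (dk / 2.0) ** 2
    return w


def synthetic_coil_maps(grid_size: int, n_coils: int) -> CoilSensitivities:
    """Smooth synthetic receive sensitivities for simulation.

    ``n_coils`` Gaussian-profile elements on a ring around the FOV, each with
    a mild linear phase; normalised so the root-sum-of-squares is exactly 1
    everywhere (the whole grid is treated as support).  A single coil yields a
    uniform unit map.
    """
    n = grid_size
    if n_coils == 1:
        return CoilSensitivities(np.ones((1, n, n), dtype=np.complex128))
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    c = (n - 1) / 2.0
    maps = np.empty((n_coils, n, n), dtype=np.complex128)
    ring = 0.55 * n
    sigma = 0.85 * n
    for i in range(n_coils):
        theta = 2.0 * np.pi * i / n_coils
        cy, cx = c + ring * np.sin(theta), c + ring * np.cos(theta)
        mag = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))
        phase = 2.0 * np.pi * 0.03 * ((xx - c) * np.cos(theta) + (yy - c) * np.sin(theta)) / n
        maps[i] = mag * np.exp(1j * (phase + theta / 3.0))
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    return CoilSensitivities(maps / rss)


def estimate_coil_sensitivities(
    kspace: MultiCoilKSpace,
    grid_size: int | None = None,
    smooth_sigma: float = 2.0,
    support_frac: float = 0.1,
) -> CoilSensitivities:
    """Estimate coil maps from the average image over all acquired spokes.

    Each coil's composite image is the density-compensated adjoint of all its
    spokes (time-averaged, hence artifact-free when the spoke count reaches
    angular Nyquist); dividing by the root-sum-of-squares composite and
    smoothing yields the maps, renormalised to unit RSS over the support
    (RSS above ``support_frac`` of its maximum) and zero outside.
    """
    if not np.any(kspace.samples):
        raise ValueError("cannot estimate sensitivities from all-zero data")
    n = grid_size if grid_size is not None else kspace.grid_size
    if n is None:
        n = kspace.trajectory.n_readout
    traj = kspace.trajectory
    nyquist = int(np.ceil(np.pi / 2.0 * n))
    if traj.n_spokes < nyquist:
        warnings.warn(
            f"{traj.n_spokes} spokes is below angular Nyquist ({nyquist}) for a "
            f"{n}x{n} grid; the composite image may contain streaks",
            stacklevel=2,
        )
    coil_imgs = nufft_adjoint(
        np.moveaxis(kspace.samples, 2, 0), traj, n, kspace.density_comp
    )
    rss = np.sqrt(np.sum(np.abs(coil_imgs) ** 2, axis=0))
    support = rss > support_frac * rss.max()
    raw = np.where(support, coil_imgs / np.where(rss > 0, rss, 1.0), 0.0)
    smoothed = np.empty_like(raw)
    for i in range(raw.shape[0]):
        smoothed[i] = gaussian_filter(raw[i].real, smooth_sigma) + 1j * gaussian_filter(
            raw[i].imag, smooth_sigma
        )
    out_rss = np.sqrt(np.sum(np.abs(smoothed) ** 2, axis=0))
    norm = np.where((out_rss > 0) & support, out_rss, 1.0)
    maps = np.where(support, smoothed / norm, 0.0)
    return CoilSensitivities(maps)
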