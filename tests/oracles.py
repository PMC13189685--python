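"""Independent brute-force oracles used by the test suite.

Every oracle here deliberately avoids the package's own computational path:
dense DFT matrices instead of the factored operator, Riemann sums instead of
the exponential recursion, explicit sum-of-squares instead of the ANOVA
routine, and CGLS on the normal equations instead of the nonlinear solver.
"""

from __future__ import annotations

import numpy as np


def dense_dft_matrix(coords: np.ndarray, grid_size: int) -> np.ndarray:
    """Row j = exp(-2i pi (kx_j px + ky_j py)) over the centred pixel grid."""
    pos = np.arange(grid_size) - grid_size // 2
    m = coords.shape[0]
    out = np.empty((m, grid_size * grid_size), dtype=complex)
    for j in range(m):
        kx, ky = coords[j]
        out[j] = np.exp(-2j * np.pi * (kx * pos[:, None] + ky * pos[None, :])).ravel()
    return out


def riemann_tofts(ktrans: float, ve: float, times: np.ndarray, cp: np.ndarray,
                  oversample: int = 400) -> np.ndarray:
    """Brute-force Tofts convolution on a fine grid (left Riemann sum of the
    linearly interpolated AIF), sampled back onto ``times``."""
    kep = ktrans / ve
    t_fine = np.linspace(times[0], times[-1], oversample * (len(times) - 1) + 1)
    cp_fine = np.interp(t_fine, times, cp)
    dt = t_fine[1] - t_fine[0]
    ct_fine = np.empty_like(t_fine)
    for i, t in enumerate(t_fine):
        tau = t_fine[: i + 1]
        ct_fine[i] = ktrans * np.trapezoid(
            cp_fine[: i + 1] * np.exp(-kep * (t - tau)), dx=dt
        )
    return np.interp(times, t_fine, ct_fine)


def brute_temporal_tv(frames: np.ndarray) -> float:
    """Element-by-element sum of |x[t+1] - x[t]| in explicit loops."""
    total = 0.0
    for t in range(frames.shape[0] - 1):
        for idx in np.ndindex(*frames.shape[1:]):
            total += abs(frames[t + 1][idx] - frames[t][idx])
    return total


def brute_anova(values: np.ndarray, labels: np.ndarray):
    """From-scratch one-way ANOVA sums of squares and pairwise LSD-t."""
    groups = list(dict.fromkeys(labels.tolist()))
    grand = values.mean()
    ss_total = float(np.sum((values - grand) ** 2))
    ss_between = 0.0
    ss_within = 0.0
    for g in groups:
        v = values[labels == g]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += float(np.sum((v - v.mean()) ** 2))
    df_b = len(groups) - 1
    df_w = len(values) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    msw = ss_within / df_w
    pairwise = {}
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            va, vb = values[labels == a], values[labels == b]
            t = (va.mean() - vb.mean()) / np.sqrt(msw * (1 / len(va) + 1 / len(vb)))
            pairwise[(a, b)] = t
    return {"ss_total": ss_total, "ss_between": ss_between, "ss_within": ss_within,
            "f": f, "pairwise": pairwise}


def cgls(forward, adjoint, y: np.ndarray, shape, n_iter: int = 200,
         tol: float = 1e-14) -> np.ndarray:
    """Conjugate gradient on the normal equations ``A^H A x = A^H y``."""
    x = np.zeros(shape, dtype=complex)
    r = y - forward(x)
    s = adjoint(r)
    p = s.copy()
    gamma = np.vdot(s, s).real
    gamma0 = gamma
    for _ in range(n_iter):
        q = forward(p)
        alpha = gamma / np.vdot(q, q).real
        x = x + alpha * p
        r = r - alpha * q
        s = adjoint(r)
        gamma_new = np.vdot(s, s).real
        if gamma_new < tol * gamma0:
            break
        p = s + (gamma_new / gamma) * p
        gamma = gamma_new
    return x
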