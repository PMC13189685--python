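# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `graspdce`, and what the synthetic experiments do and do
not demonstrate.

## Acquisition model

**Trajectory.** 2-D golden-angle radial sampling: spoke *n* lies at angle
(*n* × 111.246°) mod 180°, with 111.246° = 180°·2/(1+√5). Spoke timestamps
are *n* × TR × *n*_partitions, modelling a stack-of-stars acquisition that
encodes all partitions of one angle before rotating. At the clinical
constants (TR 3.40 ms, 24 partitions) the 34-spoke phase grouping gives
2.7744 s per contrast phase. The clinically reported total scan time for
3000 spokes × 24 partitions exceeds the bare TR product (281 s vs 244.8 s);
the difference is attributable to preparation/calibration segments, which
are not modelled — timestamps use the pure TR product.

Readout sampling uses 2× oversampling (`n_readout = 2N` for an *N*-grid, k
∈ [−0.5, 0.5) cycles/FOV in steps of 1/(2N)). This is standard for radial
MRI and is load-bearing here: with critical readout sampling the polar
quadrature behind the density-compensated adjoint fails for off-centre
objects (errors up to tens of percent), while 2× readout brings all tested
smooth objects below 5% NRMSE.

**Non-uniform Fourier operator.** The operator F is evaluated *exactly* by
factoring exp(−2πi(k_x p + k_y q)) into two dense per-axis matrices, so a
forward or adjoint application is two BLAS matrix multiplications
(O(N²·M)). At the grid sizes this package targets (≤ 256) this is faster to
apply than building a gridding interpolator, has zero kernel/apodization
error, and makes the (forward, adjoint) pair adjoint-consistent to machine
precision — the adjoint inner-product identity holds at ~1e−16. A
Kaiser–Bessel gridding NUFFT would only become preferable at much larger
matrices.

**Density compensation.** Ramp (area) weights: each sample is weighted by
its annular cell |k|·dk·dθ_s, with dθ_s the per-spoke angular cell computed
from the actual neighbour gaps mod π (golden-angle gaps are non-uniform —
by the three-distance theorem the gap ratio within any consecutive window
is at most φ² ≈ 2.618, exactly φ for Fibonacci spoke counts). The centre
sample of each spoke receives its share of the central disc. These weights
are used only for sensitivity estimation, solver initialisation and λ=0
gridding baselines; the iterative solver itself uses the strict
(unweighted) adjoint.

**Coil sensitivities.** Synthetic maps are Gaussian-profile elements on a
ring with mild linear phases, normalised to unit root-sum-of-squares (RSS).
Estimation from data follows the all-spokes composite-image approach:
density-compensated adjoint per coil over every acquired spoke
(time-averaging removes undersampling artifact when the spoke count reaches
angular Nyquist, ≈ πN/2), divided by the RSS composite, lightly smoothed
(Gaussian, σ = 2 px), renormalised to RSS = 1 over the support (RSS above
10% of maximum) and zero outside.

## Reconstruction

The dynamic series is the minimiser of ½‖FCx − y‖₂² + λ‖Tx‖₁ with T the
first-order temporal finite difference. Solver: Polak–Ribière+ nonlinear
conjugate gradient with Armijo backtracking on the smoothed objective
(|u| ≈ √(|u|² + μ²), μ = 1e−6 of the initial image maximum), restart on
non-descent directions. The logged cost is therefore monotone
non-increasing by construction, and this is asserted on every run.
Initialisation is the density-compensated, coil-combined adjoint per phase;
the solver is fully deterministic.

λ is specified relative to the maximum magnitude of that initialisation
(default 0.02). The original clinical processing does not publish λ or the
optimizer; both are package choices, with the λ=0 limit verified against a
conjugate-gradient least-squares oracle (< 1% NRMSE on fully sampled
phases) and the λ→∞ limit driving temporal variation to zero.

Spoke grouping truncates the trailing remainder (3000 spokes at 34/phase →
88 phases, 8 spokes discarded) so all phases share one duration, as the
temporal regulariser assumes. Partition re-gridding is linear interpolation
of slice centres over the same slab extent with linear extrapolation at the
edge half-cells (so linear profiles are reproduced exactly); 24 × 5 mm →
3 mm gives round(120/3) = 40 partitions.

## Pharmacokinetics

Signal is converted to concentration linearly: C = gain·(S − S₀), S₀ the
mean of the first `n_baseline_frames` frames (default 5). The gain is a
single arbitrary constant (default 1) applied identically in simulation and
analysis; only ratios of tissue to plasma concentration matter for the
Tofts parameters, which is what makes the linearity assumption workable
without a T1 map.

The Tofts convolution is computed by exponential-kernel recursion, exact
for a piecewise-linear AIF: over one interval of length Δ,
I(t+Δ) = e^(−k_ep Δ) I(t) + a·φ₁ + b·φ₂ with φ₁ = (1 − e^(−k_ep Δ))/k_ep,
φ₂ = (Δ − φ₁)/k_ep and (a, b) the AIF's value and slope at the interval
start; series expansions take over for k_ep Δ < 1e−8. This is stable at the
~3–10 s frame spacing of dynamic radial reconstructions, where a naive
Riemann sum is visibly biased. Agreement with an oversampled integration
oracle is ≤ 0.1% of peak.

Fitting is bounded trust-region least squares (K^trans ∈ [0, 5] min⁻¹,
V_e ∈ [0.001, 1]) from a 3×3 multi-start grid ({0.01, 0.1, 0.5} ×
{0.1, 0.3, 0.6}), keeping the lowest-residual solution; the convergence
flag comes from the optimizer, and pixelwise-map failures are stored as NaN
with an explicit failure mask, never as silent zeros. An identically-zero
curve short-circuits to K^trans = 0.

The reading workflow mirrors clinical practice: ROI-averaged curve per
slice → fit → mean of the two adjacent slices (session value) → mean of two
repeat sessions (final value). For single-partition 2-D series, the "two
consecutive slices" are represented by two independently jittered ROIs on
the same slice.

## Synthetic data: what it emulates, and what it does not

**AIF.** The in-vivo AIF is measured from a descending-aorta ROI and is not
published; the package uses a parametric population shape — gamma-variate
first-pass bolus (peak amplitude 6 a.u. at 15 s post-arrival, shape α=2.5)
plus a slow washout tail ((1−e^(−6t))·e^(−0.2t)) — arriving after the
baseline frames. It is smooth, differentiable and realistic in shape;
absolute concentration units are arbitrary under the linear-gain
convention.

**Phantom.** Uniform circular regions on a 64×64 grid (desk-scale stand-in
for 256×256 in-plane): one aortic disc carrying baseline + C_p(t), lesion
discs carrying baseline + C_t(t) via the *same* `tofts_forward` code path
used for fitting, a low-enhancement muscle region (K^trans 0.02 min⁻¹, V_e
0.10) as the stable healthy-tissue reference, and a non-enhancing
background at 20% baseline. Region edges are softened by a 0.8-px Gaussian
in the pipeline (pixel-sharp discs are unphysical; their Gibbs ringing
dominates reconstruction error and biases small-ROI readings). The exact
shared-code-path invariant (phantom curve ≡ Tofts forward output) holds
with smoothing disabled, which is the `PhantomSpec` default.

**Timing at desk scale.** The default pipeline uses 21 spokes/phase × 16
phases with a 10-s frame interval (the per-spoke TR is derived as
10/21 s), bolus arrival after 5 baseline frames. This preserves the
structure — baseline, first pass, partial washout over ~1.8 min — at a
computational cost of about a minute per reconstruction, at the price of
coarser temporal resolution than the clinical 2.77 s/phase and a shorter
total acquisition. The clinical constants are used verbatim in the timing
arithmetic and its tests.

**Noise.** Complex i.i.d. Gaussian noise is added in k-space with standard
deviation `noise_sd` × RMS of the noiseless baseline-frame samples
(default 0.02, a moderate clinical-SNR level). No physiological motion, B0
inhomogeneity, T1 saturation or gradient-delay effects are simulated —
passing tests demonstrate correctness of the computational chain, not
robustness to those confounds.

**Cohort.** True (K^trans, V_e) per lesion are truncated-normal draws with
per-histology means/SDs matching the reference cohort's group table
(15 adenocarcinoma / 8 squamous / 2 small-cell). MVD is an affine function
of the realised K^trans plus Gaussian noise, with slope and noise variance
calibrated against the realised K^trans spread and the mixture MVD moments
so the population correlation equals the target (default 0.738); negative
MVD draws truncate at zero. 19/25 lesions are assigned sizes > 3 cm
(truncated normal 4.9 ± 0.9 cm; the rest 2.4 ± 0.5 cm in (0.8, 3]); nodal
status is independent Bernoulli (p = 0.48) — the reference design reports
no nodal counts, and coupling nodal status to K^trans is deliberately not
modelled. Repeat-session variability is modelled purely as ROI re-placement
jitter (±1 px uniform integer shifts) on the same reconstruction, matching
a re-reading design; scanner test–retest variability is *not* included, so
the simulated repeatability correlations (~0.99) sit above clinically
reported re-reading values.

**AIF extraction in the pipeline** uses the aortic core (region radius
eroded by 2.4 px): reconstructed edge pixels are partial-volume diluted and
ring, and including them biases K^trans by several percent in either
direction. This mirrors the clinical practice of placing the aortic ROI
well inside the vessel.

## Verification summary

Every stage is tested against an independent oracle: dense DFT matrices for
the operator, adjoint inner-product identities, brute-force sums for the
temporal TV and ANOVA decompositions, CGLS on the normal equations for the
λ=0 solver limit, oversampled numerical integration and closed forms
(plateau AIF) for the Tofts model, hand-computed examples for the
statistics, and Monte-Carlo checks for the cohort calibration (mean
empirical r within ±0.05 of target over 200 replicates; significant
positive correlation in > 90% of replicates at n = 25). The end-to-end
check (frozen settings, fixed seed) recovers a uniform lesion's K^trans
within 5% — measured ≈ 0.1–1% across seeds — with series NRMSE ≈ 5.5%.
Problem sizes in tests (16–64 grids, 4–16 phases) were chosen as the
smallest at which each property is meaningfully exercised.

## Known limitations

- Pure 2-D golden-angle radial by default; stack-of-stars is supported
  structurally (timing, partition interpolation) but the solver loops 2-D
  problems rather than reconstructing 3-D jointly.
- No bolus-arrival-time term in the Tofts fit: a delay between aortic and
  lesion enhancement would bias K^trans; the phantom applies none.
- The linear signal–concentration assumption is inherited by design; no
  T1-map-based conversion, and no extended-Tofts plasma-volume term.
- Small-cell group statistics at n = 2 are fragile by construction; the
  generator accepts inflated group sizes for stability experiments.
- The exact-DFT operator scales as O(N²·M) per application and is not
  intended for 256+ grids on one CPU.
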