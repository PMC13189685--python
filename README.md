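# graspdce

Desk-scale simulation and analysis of free-breathing golden-angle radial
DCE-MRI for quantifying tumor perfusion and relating it to microvascular
density (MVD), the histological standard for tumor angiogenesis.

In lung cancer, angiogenesis is graded by counting CD34-stained microvessels
in the most vascularized ×200 field of a biopsy (vessels per 0.723 mm²) — an
invasive, spatially undersampled readout. Dynamic contrast-enhanced MRI
offers a noninvasive alternative: the volume transfer coefficient K^trans
measured from the contrast washin/washout kinetics of a lesion correlates
with MVD. This package re-creates that entire measurement chain *in silico*
so every stage can be verified against ground truth:

1. **Digital perfusion phantom** (`graspdce.phantom`) — circular lesion
   regions enhance according to the standard Tofts model under a parametric
   arterial input function (AIF); an aortic region carries the AIF itself.
   A synthetic 25-lesion cohort (15 adenocarcinoma / 8 squamous / 2
   small-cell) provides per-lesion K^trans, V_e, tumor size, nodal status
   and MVD, with the population K^trans–MVD correlation calibrated to a
   configurable target (default 0.738).
2. **Radial acquisition model** (`graspdce.radial`) — golden-angle
   (111.246° = 180°·2/(1+√5)) stack-of-stars trajectories with per-spoke
   timestamps, an exact non-uniform Fourier operator pair (F, Fᴴ), ramp
   density compensation, and coil-sensitivity maps (synthetic, or estimated
   from the all-spokes composite image).
3. **Compressed-sensing reconstruction** (`graspdce.recon`) — consecutive
   spokes are grouped into contrast phases (34 spokes × TR 3.40 ms × 24
   partitions ≈ 3 s/phase at clinical scale) and the dynamic series is
   reconstructed by solving

       x = argmin_x  ½‖F C x − y‖₂² + λ‖T x‖₁

   with T the first-order temporal finite-difference transform (temporal
   total variation), by nonlinear conjugate gradient with a monotone line
   search. Partition stacks can be re-gridded to a new slice thickness
   (24 × 5 mm → 40 × 3 mm).
4. **Pharmacokinetic analysis** (`graspdce.pk`) — linear
   signal-to-concentration conversion, aortic AIF extraction, bounded
   multi-start Tofts fitting

       C_t(t) = K^trans ∫₀ᵗ C_p(τ) e^{−(K^trans/V_e)(t−τ)} dτ,

   the two-slice / two-session ROI averaging workflow (K^trans_1, K^trans_2
   → K^trans_Final), and pixelwise parameter maps with histograms.
5. **Cohort statistics** (`graspdce.stats`) — Pearson correlations with
   Fisher-z intervals (K^trans vs MVD, V_e vs MVD, session repeatability)
   and one-way ANOVA with LSD-t pairwise comparisons across histology,
   size (>3 vs ≤3 cm) and nodal-status groups.

A single command (`graspdce all`) runs the whole chain deterministically
from one seed.

## Worked example

```bash
graspdce all --seed 1 --out run1
```

simulates the 25-lesion cohort phantom (64×64, 8 coils, 21 spokes/phase ×
16 phases), reconstructs it, reads every lesion twice with jittered ROIs,
and prints the cohort report. Key lines from the run above:

```
Correlations:
  ktrans_vs_mvd: r = 0.722 (95% CI 0.457..0.869), P = 4.604e-05, n = 25
  ve_vs_mvd: r = -0.053 (95% CI -0.439..0.349), P = 0.8004, n = 25
  repeatability_ktrans: r = 0.998 (95% CI 0.994..0.999), P = 4.513e-28, n = 25
  repeatability_ve: r = 0.995 (95% CI 0.989..0.998), P = 1.322e-24, n = 25

By histology:
  ktrans: F(2,22) = 1.131, P = 0.3409
    adenocarcinoma: 0.400 +/- 0.245 (n = 15)
    squamous: 0.304 +/- 0.211 (n = 8)
    small_cell: 0.170 +/- 0.042 (n = 2)
```

Reading: the fitted K^trans_Final values recover a strong, significant
positive correlation with the generator's MVD (r = 0.72 here; the
generator's population target is 0.738), V_e shows no significant MVD
correlation, repeat readings of the same reconstruction are nearly
identical (r ≈ 0.99), and the small small-cell group has visibly lower
K^trans without reaching significance at n = 25 — the expected behaviour of
this study design at this sample size.

The run directory contains the simulated k-space (`kspace.h5`), the
reconstructed 4-D series (`dynamic.nii` + JSON sidecar with the cost log),
truth maps, the cohort table (`cohort.csv` with `ktrans_s1 … ve_final`
columns appended), and the machine-readable report (`stats.json`). The
stages are also available individually (`graspdce simulate / recon / fit /
stats`) with the flags documented in `--help`.

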