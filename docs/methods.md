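# Methods

This note records the model, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Pipeline model

A voxel's Z-spectrum is the saturated signal divided by the unsaturated
reference image: Z(Δω) = S_sat(Δω)/S0.  The acquisition convention is
two leading far off-resonance images at −300 ppm — the first discarded
because longitudinal magnetization has not reached steady state, the
second retained as S0 — followed by one volume per saturation offset.
The default offset schedule samples ±100 ppm; ±50→±20 in 10 ppm steps;
±10→±5 and ±4→±1 in 0.5 ppm steps; ±0.5→0 in 0.25 ppm steps (51
offsets).  The half-ppm sampling between 5 and 10 ppm guarantees the MT
fit points at ±9.5 and ±8.5 ppm exist; the schedule is fully
configurable and serialized as a JSON sidecar.

The background model is one seven-parameter function — water direct
saturation (DS) and semi-solid MT, each a Lorentzian parameterized by
amplitude A, FWHM L (ppm) and center δ (ppm), plus a constant baseline
b — fitted jointly to the union of the DS subset (±1, ±0.5, ±0.25, 0)
and the MT subset (±100, ±50, ±40, ±30, ±20, ±10, ±9.5, ±9, ±8.5 ppm).
A joint fit is used because the model is a single function; the subsets
merely decide which data constrain it.  The CEST metrics are

* LD = Z_ref − Z, evaluated after B0 correction, and
* MTR_REX = 1/Z − 1/Z_ref, computed from the *window-averaged* corrected
  Z and Z_ref (windowing the spectra first, then applying the
  reciprocal, keeps both metrics consistent with the same corrected
  spectra; the alternative order differs only at second order in the
  effect size).

B0 correction: the per-voxel shift is the argmin of the fitted
background on [−2, 2] ppm searched at 0.001 ppm; measured offsets are
translated by −shift; Z and LD are linearly interpolated onto the fixed
−100..100 ppm grid at 0.1 ppm (clamped at the ends, which only ever
affects the far MT points); any named offset is then read out as the
mean over a closed ±0.2 ppm window — exactly 5 grid points.

## Tunable parameters

| parameter | default | why |
|---|---|---|
| fit initialization | A_w 0.8, L_w 1.5, δ_w 0, A_mt 0.1, L_mt 40, δ_mt 0, b 0 | generic 3 T brain values; converges from here across the full plausible range (verified over seeded draws) |
| fit bounds | A ∈ [0,1]; L_w ∈ [0.3,10], L_mt ∈ [10,300] ppm; δ_w ∈ ±1, δ_mt ∈ ±4 ppm; b ∈ ±0.2 | wide, physically motivated; δ_mt left free (slightly asymmetric MT is real and the data constrain it) |
| solver | TRF least squares, ftol = xtol = gtol = 10⁻¹⁰, ≤ 2000 evaluations | at 10⁻⁸ the noiseless round-trip residual only marginally clears the 10⁻⁶ target; 10⁻¹⁰ costs nothing (≈2.5 ms/voxel) |
| reciprocal guard ε | 10⁻³ | Z below ε is treated as missing, not clipped, so ROI statistics are never biased by fabricated reciprocals |
| filter window | 3×3 | conventional default of the local-statistics (Wiener-style) filter; applied per axial slice, per offset, to the normalized Z-volume |
| window half-width | 0.2 ppm | fixed by the read-out definition (5 points at 0.1 ppm) |
| std convention | sample (n−1) | used uniformly in CNR, thresholds and reports |

The adaptive filter estimates local mean and variance over the window
with reflective boundaries and shrinks each pixel toward the local mean
by max(σ²−ν, 0)/σ², with noise power ν the slice mean of local
variances.  Reflective boundaries (rather than zero padding) make a
constant image a fixed point, which is the correct no-noise limit.

## The synthetic phantom

The phantom emulates: piecewise-constant tissue classes (WM background,
GM rim, spherical tumor with contralateral NAWM/NAGM references); four
Lorentzian pools per tissue (water, MT, amide at +3.5 ppm, aliphatic
NOE at −3.5 ppm); saturation-power conditions as per-pool amplitude
multipliers ("1.5uT" reference, "0.5uT" scaled down, the NOE pool least
affected — CEST labeling, DS and MT all weaken at low power while the
slowly relaying NOE retains relatively more amplitude); a linear B0 ramp
of ±0.3 ppm across the first axis; additive Gaussian noise on the
normalized signal (σ = 0.005 by default — high-SNR magnitude data are
approximately Gaussian, and the analysis runs post-normalization); and a
tissue-dependent S0 intensity with the same noise model, including the
discarded non-equilibrium normalization image.

Default pool amplitudes (reference condition): water 0.78/0.84/0.80,
MT 0.14/0.10/0.10, amide 0.020/0.022/0.030, NOE 0.012/0.009/0.006 for
WM/GM/tumor.  The tumor is amide-hyperintense and NOE/MT-hypointense,
the pattern relevant for non-enhancing glioma, where only moderate APT
elevation is expected.  Amide width defaults to 1.75 ppm: at a 1.5 µT
RMS saturation amplitude the power broadening at 3 T (γB₁ ≈ 0.5 ppm)
puts fitted amide line widths in the 1.5–3 ppm range, and a width below
~1.5 ppm would also be under-sampled by the 0.5 ppm offset spacing near
+3.5 ppm — the windowed read-out of a sub-Nyquist peak varies by up to
~9% with the alignment between peak and sampling comb, an artefact of
the schedule rather than of any pipeline stage.  NOE width is 3.0 ppm.

What the phantom deliberately does **not** model: Bloch-McConnell
exchange dynamics (B1 conditions are phenomenological multipliers),
partial-volume voxels, anatomy, Rician noise floors, motion, or scanner
drift.  Passing tests therefore demonstrate the *estimator chain* is
correct and self-consistent — not that the defaults predict in vivo
effect sizes.

## Numerical choices and degenerate inputs

* Linear interpolation for the fine-grid resampling: monotone, no
  ringing across the sparse far-MT gaps; cubic alternatives measurably
  help nothing once the sampling is adequate.
* Voxels whose fit fails or whose subset data are non-finite get
  sentinel results (NaN parameters, converged = False) and are excluded
  from maps and statistics but still counted in VP denominators.
* A vanishing pool amplitude leaves its width/center unidentifiable;
  the covariance is computed via the pseudo-inverse, so such fits report
  huge standard errors instead of crashing.
* Zero pooled standard deviation makes CNR undefined — reported as NaN,
  never ±inf.  A zero NAWM std collapses both heterogeneity thresholds
  onto the mean (degenerate but well defined under the strict
  inequalities).
* VP thresholds use strict inequalities; values exactly at a threshold
  belong to neither class.
* Pipeline artifacts are uncompressed NIfTI-1 and JSON manifests with
  sha256 checksums; identical configuration and seed reproduce every
  byte.

## Known limitations

The two-pool background fit absorbs a small fraction of the CEST pools
through their tails at the background offsets (the NOE tail at ±1 ppm
in particular).  On the default phantom this biases LD/MTR_REX a few
percent low and the fitted MT amplitude up to ~1% high — an intrinsic
property of Lorentzian-difference analysis with a fixed background
subset, not a solver artefact.  The same mechanism makes the *combined*
fit-plus-correction B0 round trip amplitude-dependent: with the
background known, the correction chain itself (shift estimate,
resampling, windowing) returns to the unshifted reference within ~1.7%
for |β| ≤ 0.5 ppm, while re-running the background fit per β modulates
the absorbed fraction and raises the worst-case deviation to ~4%
(both numbers are recomputed by `scripts/acceptance.py` as
`b0_correction_max_err_pct` and `b0_fullchain_max_err_pct`).
Problem sizes used in the validation — a 32×32×8 voxel phantom, 100
identifiability draws, 10⁵ metric-equation samples, 21-point β sweeps —
keep the full suite and the acceptance script within a few minutes on a
single CPU while leaving every estimate's sampling error far below the
tolerances tested.
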