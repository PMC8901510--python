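# cestquant

Quantification of chemical exchange saturation transfer (CEST) MRI
Z-spectra at clinical field strength, aimed at mapping amide proton
transfer (APT, +3.5 ppm) and aliphatic nuclear Overhauser enhancement
(NOE, −3.5 ppm) effects in brain tissue — in particular the heterogeneity
of these effects across a glioma.

## The problem and the method

A CEST acquisition saturates at a series of frequency offsets Δω (ppm
relative to water) and records the normalized water signal, the
Z-spectrum:

    Z(Δω) = S_sat(Δω) / S0

At 3 T the APT and NOE resonances sit on a background of water direct
saturation (DS) and broad semi-solid magnetization transfer (MT).  The
package isolates the CEST effects by fitting, per voxel, a two-pool
Lorentzian background model on offsets where only the background
contributes:

    Z_ref(Δω) = 1 − A_w L_w²/4 / (L_w²/4 + (Δω − δ_w)²)
                  − A_mt L_mt²/4 / (L_mt²/4 + (Δω − δ_mt)²) + b

using ±1, ±0.5, ±0.25, 0 ppm for the DS dip and ±100, ±50, ±40, ±30,
±20, ±10, ±9.5, ±9, ±8.5 ppm for MT.  The fitted dip minimum provides a
per-voxel B0 correction: spectra are shifted by the argmin of Z_ref,
linearly resampled onto a −100..100 ppm grid at 0.1 ppm resolution and
averaged over ±0.2 ppm windows.  Two metrics are then evaluated at
±3.5 ppm:

    LD      = Z_ref − Z          (Lorentzian difference)
    MTR_REX = 1/Z − 1/Z_ref      (spillover-compensated inverse MTR)

together with the fitted MT amplitude map.  ROI statistics compare tumor
against contralateral normal-appearing white/grey matter (NAWM/NAGM):
tissue contrast TC (difference of ROI means), contrast-to-noise ratio
CNR = TC / √(σ²_tumor + σ²_ref), and — per patient and metric —
thresholds mean_NAWM ± 2·std_NAWM defining the percentages of tumor
voxels that are hyper- or hypointense (VP_hyper / VP_hypo).

Because no patient data accompany the method, the package ships a fully
synthetic multi-pool phantom (`cestquant.phantom`) with known ground
truth: tissue geometry (WM, GM rim, spherical tumor), four Lorentzian
pools per tissue, per-condition saturation-power scaling, a smooth B0
field and additive Gaussian noise.  Every stage is validated against
that truth.

## Worked example

```python
import numpy as np
import cestquant as cq

# 1. a synthetic phantom with known ground truth (noiseless, default B0 ramp)
schedule = cq.build_default_schedule()
cfg = cq.PhantomConfig(grid_shape=(16, 16, 4), tumor_center=(4, 8, 2),
                       tumor_radius=3, gm_rim_voxels=2, noise_sigma=0.0)
raw, rois, truth = cq.generate_phantom(cfg, schedule)

# 2. normalize to Z-spectra and fit the two-pool background in one voxel
zvol = cq.normalize(raw, np.ones(cfg.grid_shape, bool))
result = cq.fit_two_pool(schedule.offsets, zvol.z[12, 8, 2])
print(result.summary())

# 3. voxel-wise fit, B0 correction, metric maps, ROI report
fits = cq.fit_volume(zvol)
corrected = cq.correct_volume(zvol, fits)
maps = cq.extract_metric_maps(corrected, fits, b1_label="1.5uT")
report = cq.build_report(maps, rois)
cols = ["metric", "mean_tumor", "mean_nawm", "tc_tumor_nawm", "vp_hyper", "vp_hypo"]
print(report[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
```

prints

```
Two-pool Lorentzian background fit
======================================================
offsets used:  25   converged: True   nfev: 8
residual rms:  2.970e-04
------------------------------------------------------
   param     estimate      std err
 a_water      0.78129      0.00034
 l_water      1.40589      0.00111
 d_water      0.17982      0.00026
    a_mt      0.14112      0.00026
    l_mt     44.50286      0.21964
    d_mt      0.15523      0.02807
       b     -0.00023      0.00026
======================================================
      metric  mean_tumor  mean_nawm  tc_tumor_nawm  vp_hyper  vp_hypo
      LD_APT      0.0268     0.0177         0.0090  100.0000   0.0000
      LD_NOE      0.0050     0.0104        -0.0054    0.0000 100.0000
  MTRREX_APT      0.0377     0.0262         0.0115  100.0000   0.0000
  MTRREX_NOE      0.0068     0.0153        -0.0084    0.0000 100.0000
MT_AMPLITUDE      0.1009     0.1411        -0.0402    0.0000 100.0000
```

The voxel sits in white matter on the B0 ramp: the fit recovers the WM
truth (A_w = 0.78, L_w = 1.4 ppm, A_mt = 0.141 vs 0.14) and localizes
the water dip at +0.18 ppm — the local field offset.  In the report the
tumor is APT-hyperintense (positive TC ≈ +0.9% in LD) and NOE- and
MT-hypointense, as constructed; with a noiseless phantom every tumor
voxel clears the NAWM-derived thresholds, so VP is 100% rather than the
partial percentages a noisy acquisition yields.

The same pipeline runs from the shell on NIfTI volumes or the built-in
phantom:

```bash
cestquant run-all --out out/ --seed 1 --grid 16,16,4
cestquant simulate --out phantom/ --seed 1      # phantom + truth as NIfTI
```

Each stage is also a subcommand (`normalize`, `fit`, `b0correct`,
`maps`, `roistats`) whose outputs chain into the next and reproduce the
one-shot report exactly; `run-all --config run.yaml` reads the whole
configuration from a YAML file, and `--metrics LD_APT,LD_NOE` restricts
which maps are produced.

`run-all` writes the Z-volume, seven fitted-parameter maps, the B0-shift
map, the five metric maps, a per-ROI CSV report and a `manifest.json`
with sha256 checksums of every artifact; identical configuration and
seed reproduce the manifest byte for byte.

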