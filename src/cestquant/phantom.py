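"""Synthetic multi-pool CEST phantom with known ground truth.

The phantom emulates a brain slab: white-matter background, a grey-matter
rim, and a spherical tumor in one hemisphere, with contralateral NAWM and
NAGM reference regions in the other.  Each tissue carries four Lorentzian
pools — water direct saturation, broad semi-solid MT, an amide (APT) pool
at +3.5 ppm and an aliphatic NOE pool at -3.5 ppm — and the noiseless
Z-spectrum of a voxel is

    Z(dw) = 1 - sum_pools A * (L^2/4) / (L^2/4 + (dw - d - beta))^2)

where ``beta`` is a smooth per-voxel B0 offset field.  Saturation-power
conditions are modelled phenomenologically as per-pool amplitude
multipliers.  Raw scanner-unit volumes are produced by multiplying the
(noisy) Z-values with a tissue-dependent S0 intensity, plus the two
leading far off-resonance normalization acquisitions the real protocol
acquires.

All pool values are synthetic defaults chosen to be plausible at 3 T —
they are design parameters of the phantom, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import OffsetSchedule, build_default_schedule
from .lorentzian import LorentzianPool, lorentzian_value
from .preprocess import RawCestSeries
from .roi import RoiSet

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "default_tissue_table",
    "default_b1_multipliers",
    "generate_phantom",
    "oracle_windowed_ld",
]

TISSUES = ("WM", "GM", "TUMOR")
POOLS = ("water", "mt", "apt", "noe")

# Pool table for the reference "1.5 uT" condition.  Tumor shows elevated
# amide amplitude and depressed NOE and MT relative to WM; the GM rim has
# shallower MT.  Widths: water ~1.4-1.7 ppm, MT tens of ppm, APT 1.75 ppm
# (saturation-broadened at 3 T), NOE 3.0 ppm.
_BASE_TABLE: dict[str, dict[str, LorentzianPool]] = {
    "WM": {
        "water": LorentzianPool(0.78, 1.4, 0.0),
        "mt": LorentzianPool(0.14, 45.0, 0.0),
        "apt": LorentzianPool(0.020, 1.75, 3.5),
        "noe": LorentzianPool(0.012, 3.0, -3.5),
    },
    "GM": {
        "water": LorentzianPool(0.84, 1.6, 0.0),
        "mt": LorentzianPool(0.10, 45.0, 0.0),
        "apt": LorentzianPool(0.022, 1.75, 3.5),
        "noe": LorentzianPool(0.009, 3.0, -3.5),
    },
    "TUMOR": {
        "water": LorentzianPool(0.80, 1.7, 0.0),
        "mt": LorentzianPool(0.10, 45.0, 0.0),
        "apt": LorentzianPool(0.030, 1.75, 3.5),
        "noe": LorentzianPool(0.006, 3.0, -3.5),
    },
}

#: S0 intensity per tissue, arbitrary scanner units
_S0_INTENSITY = {"WM": 1000.0, "GM": 1100.0, "TUMOR": 1050.0}


def _canon_label(label: str) -> str:
    return label.replace(" ", "").replace("µ", "u").replace("μ", "u")


def default_b1_multipliers() -> dict[str, dict[str, float]]:
    """Per-pool amplitude multipliers for the two saturation-power conditions.

    At the lower power, labeling efficiency drops for the exchange-driven
    amide pool and for direct saturation and MT, while the slowly relaying
    NOE pool retains relatively more of its amplitude.
    """
    return {
        "1.5uT": {"water": 1.0, "mt": 1.0, "apt": 1.0, "noe": 1.0},
        "0.5uT": {"water": 0.60, "mt": 0.50, "apt": 0.45, "noe": 0.80},
    }


def default_tissue_table(b1_label: str = "1.5uT") -> dict[str, dict[str, LorentzianPool]]:
    """Per-tissue pool table under the named saturation-power condition.

    Under "1.5 uT" the tumor amide amplitude exceeds WM and the tumor NOE
    amplitude is below WM, so LD APT contrast is positive and NOE contrast
    negative by construction.  Raises for an unknown condition label.
    """
    mults = default_b1_multipliers()
    key = _canon_label(b1_label)
    if key not in mults:
        raise ValueError(f"unknown B1 condition {b1_label!r}; known: {sorted(mults)}")
    m = mults[key]
    table = {
        tissue: {
            pool: LorentzianPool(p.amplitude * m[pool], p.width, p.center)
            for pool, p in pools.items()
        }
        for tissue, pools in _BASE_TABLE.items()
    }
    _validate_table(table)
    return table


def _validate_table(table) -> None:
    for tissue, pools in table.items():
        total = sum(p.amplitude for p in pools.values())
        if total >= 1.0:
            raise ValueError(
                f"pool amplitudes of {tissue} sum to {total:.3f} >= 1; "
                "Z would go non-positive"
            )


@dataclass
class PhantomConfig:
    """Geometry, tissue model, field and noise of the synthetic phantom."""

    grid_shape: tuple = (32, 32, 8)
    tumor_center: tuple = (9.0, 16.0, 4.0)
    tumor_radius: float = 5.0
    gm_rim_voxels: int = 3
    b1_label: str = "1.5uT"
    tissue_table: dict | None = None  # default: default_tissue_table(b1_label)
    b0_ramp_ppm: float = 0.3          # linear ramp -r..+r along the first axis
    noise_sigma: float = 0.005        # additive Gaussian std on normalized signal
    seed: int = 0

    def table(self) -> dict[str, dict[str, LorentzianPool]]:
        if self.tissue_table is not None:
            _validate_table(self.tissue_table)
            return self.tissue_table
        return default_tissue_table(self.b1_label)


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    label_map: np.ndarray          # 0 = WM, 1 = GM, 2 = tumor
    pool_amplitudes: dict          # pool name -> 3-D true amplitude map
    b0_shift_map: np.ndarray       # ppm
    z_noiseless: np.ndarray        # (x, y, z, n_offsets), schedule order
    s0_true: np.ndarray
    tissue_table: dict

    def tissue_mask(self, tissue: str) -> np.ndarray:
        return self.label_map == TISSUES.index(tissue)


def _build_geometry(cfg: PhantomConfig):
    nx, ny, nz = cfg.grid_shape
    label = np.zeros(cfg.grid_shape, dtype=np.int8)  # WM background
    rim = cfg.gm_rim_voxels
    if rim > 0:
        edge = np.zeros(cfg.grid_shape, dtype=bool)
        edge[:rim, :, :] = True
        edge[-rim:, :, :] = True
        edge[:, :rim, :] = True
        edge[:, -rim:, :] = True
        label[edge] = 1
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = cfg.tumor_center
    sphere = (ii - cx) ** 2 + (jj - cy) ** 2 + (kk - cz) ** 2 <= cfg.tumor_radius ** 2
    label[sphere] = 2
    # contralateral hemisphere (opposite half along the first axis)
    contra = ii >= nx // 2 if cx < nx / 2 else ii < nx // 2
    rois = RoiSet(
        tumor=sphere,
        nawm=(label == 0) & contra,
        nagm=(label == 1) & contra,
    )
    return label, rois


def _b0_field(cfg: PhantomConfig) -> np.ndarray:
    nx = cfg.grid_shape[0]
    ramp = np.linspace(-cfg.b0_ramp_ppm, cfg.b0_ramp_ppm, nx)
    return np.broadcast_to(ramp[:, None, None], cfg.grid_shape).copy()


def generate_phantom(cfg: PhantomConfig | None = None,
                     schedule: OffsetSchedule | None = None):
    """Generate a raw CEST series, its ROI set and the ground truth.

    Returns ``(raw, rois, truth)``.  The raw series contains the
    saturated volumes (schedule order) and the retained S0 image; the
    generator also simulates the discarded not-yet-equilibrated leading
    normalization image internally, exactly as the acquisition would.
    Identical config and seed give bit-identical output.
    """
    cfg = cfg or PhantomConfig()
    schedule = schedule or build_default_schedule()
    table = cfg.table()
    label, rois = _build_geometry(cfg)
    beta = _b0_field(cfg)
    rng = np.random.default_rng(cfg.seed)

    shape = cfg.grid_shape
    offs = schedule.offsets
    z_true = np.empty(shape + (len(offs),))
    amp_maps = {pool: np.zeros(shape) for pool in POOLS}
    s0_true = np.zeros(shape)
    for t_idx, tissue in enumerate(TISSUES):
        sel = label == t_idx
        if not sel.any():
            continue
        pools = table[tissue]
        for pool in POOLS:
            amp_maps[pool][sel] = pools[pool].amplitude
        s0_true[sel] = _S0_INTENSITY[tissue]
        # evaluate the pool sum on (offset - beta) for the selected voxels
        dw = offs[None, :] - beta[sel][:, None]
        z = np.ones_like(dw)
        for pool in POOLS:
            z -= lorentzian_value(pools[pool], dw)
        z_true[sel] = z

    z_noisy = z_true + rng.normal(0.0, cfg.noise_sigma, z_true.shape) \
        if cfg.noise_sigma > 0 else z_true.copy()
    volumes = z_noisy * s0_true[..., None]

    # normalization images at the far off-resonance frequency: the first
    # has not reached steady state (overshoots), the second is S0
    def _norm_image(scale):
        img = scale * s0_true
        if cfg.noise_sigma > 0:
            img = img * (1.0 + rng.normal(0.0, cfg.noise_sigma, shape))
        return img

    _dummy = _norm_image(1.05)  # discarded by convention; generated for realism
    s0 = _norm_image(1.0)

    raw = RawCestSeries(volumes=volumes, schedule=schedule, s0_volume=s0)
    truth = PhantomTruth(label_map=label, pool_amplitudes=amp_maps,
                         b0_shift_map=beta, z_noiseless=z_true,
                         s0_true=s0_true, tissue_table=table)
    return raw, rois, truth


def oracle_windowed_ld(pools: dict[str, LorentzianPool], schedule: OffsetSchedule,
                       center_ppm: float, half_width: float = 0.2,
                       grid: np.ndarray | None = None) -> float:
    """Brute-force expected windowed LD at ``center_ppm`` for one tissue.

    Evaluates the generator model at the schedule offsets, forms the
    exact LD (true background minus full spectrum, i.e. the CEST pools
    alone, sampled like the data), resamples it onto the fine grid with
    the same linear interpolation the pipeline uses, and averages the
    +-``half_width`` window.  Serves as an independent oracle for the
    pipeline's LD maps on a phantom without noise or B0 offsets.
    """
    from .b0 import make_fine_grid, window_slice

    if grid is None:
        grid = make_fine_grid()
    offs = np.sort(schedule.offsets)
    ld_samples = lorentzian_value(pools["apt"], offs) + lorentzian_value(pools["noe"], offs)
    ld_fine = np.interp(grid, offs, ld_samples)
    return float(ld_fine[window_slice(grid, center_ppm, half_width)].mean())
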