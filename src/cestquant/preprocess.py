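"""Normalization of raw saturated volumes and adaptive noise filtering.

The raw acquisition yields one 3-D volume per saturation offset in
arbitrary scanner units.  Dividing each by the unsaturated reference
image ``S0`` produces the dimensionless Z-spectrum volume

    Z(dw) = S_sat(dw) / S0

Noise is then suppressed with a locally adaptive (Wiener-style) 2-D
filter applied per axial slice and per offset: pixels in flat regions
are pulled toward the local mean, pixels in structured regions are left
nearly untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .acquisition import OffsetSchedule

__all__ = [
    "RawCestSeries",
    "ZSpectrumVolume",
    "normalize",
    "adaptive_filter_2d",
    "filter_series",
]


@dataclass
class RawCestSeries:
    """Raw saturated volumes plus the retained normalization image.

    ``volumes`` has shape (x, y, z, n_offsets) with the offset axis in
    the schedule's acquisition order; leading normalization dummies have
    already been discarded.
    """

    volumes: np.ndarray
    schedule: OffsetSchedule
    s0_volume: np.ndarray

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.s0_volume = np.asarray(self.s0_volume, dtype=float)
        if self.volumes.ndim != 4:
            raise ValueError(f"volumes must be 4-D, got shape {self.volumes.shape}")
        if self.s0_volume.shape != self.volumes.shape[:3]:
            raise ValueError(
                f"s0 shape {self.s0_volume.shape} does not match spatial shape "
                f"{self.volumes.shape[:3]}"
            )
        if self.volumes.shape[3] != len(self.schedule):
            raise ValueError(
                f"{self.volumes.shape[3]} volumes but schedule has "
                f"{len(self.schedule)} offsets"
            )

    @classmethod
    def from_acquisition(cls, all_volumes: np.ndarray, schedule: OffsetSchedule) -> "RawCestSeries":
        """Split a full acquisition into dummies, S0 and saturated volumes.

        ``all_volumes`` holds the acquisition in order: ``n_discard_leading``
        dummy normalization images, the retained S0 image, then one volume
        per schedule offset.
        """
        all_volumes = np.asarray(all_volumes, dtype=float)
        if all_volumes.shape[3] != schedule.n_acquisitions:
            raise ValueError(
                f"expected {schedule.n_acquisitions} acquired volumes, "
                f"got {all_volumes.shape[3]}"
            )
        k = schedule.n_discard_leading
        return cls(
            volumes=all_volumes[..., k + 1 :],
            schedule=schedule,
            s0_volume=all_volumes[..., k],
        )


@dataclass
class ZSpectrumVolume:
    """Normalized, dimensionless Z-spectrum data on a voxel grid.

    ``z`` has shape (x, y, z, n_offsets); voxels outside ``mask`` are NaN.
    """

    z: np.ndarray
    schedule: OffsetSchedule
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.z.ndim != 4:
            raise ValueError("z must be 4-D")
        if self.mask.shape != self.z.shape[:3]:
            raise ValueError("mask shape does not match spatial shape")
        if self.z.shape[3] != len(self.schedule):
            raise ValueError("offset axis length does not match schedule")

    @property
    def spatial_shape(self) -> tuple:
        return self.z.shape[:3]

    def sorted_spectra(self) -> tuple[np.ndarray, np.ndarray]:
        """(offsets ascending, z reordered to match) — a convenience view."""
        idx = self.schedule.sort_index
        return self.schedule.offsets[idx], self.z[..., idx]


def normalize(raw: RawCestSeries, mask: np.ndarray) -> ZSpectrumVolume:
    """Divide every saturated volume by the S0 image inside the mask.

    Voxels outside the mask are set to NaN.  Raises if any masked voxel
    has a non-positive S0 value (those voxels cannot be normalized and
    the mask should exclude them).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != raw.s0_volume.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume shape {raw.s0_volume.shape}"
        )
    bad = mask & ~(raw.s0_volume > 0)
    if np.any(bad):
        raise ValueError(
            f"S0 is non-positive in {int(bad.sum())} masked voxel(s); "
            "exclude them from the mask"
        )
    z = np.full(raw.volumes.shape, np.nan)
    z[mask] = raw.volumes[mask] / raw.s0_volume[mask, None]
    return ZSpectrumVolume(z=z, schedule=raw.schedule, mask=mask)


def adaptive_filter_2d(
    image: np.ndarray,
    window_size: int = 3,
    noise_power: float | None = None,
) -> np.ndarray:
    """Locally adaptive noise-removal (Wiener-style) filter of a 2-D image.

    Per pixel, the local mean ``mu`` and variance ``s2`` are estimated over
    a ``window_size`` square window (reflective boundaries).  The noise
    power ``nu`` defaults to the mean of the local variances.  The output is

        mu + max(s2 - nu, 0) / max(s2, eps) * (image - mu)

    i.e. full shrinkage to the local mean where the local variance is
    explained by noise, and pass-through where local structure dominates.

    Parameters
    ----------
    image : 2-D ndarray
    window_size : odd int >= 3
    noise_power : float, optional
        Override the noise-power estimate (e.g. from a background region).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if window_size < 3 or window_size % 2 == 0:
        raise ValueError("window_size must be an odd integer >= 3")
    if window_size > min(image.shape):
        raise ValueError(
            f"window {window_size} larger than image {image.shape}"
        )
    mu = uniform_filter(image, size=window_size, mode="reflect")
    m2 = uniform_filter(image * image, size=window_size, mode="reflect")
    s2 = np.maximum(m2 - mu * mu, 0.0)
    nu = float(np.mean(s2)) if noise_power is None else float(noise_power)
    eps = np.finfo(float).tiny
    gain = np.maximum(s2 - nu, 0.0) / np.maximum(s2, eps)
    return mu + gain * (image - mu)


def filter_series(zvol: ZSpectrumVolume, window_size: int = 3) -> ZSpectrumVolume:
    """Apply the adaptive filter to every axial slice of every offset volume.

    NaN voxels (outside the mask) are excluded from the local statistics by
    filtering with the masked values replaced by the slice mean, then
    restoring NaN outside the mask.  Shape, schedule and mask are unchanged.
    """
    z = zvol.z
    out = np.full_like(z, np.nan)
    mask = zvol.mask
    for k in range(z.shape[2]):  # axial slices
        sl_mask = mask[:, :, k]
        if not np.any(sl_mask):
            continue
        for i in range(z.shape[3]):  # offsets
            sl = z[:, :, k, i]
            fill = np.nanmean(sl[sl_mask])
            work = np.where(sl_mask, sl, fill)
            filt = adaptive_filter_2d(work, window_size=window_size)
            out[:, :, k, i] = np.where(sl_mask, filt, np.nan)
    return ZSpectrumVolume(z=out, schedule=zvol.schedule, mask=mask)
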