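"""CEST effect metrics: Lorentzian difference and inverse-MTR maps.

Two metrics quantify the deviation of the measured Z-spectrum from the
fitted two-pool background Z_ref at a named offset:

    LD      = Z_ref - Z                (Lorentzian difference)
    MTR_REX = 1/Z - 1/Z_ref            (spillover-compensated inverse
                                        magnetization transfer ratio)

Both are evaluated from the B0-corrected, window-averaged spectra at
+3.5 ppm (amide proton transfer, APT) and -3.5 ppm (aliphatic NOE).
The MT pool amplitude map is taken directly from the background fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .b0 import CorrectedSpectra
from .lorentzian import VolumeFit

__all__ = [
    "METRIC_NAMES",
    "MetricMap",
    "compute_ld",
    "compute_mtr_rex",
    "extract_metric_maps",
]

METRIC_NAMES = ("LD_APT", "LD_NOE", "MTRREX_APT", "MTRREX_NOE", "MT_AMPLITUDE")

APT_OFFSET_PPM = 3.5
NOE_OFFSET_PPM = -3.5

#: reciprocal guard: Z or Z_ref at or below this is flagged missing
RECIPROCAL_EPS = 1e-3


@dataclass
class MetricMap:
    """A 3-D map of one scalar CEST metric."""

    values: np.ndarray
    metric_name: str
    offset_ppm: float | None
    b1_label: str | None = None

    def __post_init__(self) -> None:
        if self.metric_name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.metric_name!r}; "
                             f"expected one of {METRIC_NAMES}")
        self.values = np.asarray(self.values, dtype=float)


def compute_ld(zref, z):
    """Lorentzian difference ``Z_ref - Z`` (negative values permitted)."""
    return np.asarray(zref, dtype=float) - np.asarray(z, dtype=float)


def compute_mtr_rex(zref, z, eps: float = RECIPROCAL_EPS):
    """Inverse-difference metric ``1/Z - 1/Z_ref``.

    Values where ``Z`` or ``Z_ref`` is at or below ``eps`` (near-complete
    saturation) are returned as NaN rather than clipped, so downstream
    statistics are not biased by fabricated reciprocals.
    """
    zref = np.asarray(zref, dtype=float)
    z = np.asarray(z, dtype=float)
    valid = (z > eps) & (zref > eps)
    out = np.full(np.broadcast(zref, z).shape, np.nan)
    out[valid] = 1.0 / z[valid] - 1.0 / zref[valid]
    if out.ndim == 0:
        return float(out)
    return out


def extract_metric_maps(corrected: CorrectedSpectra, fits: VolumeFit,
                        b1_label: str | None = None,
                        half_width: float = 0.2) -> dict[str, MetricMap]:
    """Evaluate all five metric maps from corrected spectra and fits.

    LD and MTR_REX are computed from the window-averaged corrected Z and
    Z_ref at +-3.5 ppm; the MT amplitude map is the fitted ``a_mt``.
    """
    maps: dict[str, MetricMap] = {}
    for tag, offset in (("APT", APT_OFFSET_PPM), ("NOE", NOE_OFFSET_PPM)):
        zbar, zrefbar, ldbar = corrected.windowed(offset, half_width)
        maps[f"LD_{tag}"] = MetricMap(ldbar, f"LD_{tag}", offset, b1_label)
        maps[f"MTRREX_{tag}"] = MetricMap(
            compute_mtr_rex(zrefbar, zbar), f"MTRREX_{tag}", offset, b1_label)
    mt = np.where(fits.converged, fits.map("a_mt"), np.nan)
    maps["MT_AMPLITUDE"] = MetricMap(mt, "MT_AMPLITUDE", None, b1_label)
    return {name: maps[name] for name in METRIC_NAMES}
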