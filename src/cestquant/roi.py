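"""Region-of-interest statistics and tumor-heterogeneity measures.

Per metric map and subject, the tumor is compared against contralateral
normal-appearing white and grey matter (NAWM / NAGM):

    TC  = mean(tumor) - mean(reference)             tissue contrast
    CNR = TC / sqrt(std_tumor^2 + std_ref^2)        contrast-to-noise

Heterogeneity is summarized by patient-specific thresholds derived from
NAWM (mean +- 2 std of the same metric) and the percentages of tumor
voxels strictly above / below them (VP_hyper / VP_hypo).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import MetricMap

__all__ = [
    "RoiSet",
    "roi_mean_std",
    "tissue_contrast",
    "contrast_to_noise",
    "heterogeneity_thresholds",
    "volume_percent",
    "build_report",
]


@dataclass
class RoiSet:
    """Tumor and contralateral reference masks on the metric-map grid."""

    tumor: np.ndarray
    nawm: np.ndarray
    nagm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tumor = np.asarray(self.tumor, dtype=bool)
        self.nawm = np.asarray(self.nawm, dtype=bool)
        if self.nagm is not None:
            self.nagm = np.asarray(self.nagm, dtype=bool)
        masks = [m for m in (self.tumor, self.nawm, self.nagm) if m is not None]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if np.any(masks[i] & masks[j]):
                    raise ValueError("ROI masks must be pairwise disjoint")


def roi_mean_std(values: np.ndarray, mask: np.ndarray, ddof: int = 1):
    """Mean and sample standard deviation over valid (finite) masked voxels.

    Returns ``(mean, std, n_excluded)`` where ``n_excluded`` counts masked
    voxels dropped because their value was NaN (flagged upstream).
    Raises if no valid voxel remains.
    """
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(values, dtype=float)[mask]
    finite = np.isfinite(vals)
    n_excluded = int((~finite).sum())
    vals = vals[finite]
    if vals.size == 0:
        raise ValueError("ROI contains no valid voxels")
    std = float(np.std(vals, ddof=ddof)) if vals.size > ddof else 0.0
    return float(np.mean(vals)), std, n_excluded


def tissue_contrast(values: np.ndarray, tumor: np.ndarray, reference: np.ndarray) -> float:
    """Difference of ROI means: ``mean(tumor) - mean(reference)``."""
    mt, _, _ = roi_mean_std(values, tumor)
    mr, _, _ = roi_mean_std(values, reference)
    return mt - mr


def contrast_to_noise(values: np.ndarray, tumor: np.ndarray, reference: np.ndarray) -> float:
    """TC over the root-sum-square of the two ROI standard deviations.

    Returns NaN (flagged undefined) when both standard deviations vanish.
    """
    mt, st, _ = roi_mean_std(values, tumor)
    mr, sr, _ = roi_mean_std(values, reference)
    pooled = np.sqrt(st * st + sr * sr)
    if pooled == 0.0:
        return float("nan")
    return (mt - mr) / pooled


def heterogeneity_thresholds(values: np.ndarray, nawm: np.ndarray):
    """Patient-specific thresholds ``mean_NAWM +- 2 std_NAWM``.

    Thresholds are always derived from the same metric they classify.
    A zero NAWM standard deviation collapses both thresholds onto the
    mean (degenerate but returned as-is; ``volume_percent`` then counts
    no voxel in either class only at exact equality).
    """
    m, s, _ = roi_mean_std(values, nawm)
    return m + 2.0 * s, m - 2.0 * s


def volume_percent(values: np.ndarray, tumor: np.ndarray, thresholds) -> tuple[float, float]:
    """Percentages of tumor voxels strictly beyond the thresholds.

    ``vp_hyper`` counts voxels with value > upper threshold, ``vp_hypo``
    value < lower threshold; values exactly at a threshold belong to
    neither class.  The denominator is the full tumor voxel count
    (flagged NaN voxels count in the denominator, never in a numerator).
    """
    thresh_hyper, thresh_hypo = thresholds
    tumor = np.asarray(tumor, dtype=bool)
    n_total = int(tumor.sum())
    if n_total == 0:
        raise ValueError("tumor mask is empty")
    vals = np.asarray(values, dtype=float)[tumor]
    n_hyper = int(np.sum(vals > thresh_hyper))
    n_hypo = int(np.sum(vals < thresh_hypo))
    return 100.0 * n_hyper / n_total, 100.0 * n_hypo / n_total


def build_report(maps: dict[str, MetricMap], rois: RoiSet,
                 subject: str = "phantom") -> pd.DataFrame:
    """One tidy row per metric map: ROI statistics, TC/CNR, thresholds, VP.

    NAGM columns are NaN when no NAGM mask is provided.  Thresholds and
    volume percentages are computed per metric from its own NAWM values.
    """
    rows = []
    for name, mmap in maps.items():
        v = mmap.values
        mean_t, std_t, excl_t = roi_mean_std(v, rois.tumor)
        mean_w, std_w, excl_w = roi_mean_std(v, rois.nawm)
        row = {
            "subject": subject,
            "metric": name,
            "offset_ppm": mmap.offset_ppm,
            "b1": mmap.b1_label,
            "mean_tumor": mean_t, "std_tumor": std_t,
            "mean_nawm": mean_w, "std_nawm": std_w,
            "n_flagged_tumor": excl_t, "n_flagged_nawm": excl_w,
            "tc_tumor_nawm": tissue_contrast(v, rois.tumor, rois.nawm),
            "cnr_tumor_nawm": contrast_to_noise(v, rois.tumor, rois.nawm),
        }
        if rois.nagm is not None and rois.nagm.any():
            mean_g, std_g, _ = roi_mean_std(v, rois.nagm)
            row.update(
                mean_nagm=mean_g, std_nagm=std_g,
                tc_tumor_nagm=tissue_contrast(v, rois.tumor, rois.nagm),
                cnr_tumor_nagm=contrast_to_noise(v, rois.tumor, rois.nagm),
            )
        else:
            row.update(mean_nagm=np.nan, std_nagm=np.nan,
                       tc_tumor_nagm=np.nan, cnr_tumor_nagm=np.nan)
        thr = heterogeneity_thresholds(v, rois.nawm)
        vp_hyper, vp_hypo = volume_percent(v, rois.tumor, thr)
        row.update(thresh_hyper=thr[0], thresh_hypo=thr[1],
                   vp_hyper=vp_hyper, vp_hypo=vp_hypo)
        rows.append(row)
    return pd.DataFrame(rows)
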