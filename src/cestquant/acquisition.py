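"""Saturation offset schedules and pulse-train timing bookkeeping.

A CEST acquisition steps a saturation pulse train through a list of
frequency offsets (in ppm relative to the water resonance; positive is
downfield) and acquires one image volume per offset.  Two additional
volumes are acquired at a far off-resonance normalization frequency:
the first is discarded (the longitudinal magnetization has not reached
its steady state yet), the second serves as the unsaturated reference
``S0``.  This module carries that bookkeeping plus the trivial but
load-bearing arithmetic of the pulse train itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "OffsetSchedule",
    "SaturationTrain",
    "build_default_schedule",
    "train_total_duration",
    "train_duty_cycle",
    "slice_thickness",
]

#: offsets closer together than this (ppm) are considered duplicates
_OFFSET_RESOLUTION = 0.01


@dataclass(frozen=True)
class SaturationTrain:
    """A train of identical saturation RF pulses.

    Parameters
    ----------
    n_pulses : int
        Number of pulses in the train.
    pulse_duration_ms : float
        Duration of a single pulse, milliseconds.
    interpulse_delay_ms : float
        Gap between consecutive pulses, milliseconds.
    rms_b1_ut : float, optional
        Root-mean-square B1 amplitude over the train, microtesla.
        Carried as metadata only; it is never derived from a pulse shape.
    """

    n_pulses: int = 80
    pulse_duration_ms: float = 20.0
    interpulse_delay_ms: float = 20.0
    rms_b1_ut: float | None = None

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError(f"n_pulses must be >= 1, got {self.n_pulses}")
        if self.pulse_duration_ms <= 0:
            raise ValueError("pulse_duration_ms must be > 0")
        if self.interpulse_delay_ms < 0:
            raise ValueError("interpulse_delay_ms must be >= 0")


def train_total_duration(train: SaturationTrain) -> float:
    """Total saturation time of the train, in seconds.

    Each pulse occupies its own duration plus the following interpulse
    delay, so the train lasts ``n_pulses * (t_pulse + t_delay)``.
    """
    return train.n_pulses * (train.pulse_duration_ms + train.interpulse_delay_ms) * 1e-3


def train_duty_cycle(train: SaturationTrain) -> float:
    """Fraction of the train during which RF is applied (dimensionless)."""
    return train.pulse_duration_ms / (train.pulse_duration_ms + train.interpulse_delay_ms)


def slice_thickness(fov_mm: float, n_slices: int) -> float:
    """Slice thickness (mm) of an isotropic slab: FOV divided by slice count."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    return fov_mm / n_slices


@dataclass(frozen=True)
class OffsetSchedule:
    """Ordered saturation frequency offsets plus the normalization convention.

    Attributes
    ----------
    offsets : ndarray
        Saturation offsets in ppm, in acquisition order.  Does *not*
        include the far off-resonance normalization acquisitions.
    normalization_offset : float
        Offset (ppm) of the normalization images; must be far
        off-resonance (|offset| >= 100 ppm).
    n_discard_leading : int
        Number of leading normalization-offset images discarded before
        the retained ``S0`` image.
    """

    offsets: np.ndarray
    normalization_offset: float = -300.0
    n_discard_leading: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.offsets, dtype=float)
        object.__setattr__(self, "offsets", arr)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("offsets must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError("offsets must be finite")
        rounded = np.round(arr / _OFFSET_RESOLUTION).astype(np.int64)
        if len(np.unique(rounded)) != len(rounded):
            raise ValueError("offsets must be unique at 0.01 ppm resolution")
        if abs(self.normalization_offset) < 100.0:
            raise ValueError(
                "normalization offset must be far off-resonance (|offset| >= 100 ppm), "
                f"got {self.normalization_offset}"
            )
        if self.n_discard_leading < 0:
            raise ValueError("n_discard_leading must be >= 0")

    def __len__(self) -> int:
        return len(self.offsets)

    @property
    def n_acquisitions(self) -> int:
        """Volumes acquired in total: dummies + S0 + one per offset."""
        return len(self.offsets) + self.n_discard_leading + 1

    @property
    def sort_index(self) -> np.ndarray:
        """Indices mapping acquisition order to ascending-ppm order."""
        return np.argsort(self.offsets, kind="stable")

    @property
    def sorted_offsets(self) -> np.ndarray:
        return self.offsets[self.sort_index]

    def index_of(self, values, tol: float = _OFFSET_RESOLUTION / 2) -> np.ndarray:
        """Indices (acquisition order) of ``values`` within ``tol`` ppm.

        Raises
        ------
        ValueError
            If any requested offset is not present in the schedule.
        """
        values = np.atleast_1d(np.asarray(values, dtype=float))
        out = np.empty(len(values), dtype=np.intp)
        for i, v in enumerate(values):
            hits = np.nonzero(np.abs(self.offsets - v) <= tol)[0]
            if len(hits) == 0:
                raise ValueError(f"offset {v} ppm not present in schedule")
            out[i] = hits[0]
        return out

    def contains(self, value: float, tol: float = _OFFSET_RESOLUTION / 2) -> bool:
        return bool(np.any(np.abs(self.offsets - value) <= tol))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "offsets_ppm": [float(o) for o in self.offsets],
            "normalization_offset_ppm": float(self.normalization_offset),
            "n_discard_leading": int(self.n_discard_leading),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OffsetSchedule":
        return cls(
            offsets=np.asarray(d["offsets_ppm"], dtype=float),
            normalization_offset=float(d.get("normalization_offset_ppm", -300.0)),
            n_discard_leading=int(d.get("n_discard_leading", 1)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "OffsetSchedule":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_default_schedule() -> OffsetSchedule:
    """The default symmetric Z-spectrum sampling.

    Offsets: +-100 ppm; +-50..+-20 in steps of 10; +-10..+-5 in steps of
    0.5 (so the broad-MT fit subset at +-9.5 and +-8.5 ppm exists);
    +-4..+-1 in steps of 0.5; +-0.5..0 in steps of 0.25 — 51 offsets in
    total, stored in ascending order.  The normalization images sit at
    -300 ppm with one leading dummy discarded.
    """
    halves = np.concatenate(
        [
            [100.0],
            np.arange(50.0, 19.9, -10.0),
            np.arange(10.0, 4.9, -0.5),
            np.arange(4.0, 0.9, -0.5),
            [0.5, 0.25],
        ]
    )
    offsets = np.unique(np.concatenate([-halves, [0.0], halves]))
    return OffsetSchedule(offsets=offsets, normalization_offset=-300.0, n_discard_leading=1)
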