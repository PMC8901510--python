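"""Two-pool Lorentzian background model of the Z-spectrum.

The reference ("background") Z-spectrum is modelled as water direct
saturation (DS) plus the semi-solid magnetization-transfer (MT) pool,
each a Lorentzian line, on top of a constant baseline shift ``b``:

    Z_ref(dw) = 1 - A_w * (L_w^2/4) / (L_w^2/4 + (dw - d_w)^2)
                  - A_mt * (L_mt^2/4) / (L_mt^2/4 + (dw - d_mt)^2) + b

``A`` is the amplitude (dimensionless, 0..1 scale), ``L`` the full width
at half maximum in ppm, ``d`` the center frequency in ppm.  The seven
parameters are estimated per voxel by bounded nonlinear least squares on
offsets dominated by the background only: a narrow direct-saturation
subset around 0 ppm and a far off-resonance MT subset, deliberately
excluding the amide (+3.5 ppm) and aliphatic NOE (-3.5 ppm) regions so
the residual there isolates the CEST effects.

The model follows the statsmodels idiom: ``TwoPoolLorentzianModel``
wraps one spectrum and ``fit()`` returns a ``TwoPoolLorentzianResults``
carrying estimates, standard errors, diagnostics, ``summary()``,
``predict()`` and ``plot()``.  ``fit_volume`` runs the same estimator
over every masked voxel of a :class:`~cestquant.preprocess.ZSpectrumVolume`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .acquisition import OffsetSchedule
from .preprocess import ZSpectrumVolume

__all__ = [
    "PARAM_NAMES",
    "LorentzianPool",
    "lorentzian_value",
    "zref_value",
    "FitSubsets",
    "FitConfig",
    "TwoPoolLorentzianModel",
    "TwoPoolLorentzianResults",
    "fit_two_pool",
    "fit_volume",
    "VolumeFit",
]

PARAM_NAMES = ("a_water", "l_water", "d_water", "a_mt", "l_mt", "d_mt", "b")


@dataclass(frozen=True)
class LorentzianPool:
    """One Lorentzian line: amplitude, FWHM (ppm) and center (ppm)."""

    amplitude: float
    width: float
    center: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")


def lorentzian_value(pool: LorentzianPool, offsets_ppm) -> np.ndarray | float:
    """Evaluate ``A * (L^2/4) / (L^2/4 + (dw - d)^2)`` at the given offsets."""
    return _lorentzian(np.asarray(offsets_ppm, dtype=float),
                       pool.amplitude, pool.width, pool.center)


def _lorentzian(x, a, l, d):
    q = l * l / 4.0
    return a * q / (q + (x - d) ** 2)


def _zref(x, p):
    return (
        1.0
        - _lorentzian(x, p[0], p[1], p[2])
        - _lorentzian(x, p[3], p[4], p[5])
        + p[6]
    )


def zref_value(params, offsets_ppm) -> np.ndarray | float:
    """Background model value ``1 - water - MT + b`` at the given offsets.

    ``params`` is a length-7 sequence ordered as :data:`PARAM_NAMES`, or a
    mapping with those keys.
    """
    p = _as_param_vector(params)
    return _zref(np.asarray(offsets_ppm, dtype=float), p)


def _as_param_vector(params) -> np.ndarray:
    if isinstance(params, dict):
        return np.array([params[k] for k in PARAM_NAMES], dtype=float)
    p = np.asarray(params, dtype=float)
    if p.shape[-1] != 7:
        raise ValueError("expected 7 parameters (a_water, l_water, d_water, a_mt, l_mt, d_mt, b)")
    return p


@dataclass(frozen=True)
class FitSubsets:
    """Background offsets that constrain the two-pool fit.

    The direct-saturation subset samples the narrow water dip; the MT
    subset samples the broad background far from the CEST resonances.
    The two must be disjoint and every entry must exist in the schedule
    (within 0.01 ppm).
    """

    ds_offsets: tuple = (-1.0, -0.5, -0.25, 0.0, 0.25, 0.5, 1.0)
    mt_offsets: tuple = (
        -100.0, -50.0, -40.0, -30.0, -20.0, -10.0, -9.5, -9.0, -8.5,
        8.5, 9.0, 9.5, 10.0, 20.0, 30.0, 40.0, 50.0, 100.0,
    )

    def __post_init__(self) -> None:
        ds = np.asarray(self.ds_offsets, dtype=float)
        mt = np.asarray(self.mt_offsets, dtype=float)
        if np.intersect1d(np.round(ds * 100), np.round(mt * 100)).size:
            raise ValueError("DS and MT subsets must be disjoint")

    @property
    def union(self) -> np.ndarray:
        return np.sort(np.concatenate([self.ds_offsets, self.mt_offsets]))

    def indices_in(self, schedule: OffsetSchedule) -> np.ndarray:
        """Acquisition-order indices of the union subset; raises if missing."""
        return schedule.index_of(self.union)


@dataclass(frozen=True)
class FitConfig:
    """Initialization, bounds and solver settings for the two-pool fit.

    Defaults are generic 3 T ranges: water DS is a deep narrow line near
    0 ppm, MT a shallow line tens of ppm wide, the baseline a small
    signed shift.
    """

    x0: tuple = (0.8, 1.5, 0.0, 0.1, 40.0, 0.0, 0.0)
    lower: tuple = (0.0, 0.3, -1.0, 0.0, 10.0, -4.0, -0.2)
    upper: tuple = (1.0, 10.0, 1.0, 1.0, 300.0, 4.0, 0.2)
    ftol: float = 1e-10
    xtol: float = 1e-10
    gtol: float = 1e-10
    max_nfev: int = 2000

    def __post_init__(self) -> None:
        x0, lo, hi = (np.asarray(v, dtype=float) for v in (self.x0, self.lower, self.upper))
        if not (len(x0) == len(lo) == len(hi) == 7):
            raise ValueError("x0, lower, upper must have length 7")
        if np.any(x0 < lo) or np.any(x0 > hi):
            raise ValueError("x0 must lie inside the bounds")


class TwoPoolLorentzianModel:
    """Two-pool (DS + MT) background model for one Z-spectrum.

    Parameters
    ----------
    offsets : array-like
        Saturation offsets in ppm at which ``z`` was measured.
    z : array-like
        Normalized Z-spectrum values, same length as ``offsets``.
    subsets : FitSubsets, optional
        Background offsets used in the fit.  Every subset offset must be
        present in ``offsets`` (within 0.01 ppm); a missing offset raises
        before any fitting starts.
    config : FitConfig, optional
    """

    def __init__(self, offsets, z, subsets: FitSubsets | None = None,
                 config: FitConfig | None = None):
        self.offsets = np.asarray(offsets, dtype=float)
        self.z = np.asarray(z, dtype=float)
        if self.offsets.shape != self.z.shape or self.offsets.ndim != 1:
            raise ValueError("offsets and z must be 1-D arrays of equal length")
        self.subsets = subsets or FitSubsets()
        self.config = config or FitConfig()
        # resolve subset indices up front; missing offsets are structural
        sched = OffsetSchedule(offsets=self.offsets, normalization_offset=-300.0)
        self._subset_idx = self.subsets.indices_in(sched)
        if len(self._subset_idx) < 8:
            raise ValueError("need at least 8 background offsets to fit 7 parameters")

    @classmethod
    def from_schedule(cls, schedule: OffsetSchedule, z, **kwargs) -> "TwoPoolLorentzianModel":
        return cls(schedule.offsets, z, **kwargs)

    def fit(self) -> "TwoPoolLorentzianResults":
        """Bounded nonlinear least squares over the background subsets.

        Voxels with non-finite z at a subset offset yield a flagged
        non-converged sentinel result instead of raising.
        """
        x = self.offsets[self._subset_idx]
        y = self.z[self._subset_idx]
        if not np.all(np.isfinite(y)):
            return TwoPoolLorentzianResults._sentinel(self, len(x))
        params, cost, jac, success, nfev = _solve(x, y, self.config)
        return TwoPoolLorentzianResults(self, params, cost, jac, success, nfev, len(x))


def _solve(x, y, cfg: FitConfig):
    """Run the bounded TRF solver on one background spectrum."""
    res = least_squares(
        lambda p: _zref(x, p) - y,
        np.asarray(cfg.x0, dtype=float),
        bounds=(np.asarray(cfg.lower, float), np.asarray(cfg.upper, float)),
        ftol=cfg.ftol, xtol=cfg.xtol, gtol=cfg.gtol, max_nfev=cfg.max_nfev,
        method="trf",
    )
    return res.x, res.cost, res.jac, bool(res.success), int(res.nfev)


class TwoPoolLorentzianResults:
    """Estimates and diagnostics of one two-pool background fit."""

    def __init__(self, model, params, cost, jac, converged, nfev, n_used):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.converged = bool(converged)
        self.nfev = int(nfev)
        self.n_offsets_used = int(n_used)
        self._cost = float(cost) if cost is not None else np.nan
        self._jac = jac

    @classmethod
    def _sentinel(cls, model, n_used):
        return cls(model, np.full(7, np.nan), np.nan, None, False, 0, n_used)

    # -- parameter access -------------------------------------------------

    @property
    def params_dict(self) -> dict:
        return dict(zip(PARAM_NAMES, self.params))

    @property
    def water(self) -> LorentzianPool:
        return LorentzianPool(*self.params[0:3])

    @property
    def mt(self) -> LorentzianPool:
        return LorentzianPool(*self.params[3:6])

    @property
    def baseline(self) -> float:
        return float(self.params[6])

    # -- diagnostics -------------------------------------------------------

    @property
    def residual_rms(self) -> float:
        """Root-mean-square residual over the fitted background offsets."""
        if not self.converged:
            return np.nan
        return float(np.sqrt(2.0 * self._cost / self.n_offsets_used))

    @property
    def scale(self) -> float:
        """Residual variance estimate (denominator n - p)."""
        dof = max(self.n_offsets_used - len(self.params), 1)
        return 2.0 * self._cost / dof

    def cov_params(self) -> np.ndarray:
        """Asymptotic covariance of the estimates, ``s^2 (J'J)^-1``.

        Near-singular information (e.g. a vanishing pool amplitude makes
        its width and center unidentifiable) yields large or infinite
        variances via the pseudo-inverse.
        """
        if self._jac is None:
            return np.full((7, 7), np.nan)
        jtj = self._jac.T @ self._jac
        return self.scale * np.linalg.pinv(jtj)

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of the seven parameter estimates."""
        return np.sqrt(np.clip(np.diag(self.cov_params()), 0.0, None))

    def predict(self, offsets_ppm=None) -> np.ndarray:
        """Background model Z_ref at ``offsets_ppm`` (default: model offsets)."""
        if offsets_ppm is None:
            offsets_ppm = self.model.offsets
        return _zref(np.asarray(offsets_ppm, dtype=float), self.params)

    def summary(self) -> str:
        lines = [
            "Two-pool Lorentzian background fit",
            "=" * 54,
            f"offsets used:  {self.n_offsets_used}   converged: {self.converged}"
            f"   nfev: {self.nfev}",
            f"residual rms:  {self.residual_rms:.3e}",
            "-" * 54,
            f"{'param':>8s} {'estimate':>12s} {'std err':>12s}",
        ]
        for name, est, se in zip(PARAM_NAMES, self.params, self.bse):
            lines.append(f"{name:>8s} {est:12.5f} {se:12.5f}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data, fitted background and their difference vs offset."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        order = np.argsort(m.offsets)
        ax.plot(m.offsets[order], m.z[order], "k.", label="Z")
        ax.plot(m.offsets[order], self.predict(m.offsets[order]), "C0-", label="Z_ref fit")
        ax.plot(m.offsets[order],
                self.predict(m.offsets[order]) - m.z[order], "C3-", label="LD")
        ax.set_xlabel("offset (ppm)")
        ax.set_ylabel("Z")
        ax.invert_xaxis()  # CEST convention: downfield left
        ax.legend()
        return ax


def fit_two_pool(offsets, z, subsets: FitSubsets | None = None,
                 config: FitConfig | None = None) -> TwoPoolLorentzianResults:
    """Convenience: build the model and fit in one call."""
    return TwoPoolLorentzianModel(offsets, z, subsets=subsets, config=config).fit()


@dataclass
class VolumeFit:
    """Voxel-wise two-pool fit results as parameter maps.

    ``params`` has shape (x, y, z, 7) ordered as :data:`PARAM_NAMES`;
    non-converged or unmasked voxels are NaN with ``converged`` False.
    """

    params: np.ndarray
    residual_rms: np.ndarray
    converged: np.ndarray
    mask: np.ndarray
    n_offsets_used: int
    subsets: FitSubsets
    config: FitConfig

    def map(self, name: str) -> np.ndarray:
        """3-D map of one named parameter."""
        return self.params[..., PARAM_NAMES.index(name)]

    @property
    def convergence_fraction(self) -> float:
        n = int(self.mask.sum())
        return float(self.converged.sum() / n) if n else float("nan")


def fit_volume(zvol: ZSpectrumVolume, subsets: FitSubsets | None = None,
               config: FitConfig | None = None) -> VolumeFit:
    """Fit the two-pool background independently in every masked voxel."""
    subsets = subsets or FitSubsets()
    config = config or FitConfig()
    idx = subsets.indices_in(zvol.schedule)
    x = zvol.schedule.offsets[idx]

    shape = zvol.spatial_shape
    params = np.full(shape + (7,), np.nan)
    rms = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)

    vox = np.argwhere(zvol.mask)
    zsub = zvol.z[..., idx]
    for i, j, k in vox:
        y = zsub[i, j, k]
        if not np.all(np.isfinite(y)):
            continue
        p, cost, _, success, _ = _solve(x, y, config)
        if success:
            params[i, j, k] = p
            rms[i, j, k] = np.sqrt(2.0 * cost / len(x))
            conv[i, j, k] = True
    return VolumeFit(params=params, residual_rms=rms, converged=conv,
                     mask=zvol.mask.copy(), n_offsets_used=len(x),
                     subsets=subsets, config=config)
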