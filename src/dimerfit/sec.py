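"""Homodimer K_D estimation from small-zone size-exclusion chromatography.

A fast-exchange monomer-dimer system (interconversion much faster than the
run) elutes as a single population-averaged peak whose position moves with
the loaded concentration. Treating elution *velocity* as inverse elution
volume at constant flow rate, the mixed peak obeys the linear mixing rule

    1/V_mixed = f · (1/V_dimer) + (1 − f) · (1/V_monomer),

where f is the dimer fraction (monomer units in dimers) and V_dimer,
V_monomer are the calibrated pure-species elution volumes. Inverting the
rule converts each observed peak volume into a dimer fraction, and the set
of (load concentration, dimer fraction) points is fit to the mass-action
isotherm

    f(T; K_D) = (4T + K_D − sqrt(K_D² + 8·K_D·T)) / (4T),

by least squares on the fraction scale, yielding the homodimer K_D.

Deliberate simplifications: diffusion/dispersion and on-column dilution are
ignored, so the loaded concentration stands in for the equilibrium total —
a known bias source, one reason SEC-derived K_D values should be read as a
range rather than a point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from ._boot import se_log10_kd, studentized_bootstrap_ci
from .equilibrium import dimer_fraction
from .errors import DataError, FitError, TruncatedPeakWarning

__all__ = [
    "SECCalibration",
    "SECRun",
    "SECFitResult",
    "detect_peak_volume",
    "predict_elution_volume",
    "volume_to_dimer_fraction",
    "SECKdEstimator",
    "fit_sec_kd",
]


@dataclass(frozen=True)
class SECCalibration:
    """Pure-species elution volumes (mL) bracketing the mixed peak.

    The dimer, being larger, elutes earlier: ``v_dimer < v_monomer``.
    ``column_volume`` is an optional sanity bound.
    """

    v_dimer: float
    v_monomer: float
    column_volume: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.v_dimer < self.v_monomer):
            raise DataError(
                f"require 0 < v_dimer < v_monomer, got "
                f"v_dimer={self.v_dimer!r}, v_monomer={self.v_monomer!r}"
            )
        if self.column_volume is not None and self.v_monomer > self.column_volume:
            raise DataError("elution volumes exceed the column volume")


@dataclass
class SECRun:
    """One chromatography run: load concentration plus a trace or peak volume.

    ``load_conc`` is the loaded concentration in µM monomer equivalents.
    ``trace`` is an optional ``(volumes_mL, absorbances_mAU)`` pair with
    strictly increasing volumes; if no pre-extracted ``peak_volume`` is
    given, it is detected from the trace.
    """

    load_conc: float
    trace: tuple[np.ndarray, np.ndarray] | None = None
    peak_volume: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.load_conc) or self.load_conc <= 0:
            raise DataError(f"load_conc must be positive, got {self.load_conc!r}")
        if self.trace is not None:
            v = np.asarray(self.trace[0], dtype=float)
            a = np.asarray(self.trace[1], dtype=float)
            if v.ndim != 1 or v.shape != a.shape:
                raise DataError("trace must be two 1-D arrays of equal length")
            if np.any(np.diff(v) <= 0):
                raise DataError("trace volumes must be strictly increasing")
            self.trace = (v, a)
        if self.trace is None and self.peak_volume is None:
            raise DataError("SECRun needs either a trace or a peak_volume")


@dataclass(frozen=True)
class SECPerRun:
    load_conc: float
    peak_volume: float
    dimer_fraction: float
    predicted_fraction: float


@dataclass(frozen=True)
class SECFitResult:
    kd_hat: float  # µM
    ci_low: float | None
    ci_high: float | None
    per_run: tuple[SECPerRun, ...]
    residual_norm: float
    n_runs: int


def detect_peak_volume(trace, smooth_window: int = 5) -> float:
    """Elution volume of the trace's highest point, after light smoothing.

    The trace is smoothed with a centered moving average (default window 5
    points, edge-reflected) and the volume of the global maximum returned;
    ties break toward the smallest volume. A maximum on either boundary
    raises :class:`TruncatedPeakWarning` (the peak may be cut off).
    """
    v = np.asarray(trace[0], dtype=float)
    a = np.asarray(trace[1], dtype=float)
    if v.ndim != 1 or v.shape != a.shape or len(v) < 5:
        raise DataError("trace must be two equal-length 1-D arrays of >= 5 points")
    if np.any(np.diff(v) <= 0):
        raise DataError("trace volumes must be strictly increasing")
    if np.ptp(a) == 0:
        raise DataError("trace is flat: no peak to detect")
    if smooth_window > 1:
        w = int(smooth_window)
        if w % 2 == 0:
            raise ValueError("smooth_window must be odd")
        pad = w // 2
        padded = np.pad(a, pad, mode="reflect")
        a = np.convolve(padded, np.ones(w) / w, mode="valid")
    idx = int(np.argmax(a))  # argmax takes the first (smallest-volume) tie
    if idx in (0, len(v) - 1):
        warnings.warn(
            f"trace maximum at boundary volume {v[idx]:.3g} mL; peak may be truncated",
            TruncatedPeakWarning,
            stacklevel=2,
        )
    return float(v[idx])


def predict_elution_volume(f_dimer: float, calib: SECCalibration) -> float:
    """Mixed-peak elution volume under the velocity (inverse-volume) mixing rule."""
    if not (0.0 <= f_dimer <= 1.0) or not np.isfinite(f_dimer):
        raise ValueError(f"f_dimer must lie in [0, 1], got {f_dimer!r}")
    inv = f_dimer / calib.v_dimer + (1.0 - f_dimer) / calib.v_monomer
    return 1.0 / inv


def volume_to_dimer_fraction(
    v_obs: float, calib: SECCalibration, clamp_tol: float = 0.02
) -> float:
    """Invert the mixing rule: observed peak volume (mL) to dimer fraction.

    Volumes falling outside [v_dimer, v_monomer] by up to ``clamp_tol`` of
    the interval width are clamped (measurement noise); anything further out
    raises :class:`DataError` (likely mis-calibration).
    """
    if not np.isfinite(v_obs) or v_obs <= 0:
        raise DataError(f"v_obs must be positive, got {v_obs!r}")
    delta = clamp_tol * (calib.v_monomer - calib.v_dimer)
    if v_obs < calib.v_dimer - delta or v_obs > calib.v_monomer + delta:
        raise DataError(
            f"observed volume {v_obs:.4g} mL lies outside the calibrated "
            f"interval [{calib.v_dimer:.4g}, {calib.v_monomer:.4g}] mL by more "
            f"than {clamp_tol:.0%} of its width: check the calibration"
        )
    v = min(max(v_obs, calib.v_dimer), calib.v_monomer)
    f = (1.0 / v - 1.0 / calib.v_monomer) / (
        1.0 / calib.v_dimer - 1.0 / calib.v_monomer
    )
    return float(min(max(f, 0.0), 1.0))


class SECKdEstimator(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator of the homodimer K_D from SEC peaks.

    ``fit(X, y)`` takes load concentrations (µM, monomer equivalents) as X
    and observed peak elution volumes (mL) as y; volumes are converted to
    dimer fractions via the calibration and the mass-action isotherm is fit
    on the fraction scale. ``predict(X)`` returns model peak volumes.

    Attributes (after fit): ``kd_`` (µM), ``ci_`` (bootstrap percentile
    interval), ``fractions_`` (observed dimer fractions),
    ``result_`` (:class:`SECFitResult`).
    """

    #: observed fractions must leave this band for the fit to be identifiable
    _FLOOR, _CEIL = 0.05, 0.95

    def __init__(
        self,
        calibration: SECCalibration | None = None,
        n_boot: int = 1000,
        ci_level: float = 0.95,
        clamp_tol: float = 0.02,
        random_state: int | None = None,
    ):
        self.calibration = calibration
        self.n_boot = n_boot
        self.ci_level = ci_level
        self.clamp_tol = clamp_tol
        self.random_state = random_state

    def _fit_core(self, loads: np.ndarray, fracs: np.ndarray, kd0: float):
        """1-D least squares on the fraction scale; returns (kd, se_log10_kd)."""
        lo, hi = -4.0, 5.0  # log10 µM

        def res(x):
            kd = 10.0 ** x[0]
            return np.array([dimer_fraction(t, kd) for t in loads]) - fracs

        sol = least_squares(
            res,
            x0=[np.clip(np.log10(kd0), lo, hi)],
            bounds=([lo], [hi]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        return 10.0 ** sol.x[0], se_log10_kd(sol, len(loads), 1)

    def fit(self, X, y):
        if self.calibration is None:
            raise DataError("SECKdEstimator requires a calibration")
        loads = np.asarray(X, dtype=float)
        if loads.ndim == 2:
            if loads.shape[1] != 1:
                raise DataError("X must be a single load-concentration column")
            loads = loads[:, 0]
        vols = np.asarray(y, dtype=float)
        if loads.shape != vols.shape or loads.ndim != 1:
            raise DataError("X and y must be 1-D of equal length")
        if len(loads) < 3:
            raise DataError("need at least 3 runs")
        if np.max(loads) / np.min(loads) < 4.0:
            raise DataError("load concentrations must span at least 4-fold")

        fracs = np.array(
            [volume_to_dimer_fraction(v, self.calibration, self.clamp_tol) for v in vols]
        )
        if np.all(fracs < self._FLOOR) or np.all(fracs > self._CEIL):
            raise FitError(
                "no monomer-dimer transition sampled (all dimer fractions "
                f"{'below' if fracs[0] < 0.5 else 'above'} "
                f"{self._FLOOR if fracs[0] < 0.5 else self._CEIL}); rerun at "
                "load concentrations nearer the expected K_D"
            )

        # initial K_D: the load whose observed fraction is nearest 1/2
        kd0 = loads[int(np.argmin(np.abs(fracs - 0.5)))]
        kd, se_log_kd = self._fit_core(loads, fracs, kd0)
        pred = np.array([dimer_fraction(t, kd) for t in loads])
        residuals = fracs - pred

        ci = (float("nan"), float("nan"))
        if self.n_boot and self.n_boot > 0:
            rng = np.random.default_rng(self.random_state)
            ci = studentized_bootstrap_ci(
                kd,
                se_log_kd,
                pred,
                residuals,
                1,
                lambda f_b: self._fit_core(loads, f_b, kd),
                self.n_boot,
                self.ci_level,
                rng,
                clip=(0.0, 1.0),
            )

        self.kd_ = kd
        self.ci_ = ci
        self.fractions_ = fracs
        self.loads_ = loads
        self.result_ = SECFitResult(
            kd_hat=kd,
            ci_low=ci[0],
            ci_high=ci[1],
            per_run=tuple(
                SECPerRun(float(t), float(v), float(f), float(p))
                for t, v, f, p in zip(loads, vols, fracs, pred)
            ),
            residual_norm=float(np.linalg.norm(residuals)),
            n_runs=len(loads),
        )
        return self

    def predict(self, X):
        """Model-predicted peak elution volumes (mL) at load concentrations X."""
        if not hasattr(self, "kd_"):
            raise FitError("estimator is not fitted")
        loads = np.asarray(X, dtype=float)
        if loads.ndim == 2:
            loads = loads[:, 0]
        return np.array(
            [
                predict_elution_volume(dimer_fraction(t, self.kd_), self.calibration)
                for t in loads
            ]
        )


def fit_sec_kd(
    runs: list[SECRun],
    calib: SECCalibration,
    n_boot: int = 1000,
    random_state: int | None = 0,
    smooth_window: int = 5,
    clamp_tol: float = 0.02,
) -> SECFitResult:
    """Fit the homodimer K_D to a set of SEC runs.

    Runs carrying a trace have their peak detected first; runs with a
    pre-extracted ``peak_volume`` use it directly. Thin wrapper over
    :class:`SECKdEstimator`.
    """
    loads, vols = [], []
    for run in runs:
        v = run.peak_volume
        if v is None:
            v = detect_peak_volume(run.trace, smooth_window=smooth_window)
        loads.append(run.load_conc)
        vols.append(v)
    est = SECKdEstimator(
        calibration=calib,
        n_boot=n_boot,
        clamp_tol=clamp_tol,
        random_state=random_state,
    ).fit(np.asarray(loads), np.asarray(vols))
    return est.result_
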