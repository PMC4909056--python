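"""Xylem vulnerability curves: the two-parameter sigmoid and its fit.

A vulnerability curve records the percent loss of hydraulic conductivity (PLC)
of a branch segment as xylem pressure is driven progressively more negative.
The curve is modelled with the Pammenter–Vander Willigen logistic

    PLC(P) = 100 / (1 + exp(s/25 · (P − P50)))

where P50 (MPa, negative) is the pressure at 50 % loss and s (% MPa⁻¹, > 0)
the slope at the inflexion point.  P12 and P88 — the onset of embolism and
the threshold of irreversible hydraulic failure in angiosperms — follow from
the analytic inverse.

Sign convention: pressures are tensions, stored as negative MPa; P12 > P50 >
P88 on the signed axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PLCSeries",
    "VulnCurveFit",
    "HydraulicMeasurement",
    "sigmoid_plc",
    "pressure_at_plc",
    "plc_from_conductance",
    "fit_vulnerability_curve",
    "VulnerabilityCurve",
    "empirical_conductivities",
]


def sigmoid_plc(pressure_mpa, p50: float, slope: float):
    """PLC (%) predicted by the logistic model at the given xylem pressure.

    Strictly decreasing in pressure (PLC grows as tension increases); equals
    50 exactly at ``p50``.  ``slope`` must be positive.
    """
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    p = np.asarray(pressure_mpa, dtype=float)
    out = 100.0 / (1.0 + np.exp(np.clip(slope / 25.0 * (p - p50), -700, 700)))
    return float(out) if out.ndim == 0 else out


def pressure_at_plc(p50: float, slope: float, target_plc: float) -> float:
    """Analytic inverse: the pressure (MPa) at which PLC equals ``target_plc``.

    ``P = P50 + (25/s) · ln((100 − t)/t)``; the logistic is symmetric about
    P50, so |P50 − P12| = |P88 − P50|.
    """
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    if not 0.0 < target_plc < 100.0:
        raise ValueError(f"target PLC must lie in (0, 100), got {target_plc}")
    return p50 + 25.0 / slope * np.log((100.0 - target_plc) / target_plc)


def plc_from_conductance(k_i: float, k_max: float) -> float:
    """Percent loss of conductivity from a conductance pair, clipped to [0, 100].

    Small overshoots (k_i marginally above k_max from measurement noise) clip
    to 0 rather than erroring.
    """
    if k_max <= 0:
        raise ValueError(f"k_max must be positive, got {k_max}")
    if k_i < 0:
        raise ValueError(f"conductance must be non-negative, got {k_i}")
    return float(np.clip(100.0 * (1.0 - k_i / k_max), 0.0, 100.0))


@dataclass
class PLCSeries:
    """One branch's vulnerability measurements.

    ``pressures_mpa`` are negative and strictly decreasing (increasing
    tension); ``plc`` holds the matching percent-loss values.  Use
    :func:`plc_from_conductance` to build ``plc`` from raw conductances.
    """

    branch_id: str
    pressures_mpa: np.ndarray
    plc: np.ndarray

    def __post_init__(self):
        self.pressures_mpa = np.asarray(self.pressures_mpa, dtype=float)
        self.plc = np.asarray(self.plc, dtype=float)
        if self.pressures_mpa.shape != self.plc.shape:
            raise ValueError("pressures and PLC must have equal length")
        if np.any(np.diff(self.pressures_mpa) >= 0):
            raise ValueError("pressures must be strictly decreasing (more negative)")
        if np.any((self.plc < 0) | (self.plc > 100)):
            raise ValueError("PLC values must lie in [0, 100]")


@dataclass
class VulnCurveFit:
    """Fitted sigmoid parameters with derived thresholds and QC flags."""

    branch_id: str
    p50: float
    slope: float
    p12: float
    p88: float
    rss: float
    max_plc_reached: float
    converged: bool
    qc_pass: bool
    n_points: int
    message: str = ""


@dataclass
class HydraulicMeasurement:
    """Flow-normalized empirical conductivities of one segment."""

    ks_emp: float  # K_h / A_xylem, kg m⁻¹ MPa⁻¹ s⁻¹
    kl_emp: float | None  # K_h / A_L, None when leaf area unknown


def empirical_conductivities(
    k_h: float, a_xylem_m2: float, a_leaf_m2: float | None = None
) -> HydraulicMeasurement:
    """Normalize a measured hydraulic conductivity K_h (kg m MPa⁻¹ s⁻¹).

    KS_emp divides by the maximal basipetal sapwood area; KL_emp by the
    cumulative distal leaf area when available.
    """
    if a_xylem_m2 <= 0:
        raise ValueError("sapwood area must be positive")
    if k_h < 0:
        raise ValueError("conductivity must be non-negative")
    kl = None
    if a_leaf_m2 is not None:
        if a_leaf_m2 <= 0:
            raise ValueError("leaf area must be positive")
        kl = k_h / a_leaf_m2
    return HydraulicMeasurement(ks_emp=k_h / a_xylem_m2, kl_emp=kl)


class VulnerabilityCurve:
    """Least-squares sigmoid fit of one PLC series.

    Nonlinear least squares on the PLC scale with multi-start initialization:
    the primary start puts P50 at the pressure whose observed PLC is nearest
    50 and sets the slope from the central finite-difference gradient of the
    series; a coarse fallback grid over (P50, s) guards against bad starts.
    Points with PLC exactly 0 or 100 are kept unweighted.

    Fitted attributes (set by :meth:`fit`): ``p50_``, ``slope_``, ``p12_``,
    ``p88_``, ``rss_``, ``converged_``, ``qc_pass_``.

    QC: a fit passes when it converged with s > 0, the series has ≥ 4 points
    whose observed PLC spans below ``qc_span_low`` and above ``qc_span_high``,
    and the maximum PLC reached is at least ``qc_max_plc`` (the measurement
    stopping rule: spin until ≥ 90 % loss).
    """

    #: fallback slope starts, % MPa⁻¹
    _SLOPE_GRID = (10.0, 25.0, 50.0, 100.0)

    def __init__(
        self,
        qc_span_low: float = 30.0,
        qc_span_high: float = 70.0,
        qc_max_plc: float = 90.0,
        min_points: int = 4,
    ):
        self.qc_span_low = qc_span_low
        self.qc_span_high = qc_span_high
        self.qc_max_plc = qc_max_plc
        self.min_points = min_points

    @staticmethod
    def _residuals(theta, pressures, plc):
        p50, log_s = theta
        return sigmoid_plc(pressures, p50, np.exp(log_s)) - plc

    def _starts(self, pressures, plc):
        p50_0 = pressures[np.argmin(np.abs(plc - 50.0))]
        starts = []
        # Central finite-difference slope of PLC vs P; at the inflexion the
        # model derivative is exactly -s, so s0 = -dPLC/dP there.
        if len(pressures) >= 3:
            grad = np.gradient(plc, pressures)
            s0 = -grad[np.argmin(np.abs(plc - 50.0))]
            if np.isfinite(s0) and s0 > 0:
                starts.append((p50_0, s0))
        for s in self._SLOPE_GRID:
            starts.append((p50_0, s))
            starts.append((np.median(pressures), s))
        return starts

    def fit(self, series: PLCSeries) -> "VulnerabilityCurve":
        pressures, plc = series.pressures_mpa, series.plc
        self.n_points_ = len(pressures)
        self.max_plc_reached_ = float(np.max(plc)) if len(plc) else np.nan
        self.branch_id_ = series.branch_id

        best = None
        message = ""
        if len(pressures) >= 2 and np.ptp(plc) > 0:
            for p50_0, s0 in self._starts(pressures, plc):
                try:
                    res = least_squares(
                        self._residuals,
                        x0=[p50_0, np.log(s0)],
                        args=(pressures, plc),
                        method="lm" if len(pressures) > 2 else "trf",
                        max_nfev=2000,
                    )
                except Exception as exc:  # pragma: no cover - optimizer guard
                    message = str(exc)
                    continue
                rss = float(np.sum(res.fun**2))
                if res.success and (best is None or rss < best[0]):
                    best = (rss, res.x)
        else:
            message = "degenerate series (constant PLC or too few points)"

        if best is None:
            self.converged_ = False
            self.p50_ = self.slope_ = self.p12_ = self.p88_ = np.nan
            self.rss_ = np.nan
            self.qc_pass_ = False
            self.message_ = message or "no start converged"
            return self

        self.rss_, (self.p50_, log_s) = best
        self.slope_ = float(np.exp(log_s))
        self.p12_ = pressure_at_plc(self.p50_, self.slope_, 12.0)
        self.p88_ = pressure_at_plc(self.p50_, self.slope_, 88.0)
        self.converged_ = True
        self.message_ = ""
        self.qc_pass_ = bool(
            self.n_points_ >= self.min_points
            and np.min(plc) < self.qc_span_low
            and np.max(plc) > self.qc_span_high
            and self.max_plc_reached_ >= self.qc_max_plc
            and self.slope_ > 0
        )
        return self

    def predict(self, pressures_mpa):
        """Model PLC at the given pressures (requires a converged fit)."""
        if not getattr(self, "converged_", False):
            raise RuntimeError("curve has no converged fit")
        return sigmoid_plc(np.asarray(pressures_mpa, dtype=float), self.p50_, self.slope_)

    def result(self) -> VulnCurveFit:
        return VulnCurveFit(
            branch_id=self.branch_id_,
            p50=self.p50_,
            slope=self.slope_,
            p12=self.p12_,
            p88=self.p88_,
            rss=self.rss_,
            max_plc_reached=self.max_plc_reached_,
            converged=self.converged_,
            qc_pass=self.qc_pass_,
            n_points=self.n_points_,
            message=self.message_,
        )


def fit_vulnerability_curve(series: PLCSeries, **kwargs) -> VulnCurveFit:
    """Fit the sigmoid to one PLC series; see :class:`VulnerabilityCurve`.

    Never raises on bad data: non-convergence is reported through the
    ``converged``/``qc_pass`` flags and the diagnostic message.
    """
    return VulnerabilityCurve(**kwargs).fit(series).result()
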