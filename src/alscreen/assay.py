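"""Analysis of the pipeline's downstream assays.

Three computations mirror how nucleotide-binding-domain inhibitors are
characterised experimentally:

* **calcein-AM efflux** — fluorescence time courses are background-corrected
  and fit by linear regression; the efflux relative to control is the
  inverse slope ratio, ``efflux = m_control / m_compound``.
* **dose-response** — the three-parameter logistic
  ``Y = Bottom + (Top − Bottom)/(1 + 10^(X − LogIC50))`` (X = log10 of the
  concentration in µM) is fit by nonlinear least squares; standard errors
  come from the Gauss–Newton covariance at the optimum and
  ``IC50 = 10^LogIC50``.
* **vanadate-sensitive ATPase activity** — absorbances convert to nmol
  inorganic phosphate via a linear phosphate standard curve, normalise by
  reaction time and protein amount, and the vanadate-inhibited background is
  subtracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats


class AssayInputError(ValueError):
    """Raised for malformed assay inputs."""


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge; carries diagnostics."""

    def __init__(self, message: str, best_params=None, diagnostics: str = ""):
        super().__init__(message)
        self.best_params = best_params
        self.diagnostics = diagnostics


# --------------------------------------------------------------------------
# fluorescence slopes and efflux
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SlopeFit:
    """OLS slope of background-corrected fluorescence vs time."""

    slope: float  # a.u./s
    stderr: float
    intercept: float
    n_points: int


def fluorescence_slope(
    time: Sequence[float], signal: Sequence[float], background: float | Sequence[float] = 0.0
) -> SlopeFit:
    """Least-squares slope of (signal − background) against time."""
    t = np.asarray(time, dtype=float)
    y = np.asarray(signal, dtype=float) - np.asarray(background, dtype=float)
    if len(t) < 3:
        raise AssayInputError("fluorescence series needs at least 3 time points")
    if not np.all(np.diff(t) > 0):
        raise AssayInputError("time points must be strictly increasing")
    res = stats.linregress(t, y)
    stderr = 0.0 if np.isnan(res.stderr) else float(res.stderr)
    return SlopeFit(slope=float(res.slope), stderr=stderr, intercept=float(res.intercept), n_points=len(t))


def calcein_efflux(m_compound: float, m_control: float, *, rel_tolerance: float = 1e-6) -> float:
    """Calcein-AM efflux relative to control: 1 ÷ (m_compound / m_control).

    Calcein accumulation is a surrogate for pump inhibition, so the inverse
    slope ratio reads as residual transporter activity: a compound that
    doubles the fluorescence slope relative to control (strong inhibition)
    gives efflux 0.5.
    """
    if m_control == 0:
        raise AssayInputError("control slope must be non-zero")
    if m_compound == 0:
        raise AssayInputError("compound slope is zero; efflux undefined")
    if abs(m_compound) < rel_tolerance * abs(m_control):
        warnings.warn("compound slope is near zero; efflux value is unstable")
    return float(m_control / m_compound)


# --------------------------------------------------------------------------
# three-parameter dose-response fit
# --------------------------------------------------------------------------


def three_param_logistic(x, top, bottom, log_ic50):
    """Y = Bottom + (Top − Bottom)/(1 + 10^(X − LogIC50))."""
    return bottom + (top - bottom) / (1 + 10.0 ** (np.asarray(x, dtype=float) - log_ic50))


@dataclass(frozen=True)
class DoseResponseFit:
    """Three-parameter logistic fit results (concentration scale: µM)."""

    top: float
    bottom: float
    log_ic50: float
    se_top: float
    se_bottom: float
    se_log_ic50: float
    n_points: int
    residual_ss: float
    converged: bool = True

    @property
    def ic50(self) -> float:
        """IC50 in µM: 10^LogIC50."""
        return ic50_from_log(self.log_ic50)

    def summary(self) -> str:
        lines = [
            "Three-parameter dose-response fit",
            "---------------------------------",
            f"  Top      {self.top:10.4g}  (SE {self.se_top:.3g})",
            f"  Bottom   {self.bottom:10.4g}  (SE {self.se_bottom:.3g})",
            f"  LogIC50  {self.log_ic50:10.4g}  (SE {self.se_log_ic50:.3g})",
            f"  IC50     {self.ic50:10.4g} µM",
            f"  n = {self.n_points}, residual SS = {self.residual_ss:.4g}",
        ]
        return "\n".join(lines)


def ic50_from_log(log_ic50: float) -> float:
    """IC50 (µM) from its base-10 logarithm."""
    if not np.isfinite(log_ic50):
        raise AssayInputError("log IC50 must be finite")
    return float(10.0 ** log_ic50)


def fit_dose_response(
    concentrations_uM: Sequence[float], responses: Sequence[float], *, max_nfev: int = 500
) -> DoseResponseFit:
    """Fit the three-parameter logistic to (concentration, response) data.

    Initialisation: Top/Bottom from the response extremes, LogIC50 from the
    concentration whose response is nearest their midpoint.  Standard errors
    are the square roots of the diagonal of the Gauss–Newton covariance
    (residual-variance-scaled) at the optimum.  The parameterisation permits
    either orientation (Top < Bottom fits stimulation-shaped data).
    """
    conc = np.asarray(concentrations_uM, dtype=float)
    y = np.asarray(responses, dtype=float)
    if conc.shape != y.shape:
        raise AssayInputError("concentrations and responses must have equal length")
    if np.any(conc <= 0):
        raise AssayInputError("concentrations must be positive")
    if not np.all(np.isfinite(y)):
        raise AssayInputError("responses must be finite")
    if len(np.unique(conc)) < 4:
        raise AssayInputError("need at least 4 distinct concentrations")
    x = np.log10(conc)

    top0 = float(y[np.argmin(x)])  # low-concentration plateau
    bottom0 = float(y[np.argmax(x)])
    if top0 == bottom0:
        top0, bottom0 = float(np.max(y)), float(np.min(y))
    mid = (top0 + bottom0) / 2
    log_ic50_0 = float(x[np.argmin(np.abs(y - mid))])
    p0 = np.array([top0, bottom0, log_ic50_0])

    def residuals(p):
        return three_param_logistic(x, *p) - y

    result = optimize.least_squares(
        residuals, p0, method="lm", max_nfev=max_nfev, xtol=1e-10, ftol=1e-10, gtol=1e-10
    )
    if not result.success:
        raise FitError(
            "dose-response fit did not converge", best_params=result.x, diagnostics=result.message
        )
    p = result.x
    dof = max(len(y) - 3, 1)
    s2 = float(2 * result.cost) / dof  # cost = 0.5·SS
    jtj = result.jac.T @ result.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    return DoseResponseFit(
        top=float(p[0]),
        bottom=float(p[1]),
        log_ic50=float(p[2]),
        se_top=float(se[0]),
        se_bottom=float(se[1]),
        se_log_ic50=float(se[2]),
        n_points=len(y),
        residual_ss=float(2 * result.cost),
    )


# --------------------------------------------------------------------------
# vanadate-sensitive ATPase activity
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AtpaseMeasurement:
    """One ATPase condition: absorbance (740 nm) plus its standard curve."""

    absorbance: float
    time_min: float
    protein_mg: float
    vanadate: bool
    standards_absorbance: tuple[float, ...]
    standards_nmol: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.time_min <= 0 or self.protein_mg <= 0:
            raise AssayInputError("reaction time and protein amount must be positive")
        if len(self.standards_absorbance) < 2 or len(self.standards_absorbance) != len(self.standards_nmol):
            raise AssayInputError("standard curve needs >= 2 (absorbance, nmol) points")


def _standard_curve(meas: AtpaseMeasurement) -> tuple[float, float]:
    """Least-squares absorbance = intercept + slope·nmol; slope must be > 0."""
    res = stats.linregress(meas.standards_nmol, meas.standards_absorbance)
    if res.slope <= 0:
        raise AssayInputError("phosphate standard curve has non-positive slope")
    return float(res.slope), float(res.intercept)


def _specific_activity(meas: AtpaseMeasurement) -> float:
    slope, intercept = _standard_curve(meas)
    nmol = (meas.absorbance - intercept) / slope
    return nmol / (meas.time_min * meas.protein_mg)


def sensitive_atpase_activity(
    test: AtpaseMeasurement, vanadate_ref: AtpaseMeasurement
) -> float:
    """Vanadate-sensitive ATPase activity in nmol Pi/min/mg.

    Each absorbance converts to nmol phosphate through the shared standard
    curve and normalises by reaction time and protein; the activity measured
    in the presence of vanadate is subtracted.  Negative results are
    reported as-is with a warning.
    """
    if not vanadate_ref.vanadate:
        raise AssayInputError("reference measurement must be the vanadate condition")
    if test.standards_absorbance != vanadate_ref.standards_absorbance or (
        test.standards_nmol != vanadate_ref.standards_nmol
    ):
        raise AssayInputError("test and reference must share a standard curve")
    activity = _specific_activity(test) - _specific_activity(vanadate_ref)
    if activity < 0:
        warnings.warn("vanadate-sensitive activity is negative")
    return float(activity)
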