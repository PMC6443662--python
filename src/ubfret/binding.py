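"""Exact binding-isotherm fitting for FRET-species population shifts.

A labeled species at fixed (picomolar) concentration ``C_diUb`` is titrated
with an unlabeled partner at concentration ``C_partner``.  The enrichment of
a particular FRET species, in percentage points, follows the exact
(ligand-depletion) two-state binding isotherm

    ΔP(C) = P_max * (S - sqrt(S^2 - 4*C_partner*C_diUb)) / (2*C_diUb),
    S = C_partner + C_diUb + K_D

i.e. ΔP is P_max times the bound fraction of the labeled species.  When
C_diUb << K_D this literal form suffers catastrophic cancellation, so the
implementation evaluates the algebraically identical

    ΔP(C) = P_max * 2*C_partner / (S + sqrt(S^2 - 4*C_partner*C_diUb))

which is well-conditioned everywhere.  :func:`fit_kd` estimates (K_D, P_max)
by nonlinear least squares with asymptotic standard errors.

Competition experiments are summarised arithmetically: an enrichment of the
monitored species by ``e`` points that is knocked back down by ``d`` points
corresponds to 100*d/e percent inhibition of the bound labeled species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .units import parse_concentration

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "isotherm",
    "isotherm_literal",
    "fit_kd",
    "calibrate_pmax",
    "percent_inhibition",
    "fold_change",
    "predict_population",
]


@dataclass
class TitrationSeries:
    """Partner concentration vs FRET-species population change.

    ``c_partner`` in molar, ``delta_p`` in percentage points relative to the
    partner-free baseline.  Replicate measurements appear as repeated
    concentrations.  ``c_diub`` is the labeled-species concentration
    (typically 150 pM).
    """

    c_partner: np.ndarray
    delta_p: np.ndarray
    c_diub: float
    baseline_population: float = 0.0
    delta_p_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.c_partner = np.asarray(self.c_partner, dtype=float)
        self.delta_p = np.asarray(self.delta_p, dtype=float)
        if self.c_partner.shape != self.delta_p.shape:
            raise ValueError("c_partner and delta_p must have matching shapes")
        if np.any(self.c_partner < 0):
            raise ValueError("partner concentrations must be nonnegative")
        if not self.c_diub > 0:
            raise ValueError("c_diub must be positive")
        if not np.all(np.isfinite(self.delta_p)):
            raise ValueError("delta_p contains non-finite values")

    def __len__(self) -> int:
        return int(self.c_partner.size)


@dataclass(frozen=True)
class BindingFit:
    """Least-squares isotherm fit: best values ± asymptotic 1-SD errors."""

    kd: float
    kd_err: float
    p_max: float
    p_max_err: float
    residual_sum: float
    covariance_available: bool = True


def isotherm(c_partner, c_diub: float, kd: float, p_max: float):
    """Population change ΔP (same units as ``p_max``) at partner
    concentration ``c_partner`` (molar; scalar or array).

    Uses the rationalised quadratic root, stable when c_diub << kd.
    """
    c = np.asarray(c_partner, dtype=float)
    if np.any(c < 0):
        raise ValueError("c_partner must be nonnegative")
    if not c_diub > 0:
        raise ValueError("c_diub must be positive")
    if kd < 0 or p_max < 0:
        raise ValueError("kd and p_max must be nonnegative")
    s = c + c_diub + kd
    disc = s * s - 4.0 * c * c_diub
    dp = p_max * 2.0 * c / (s + np.sqrt(disc))
    return float(dp) if np.isscalar(c_partner) or c.ndim == 0 else dp


def isotherm_literal(c_partner, c_diub: float, kd: float, p_max: float):
    """The textbook form ``P_max*(S - sqrt(S² - 4*C*C_diUb))/(2*C_diUb)``.

    Mathematically identical to :func:`isotherm`; kept for cross-checking
    because it loses precision when ``c_diub`` is far below ``kd``.
    """
    c = np.asarray(c_partner, dtype=float)
    s = c + c_diub + kd
    dp = p_max * (s - np.sqrt(s * s - 4.0 * c * c_diub)) / (2.0 * c_diub)
    return float(dp) if np.isscalar(c_partner) or c.ndim == 0 else dp


def fit_kd(
    series: TitrationSeries,
    init_kd: float | None = None,
    init_pmax: float | None = None,
) -> BindingFit:
    """Fit (K_D, P_max) to a titration series by nonlinear least squares.

    Positivity is enforced by optimising in log-parameters; the reported
    errors are asymptotic 1-SD values propagated back to the linear scale
    (delta method).  Requires at least three distinct concentrations.
    """
    c, dp = series.c_partner, series.delta_p
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct concentrations to fit")
    if np.max(np.abs(dp)) < 1e-12:
        raise ValueError("delta_p is identically zero; nothing to fit (p_max ≈ 0)")
    if init_kd is None:
        positive = c[c > 0]
        init_kd = float(np.median(positive)) if positive.size else 1e-9
    if init_pmax is None:
        init_pmax = float(np.max(dp))
        if init_pmax <= 0:
            init_pmax = 1.0

    def model(conc, log_kd, log_pmax):
        return isotherm(conc, series.c_diub, np.exp(log_kd), np.exp(log_pmax))

    p0 = [np.log(init_kd), np.log(init_pmax)]
    cov_ok = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(model, c, dp, p0=p0, maxfev=20000)
    kd, p_max = float(np.exp(popt[0])), float(np.exp(popt[1]))
    if not np.all(np.isfinite(pcov)):
        cov_ok = False
        kd_err = p_max_err = float("nan")
    else:
        # var(log x) -> var(x) by delta method: sd(x) = x * sd(log x)
        kd_err = kd * float(np.sqrt(pcov[0, 0]))
        p_max_err = p_max * float(np.sqrt(pcov[1, 1]))
    resid = dp - isotherm(c, series.c_diub, kd, p_max)
    return BindingFit(
        kd=kd,
        kd_err=kd_err,
        p_max=p_max,
        p_max_err=p_max_err,
        residual_sum=float(np.sum(resid ** 2)),
        covariance_available=cov_ok,
    )


def calibrate_pmax(kd: float, c_diub: float, c_ref, delta_p_ref: float) -> float:
    """P_max implied by one known on-curve point ΔP(c_ref) = delta_p_ref.

    Used when a saturation plateau was never reached experimentally but one
    (concentration, enrichment) pair is known.  Concentrations accept unit
    strings (e.g. ``"100nM"``).
    """
    c_ref = parse_concentration(c_ref)
    unit_dp = isotherm(c_ref, c_diub, kd, 1.0)
    if unit_dp <= 0:
        raise ValueError("reference point is at zero bound fraction")
    return float(delta_p_ref) / unit_dp


def percent_inhibition(enrichment: float, decrease: float) -> float:
    """Percent inhibition of the bound labeled species by a competitor.

    ``enrichment`` is the partner-induced population increase (percentage
    points); ``decrease`` is how much of it the competitor removed.  A
    decrease slightly exceeding the enrichment (replicate noise) is clipped
    to 100% with a warning.
    """
    if enrichment <= 0:
        raise ValueError("enrichment must be positive")
    if decrease < 0:
        raise ValueError("decrease must be nonnegative")
    if decrease > enrichment:
        warnings.warn(
            f"decrease {decrease} exceeds enrichment {enrichment}; clipping to 100%",
            stacklevel=2,
        )
        decrease = enrichment
    return 100.0 * decrease / enrichment


def fold_change(kd_a: float, kd_b: float) -> float:
    """Affinity ratio K_D(a)/K_D(b); >1 means ``a`` binds more weakly."""
    if kd_a <= 0 or kd_b <= 0:
        raise ValueError("dissociation constants must be positive")
    return kd_a / kd_b


def predict_population(
    baseline: float,
    kd: float,
    p_max: float,
    c_partner,
    c_diub: float,
) -> float:
    """Absolute species population (%) at a partner concentration:
    baseline + ΔP from the isotherm."""
    return float(baseline) + isotherm(parse_concentration(c_partner), c_diub, kd, p_max)
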