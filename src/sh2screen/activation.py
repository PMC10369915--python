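"""Phosphopeptide-stimulated phosphatase activation analysis.

Full-length SHP2 is autoinhibited; binding of a phosphopeptide to the
N-SH2 domain relieves the inhibition, so initial catalytic rate rises
hyperbolically with activator concentration. Each curve is fit with

    rate(c) = basal + (max − basal) · cⁿ / (EC50ⁿ + cⁿ)

with the Hill coefficient n fixed to 1 by default. The basal rate is a
fitted parameter, so zero-activator points inform it rather than being
subtracted. EC50 values are related to N-SH2 binding affinity by Pearson
correlation of log10(EC50) against log10(Kd); basal catalytic-efficiency
comparisons between enzyme variants are plain kcat/Km ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .library_io import ComputationError, ValidationError

__all__ = [
    "ActivationDataset",
    "ActivationFit",
    "CorrelationReport",
    "fit_activation",
    "kd_ec50_correlation",
    "catalytic_fold",
]


@dataclass
class ActivationDataset:
    """Initial rates versus activating-peptide concentration (µM)."""

    peptide_label: str
    concentrations: np.ndarray
    rates: np.ndarray
    enzyme_label: str = "SHP2"
    replicate: str = "rep1"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.concentrations.shape != self.rates.shape:
            raise ValidationError("concentrations and rates differ in length")
        if np.any(self.concentrations < 0):
            raise ValidationError("concentrations must be non-negative")


@dataclass
class ActivationFit:
    """Fitted half-maximal activation constant and rate endpoints."""

    ec50: float  # µM
    rate_basal: float
    rate_max: float
    hill: float
    se_ec50: float
    se_rate_basal: float
    se_rate_max: float
    rss: float
    converged: bool
    no_transition: bool = False


@dataclass
class CorrelationReport:
    """Pearson correlation of log10-transformed (Kd, EC50) pairs."""

    r: float  # NaN when undefined (zero variance)
    p_value: float
    slope: float
    intercept: float
    n: int
    defined: bool


def _hill_rate(c, ec50, basal, maximum, n):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(c > 0, c**n / (ec50**n + c**n), 0.0)
    return basal + (maximum - basal) * x


def fit_activation(ds: ActivationDataset, hill: bool = False) -> ActivationFit:
    """Least-squares fit of the saturating activation curve.

    With ``hill=False`` (default) the Hill coefficient is fixed at 1.
    EC50 is log-parameterized with 3 optimizer starts. Degenerate inputs
    (a single distinct concentration, e.g. all zero) return a
    no-transition flag instead of a fit.
    """
    conc, y = ds.concentrations, ds.rates
    n_params = 4 if hill else 3
    if len(conc) < n_params + 1:
        raise ValidationError(
            f"need at least {n_params + 1} points to fit {n_params} parameters"
        )
    if np.unique(conc).size < 2 or not np.any(conc > 0):
        return ActivationFit(
            ec50=math.nan, rate_basal=float(np.mean(y)),
            rate_max=float(np.mean(y)), hill=1.0,
            se_ec50=math.nan, se_rate_basal=math.nan, se_rate_max=math.nan,
            rss=float(np.sum((y - np.mean(y)) ** 2)),
            converged=False, no_transition=True,
        )
    pos = conc[conc > 0]
    # standardize the rate axis: makes the fit (and hence EC50) exactly
    # invariant to affine rescaling of the rates, which basal/max absorb
    y_shift = float(np.mean(y))
    y_scale = float(np.std(y)) or 1.0
    y_std = (y - y_shift) / y_scale
    lo, hi = float(np.min(y_std)), float(np.max(y_std))

    def residual(x):
        if hill:
            log_ec50, basal, maximum, log_n = x
            n = math.exp(log_n)
        else:
            log_ec50, basal, maximum = x
            n = 1.0
        return _hill_rate(conc, math.exp(log_ec50), basal, maximum, n) - y_std

    starts = []
    for g in (np.median(pos), pos.min(), pos.max()):
        x0 = [math.log(g), lo, hi] + ([0.0] if hill else [])
        starts.append(np.array(x0))
    lb = [math.log(pos.min()) - 16.0, -np.inf, -np.inf] + (
        [math.log(0.1)] if hill else []
    )
    ub = [math.log(pos.max()) + 16.0, np.inf, np.inf] + (
        [math.log(10.0)] if hill else []
    )
    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(
                residual, x0, bounds=(lb, ub),
                ftol=1e-15, xtol=1e-15, gtol=1e-15,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ComputationError("all optimizer starts failed")
    # Gauss-Newton polish with the analytic Jacobian: drives the
    # gradient to machine zero so the reported optimum does not depend
    # on the trust-region stopping point
    def jacobian(x):
        log_ec50, _, _ = x[:3]
        n = math.exp(x[3]) if hill else 1.0
        ec50 = math.exp(log_ec50)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(conc > 0, conc**n / (ec50**n + conc**n), 0.0)
        amp = x[2] - x[1]
        cols = [
            -amp * n * frac * (1.0 - frac),  # d/d log_ec50
            1.0 - frac,                      # d/d basal
            frac,                            # d/d max
        ]
        if hill:
            with np.errstate(divide="ignore", invalid="ignore"):
                dlog = np.where(conc > 0, np.log(conc / ec50), 0.0)
            cols.append(amp * n * frac * (1.0 - frac) * dlog)  # d/d log_n
        return np.column_stack(cols)

    x = best.x.copy()
    cost = 2.0 * best.cost
    for _ in range(50):
        r = residual(x)
        try:
            step = np.linalg.lstsq(jacobian(x), -r, rcond=None)[0]
        except np.linalg.LinAlgError:
            break
        x_new = np.clip(x + step, lb, ub)
        cost_new = float(residual(x_new) @ residual(x_new))
        if not np.isfinite(cost_new) or cost_new > cost * (1 + 1e-14):
            break
        moved = np.max(np.abs(x_new - x))
        x, cost = x_new, cost_new
        if moved < 1e-14:
            break

    from types import SimpleNamespace

    best = SimpleNamespace(x=x, cost=0.5 * cost, jac=jacobian(x),
                           success=best.success)

    log_ec50, basal_std, max_std = best.x[:3]
    n_hill = math.exp(best.x[3]) if hill else 1.0
    ec50 = math.exp(log_ec50)
    basal = basal_std * y_scale + y_shift
    maximum = max_std * y_scale + y_shift
    dof = max(len(conc) - n_params, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = np.linalg.pinv(best.jac.T @ best.jac) * s2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(n_params, np.nan)
    amplitude = abs(max_std - basal_std)
    converged = bool(
        best.success
        and amplitude > 1e-6 * max(1.0, abs(basal_std), abs(max_std))
    )
    return ActivationFit(
        ec50=ec50,
        rate_basal=float(basal),
        rate_max=float(maximum),
        hill=float(n_hill),
        se_ec50=float(ec50 * se[0]),
        se_rate_basal=float(se[1] * y_scale),
        se_rate_max=float(se[2] * y_scale),
        rss=float(2.0 * best.cost * y_scale**2),
        converged=converged,
        no_transition=not converged and amplitude <= 1e-6,
    )


def kd_ec50_correlation(pairs) -> CorrelationReport:
    """Pearson r of log10(EC50) against log10(Kd), with the log-log fit.

    Requires at least 3 strictly positive pairs. When either axis has
    zero variance the correlation is undefined and reported as such
    (``r = NaN, defined = False``).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValidationError("need at least 3 (Kd, EC50) pairs")
    if np.any(arr <= 0):
        raise ValidationError("Kd and EC50 values must be strictly positive")
    log_kd = np.log10(arr[:, 0])
    log_ec50 = np.log10(arr[:, 1])
    if np.ptp(log_kd) == 0 or np.ptp(log_ec50) == 0:
        return CorrelationReport(
            r=math.nan, p_value=math.nan, slope=math.nan,
            intercept=math.nan, n=len(arr), defined=False,
        )
    lin = stats.linregress(log_kd, log_ec50)
    return CorrelationReport(
        r=float(lin.rvalue),
        p_value=float(lin.pvalue),
        slope=float(lin.slope),
        intercept=float(lin.intercept),
        n=len(arr),
        defined=True,
    )


def catalytic_fold(eff_variant: float, eff_wt: float) -> float:
    """Fold-change in basal catalytic efficiency, kcat/Km ratio."""
    if eff_variant <= 0 or eff_wt <= 0:
        raise ValidationError("catalytic efficiencies must be positive")
    return eff_variant / eff_wt
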