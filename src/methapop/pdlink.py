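"""Effect-compartment PK/PD link and inhibitory sigmoid-Emax withdrawal model.

Plasma concentration drives a hypothetical effect site via
dCe/dt = ke0 (Cp - Ce); the effect-site concentration Ce suppresses the
SOWS withdrawal score through

    E = E0 * [1 - Emax * Ce^n / (Ce^n + EC50^n)]

where Emax is the maximal fractional suppression (0-1, displayed x100 as %),
EC50 the effect-site concentration at half-maximal suppression, and n the
sigmoidicity.  The lag between Cp and Ce produces a hysteresis loop in the
concentration-effect plane; with the effect expressed as withdrawal
suppression E0 - E the loop runs counter-clockwise, collapsing as ke0 grows.

The population analysis is two-stage: each subject's PD parameters are fit
by bounded least squares conditional on that subject's PK parameters, and
the subject-level estimates are then summarized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .pk import DoseRegimen, PKParameters, disposition_terms, _NG_PER_ML_PER_MG_PER_L
from .stats import SummaryStats, summarize

__all__ = [
    "PDParameters",
    "EffectPrediction",
    "PDFitResult",
    "ce_steady_state",
    "sows_effect",
    "effect_steady_state",
    "hysteresis_loop_area",
    "suppression_loop_area",
    "fit_pd_individual",
    "fit_pd_population",
]

logger = logging.getLogger(__name__)

SOWS_MAX = 64.0  # 16 items x 0-4

_COINCIDENCE_RTOL = 1e-8
_PERTURB_RTOL = 1e-6


@dataclass(frozen=True)
class PDParameters:
    """Effect-compartment + inhibitory sigmoid-Emax parameters.

    e0   : baseline SOWS score (points, 0-64)
    emax : maximal fractional suppression of baseline (0-1)
    ec50 : effect-site concentration at half-maximal suppression (ng/ml)
    n    : sigmoidicity factor (>0, default 1)
    ke0  : effect-compartment equilibration rate (1/h)
    """

    e0: float
    emax: float
    ec50: float
    n: float = 1.0
    ke0: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.e0 <= SOWS_MAX:
            raise ValueError(f"e0 must lie in [0, {SOWS_MAX}], got {self.e0}")
        if not 0.0 <= self.emax <= 1.0:
            raise ValueError(f"emax must lie in [0, 1], got {self.emax}")
        if not self.ec50 > 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if not self.n > 0:
            raise ValueError(f"n must be > 0, got {self.n}")
        if not self.ke0 > 0:
            raise ValueError(f"ke0 must be > 0, got {self.ke0}")


@dataclass(frozen=True)
class EffectPrediction:
    """Model-predicted effect-site concentration and SOWS score over time."""

    time: np.ndarray
    ce: np.ndarray
    e: np.ndarray


@dataclass(frozen=True)
class PDFitResult:
    """A subject-level two-stage PD fit.

    `identified` is False when the optimizer pinned EC50 at a search bound or
    drove Emax to 1, i.e. the subject's data do not identify the
    concentration-effect relationship; such subjects are excluded from the
    population EC50/Emax summary.
    """

    params: PDParameters
    success: bool
    identified: bool
    sse: float
    n_obs: int


def ce_steady_state(p: PKParameters, ke0: float, r: DoseRegimen, t) -> np.ndarray | float:
    """Steady-state effect-site concentration (ng/ml) at t hours post dose.

    Closed form: each plasma exponential term is convolved with the ke0
    equilibration kernel, adding a ke0-exponential of its own, and every term
    is accumulated by its geometric factor over past doses.  Periodic in tau.
    """
    if not ke0 > 0:
        raise ValueError(f"ke0 must be > 0, got {ke0}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    lam, coef = disposition_terms(p)
    if np.any(np.abs(ke0 - lam) < _COINCIDENCE_RTOL * np.max(lam)):
        ke0 = ke0 * (1.0 + _PERTURB_RTOL)
    b = coef * ke0 / (ke0 - lam)
    lam_all = np.append(lam, ke0)
    coef_all = np.append(b, -np.sum(b))
    tr = np.mod(t, r.tau)
    acc = coef_all / -np.expm1(-lam_all * r.tau)
    c = (r.dose / p.v_f) * np.exp(-np.outer(tr, lam_all)) @ acc
    out = _NG_PER_ML_PER_MG_PER_L * c
    return out if out.ndim else float(out)


def sows_effect(pd: PDParameters, ce) -> np.ndarray | float:
    """SOWS score E = E0 [1 - Emax Ce^n / (Ce^n + EC50^n)]; monotone in ce."""
    ce = np.asarray(ce, dtype=float)
    if np.any(ce < 0):
        raise ValueError("ce must be >= 0")
    cen = np.power(ce, pd.n)
    e = pd.e0 * (1.0 - pd.emax * cen / (cen + pd.ec50**pd.n))
    return e if e.ndim else float(e)


def effect_steady_state(
    p: PKParameters, pd: PDParameters, r: DoseRegimen, t
) -> EffectPrediction:
    """Joint effect-site and SOWS prediction on a time grid at steady state."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    ce = np.atleast_1d(ce_steady_state(p, pd.ke0, r, t))
    return EffectPrediction(time=t, ce=ce, e=np.atleast_1d(sows_effect(pd, ce)))


def hysteresis_loop_area(times, x, y) -> float:
    """Signed shoelace area of the closed (x, y) trajectory; + = counter-clockwise.

    Points must be in increasing time order and span one loop traversal; the
    polygon is closed by joining the last point back to the first.
    """
    times = np.asarray(times, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (times.shape == x.shape == y.shape):
        raise ValueError("times, x, y must have equal lengths")
    if times.size < 4:
        raise ValueError("need at least 4 points to form a loop")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    x2 = np.append(x, x[0])
    y2 = np.append(y, y[0])
    return float(0.5 * np.sum(x2[:-1] * y2[1:] - x2[1:] * y2[:-1]))


def suppression_loop_area(times, cp, sows, e0: float) -> float:
    """Hysteresis area of plasma concentration vs withdrawal suppression e0 - SOWS.

    A positive (counter-clockwise) area indicates the effect lags the plasma
    concentration, the signature of effect-compartment equilibration delay.
    """
    sows = np.asarray(sows, dtype=float)
    return hysteresis_loop_area(times, cp, e0 - sows)


def _pd_residuals(theta, ce, sows, base: PDParameters, fit_ke0, ce_builder):
    e0, emax, log_ec50 = theta[:3]
    pd = replace(base, e0=e0, emax=emax, ec50=float(np.exp(log_ec50)))
    if fit_ke0:
        pd = replace(pd, ke0=float(np.exp(theta[3])))
        ce = ce_builder(pd.ke0)
    return sows_effect(pd, ce) - sows


def fit_pd_individual(
    ce_builder,
    times,
    sows,
    init: PDParameters,
    *,
    fit_ke0: bool = False,
    ec50_bounds: tuple[float, float] = (10.0, 5000.0),
) -> PDFitResult:
    """Least-squares fit of (e0, emax, ec50) to one subject's SOWS series.

    ce_builder(ke0) must return effect-site concentrations at `times` for the
    subject's (MAP or true) PK parameters; with `fit_ke0` False (default) it
    is evaluated once at init.ke0 and ke0 is held fixed, as is n.  Residuals
    are unweighted (additive error on the bounded integer score).  Multi-start
    over coarse (emax, ec50) grid; best SSE wins.
    """
    times = np.asarray(times, dtype=float)
    sows = np.asarray(sows, dtype=float)
    if times.size < 4:
        raise ValueError("need at least 4 SOWS observations")
    ce = np.atleast_1d(ce_builder(init.ke0))

    lo = [0.0, 0.0, np.log(ec50_bounds[0])]
    hi = [SOWS_MAX, 1.0, np.log(ec50_bounds[1])]
    starts = [[init.e0, init.emax, np.log(init.ec50)]]
    e0_start = float(np.clip(np.max(sows), 1.0, SOWS_MAX))
    for emax0 in (0.2, 0.5):
        for ec50_0 in (100.0, 400.0, 1500.0):
            starts.append([e0_start, emax0, np.log(ec50_0)])
    if fit_ke0:
        lo.append(np.log(1e-3))
        hi.append(np.log(1e3))
        starts = [s + [np.log(init.ke0)] for s in starts]

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(
                _pd_residuals,
                x0,
                bounds=(lo, hi),
                args=(ce, sows, init, fit_ke0, ce_builder),
                method="trf",
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        logger.warning("PD fit failed for all starts")
        return PDFitResult(init, success=False, identified=False, sse=np.inf, n_obs=times.size)

    e0, emax, log_ec50 = best.x[:3]
    ec50 = float(np.exp(log_ec50))
    params = replace(init, e0=float(e0), emax=float(emax), ec50=ec50)
    if fit_ke0:
        params = replace(params, ke0=float(np.exp(best.x[3])))
    log_lo, log_hi = np.log(ec50_bounds)
    at_bound = (
        log_ec50 - log_lo < 1e-3 or log_hi - log_ec50 < 1e-3 or emax > 0.999
    )
    return PDFitResult(
        params,
        success=True,
        identified=not at_bound,
        sse=float(2.0 * best.cost),
        n_obs=times.size,
    )


def fit_pd_population(fits: list[PDFitResult]) -> dict[str, SummaryStats]:
    """Summarize subject-level PD fits into the population parameter table.

    Returns mean/SD/95% CI/min/max/fold-change blocks for EC50 (ng/ml) and
    Emax (%, fraction x 100), computed over the identified subject fits,
    plus the baseline score E0 over all successful fits.
    """
    ok = [f for f in fits if f.success]
    ident = [f for f in ok if f.identified]
    if len(ident) < 2:
        raise ValueError("need at least 2 identified subject fits")
    n_dropped = len(fits) - len(ident)
    if n_dropped:
        logger.warning("%d of %d subject PD fits excluded from summary", n_dropped, len(fits))
    return {
        "ec50": summarize([f.params.ec50 for f in ident]),
        "emax_pct": summarize([100.0 * f.params.emax for f in ident]),
        "e0": summarize([f.params.e0 for f in ok]),
    }
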