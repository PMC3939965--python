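"""Closed-form linear compartmental pharmacokinetics at multiple-dose steady state.

One- and two-compartment disposition with first-order oral absorption,
parameterized by apparent clearance/volume (CL/F, V/F) and micro rate
constants (k12, k21, ka).  Concentrations are predicted for a repeating
once-daily (or arbitrary tau) regimen by accumulating each exponential term
of the single-dose solution with its geometric factor 1/(1 - exp(-lambda*tau)).

Unit convention (fixed throughout the package): dose in mg, volumes in L,
times in h; mg/L predictions are converted once to ng/ml at output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DoseRegimen",
    "PKParameters",
    "MacroDisposition",
    "micro_to_macro",
    "disposition_terms",
    "conc_single_dose",
    "conc_steady_state",
    "halflife_beta",
    "css_average",
]

#: mg/L -> ng/ml
_NG_PER_ML_PER_MG_PER_L = 1000.0

#: relative closeness of ka to a disposition exponent that triggers perturbation
_COINCIDENCE_RTOL = 1e-8
#: relative perturbation applied to ka (or ke0) on exponent coincidence
_PERTURB_RTOL = 1e-6


@dataclass(frozen=True)
class DoseRegimen:
    """A repeated oral dose: `dose` mg every `tau` hours (default once daily)."""

    dose: float
    tau: float = 24.0

    def __post_init__(self) -> None:
        if not self.dose >= 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class PKParameters:
    """Micro-constant parameterization of oral methadone disposition.

    cl_f : apparent oral clearance CL/F (L/h)
    v_f  : apparent central volume V/F (L)
    k12, k21 : central<->peripheral first-order transfer rates (1/h);
               both zero for the one-compartment model
    ka   : first-order absorption rate (1/h)
    """

    cl_f: float
    v_f: float
    k12: float
    k21: float
    ka: float

    def __post_init__(self) -> None:
        for name in ("cl_f", "v_f", "ka"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        one_cpt = self.k12 == 0 and self.k21 == 0
        if not one_cpt and not (self.k12 > 0 and self.k21 > 0):
            raise ValueError(
                "k12 and k21 must both be > 0 (two-compartment) or both 0 "
                f"(one-compartment); got k12={self.k12}, k21={self.k21}"
            )

    @property
    def k10(self) -> float:
        """Elimination rate from the central compartment, CL/F / (V/F) (1/h)."""
        return self.cl_f / self.v_f

    @property
    def is_one_compartment(self) -> bool:
        return self.k12 == 0 and self.k21 == 0

    @classmethod
    def one_compartment(cls, cl_f: float, v_f: float, ka: float) -> "PKParameters":
        return cls(cl_f=cl_f, v_f=v_f, k12=0.0, k21=0.0, ka=ka)


@dataclass(frozen=True)
class MacroDisposition:
    """Disposition exponents and single-dose exponential coefficients.

    The oral single-dose central concentration is

        C(t) = (dose / v_f) * sum_i coeffs[i] * exp(-lambdas[i] * t)   (mg/L)

    with dimensionless coeffs summing to zero (C(0) = 0, no IV component).
    alpha >= beta are the disposition roots; for a one-compartment model
    alpha == beta == k10.
    """

    alpha: float
    beta: float
    lambdas: tuple[float, ...]
    coeffs: tuple[float, ...]


def _effective_ka(ka: float, exponents: tuple[float, ...], scale: float) -> float:
    """Nudge ka away from an exponent coincidence (measure-zero degeneracy)."""
    if any(abs(ka - lam) < _COINCIDENCE_RTOL * scale for lam in exponents):
        return ka * (1.0 + _PERTURB_RTOL)
    return ka


def micro_to_macro(p: PKParameters) -> MacroDisposition:
    """Macro-constants from micro-constants.

    alpha, beta are the roots of lambda^2 - (k10+k12+k21) lambda + k10*k21 = 0
    (alpha >= beta).  Computed with the numerically stable form beta =
    product / alpha.  The ka term coefficient follows the standard
    first-order-absorption partial-fraction expansion.
    """
    k10 = p.k10
    if p.is_one_compartment:
        ka = _effective_ka(p.ka, (k10,), k10)
        c = ka / (ka - k10)
        return MacroDisposition(
            alpha=k10, beta=k10, lambdas=(k10, ka), coeffs=(c, -c)
        )

    s = k10 + p.k12 + p.k21
    prod = k10 * p.k21
    disc = s * s - 4.0 * prod
    if disc < 0:  # cannot happen for positive micro-constants; guard roundoff
        disc = 0.0
    alpha = 0.5 * (s + math.sqrt(disc))
    beta = prod / alpha
    ka = _effective_ka(p.ka, (alpha, beta), alpha)

    c_alpha = ka * (p.k21 - alpha) / ((ka - alpha) * (beta - alpha))
    c_beta = ka * (p.k21 - beta) / ((ka - beta) * (alpha - beta))
    c_ka = ka * (p.k21 - ka) / ((alpha - ka) * (beta - ka))
    return MacroDisposition(
        alpha=alpha,
        beta=beta,
        lambdas=(alpha, beta, ka),
        coeffs=(c_alpha, c_beta, c_ka),
    )


def disposition_terms(p: PKParameters) -> tuple[np.ndarray, np.ndarray]:
    """(lambdas, coeffs) arrays of the single-dose exponential expansion."""
    m = micro_to_macro(p)
    return np.asarray(m.lambdas), np.asarray(m.coeffs)


def conc_single_dose(p: PKParameters, dose: float, t) -> np.ndarray | float:
    """Central concentration (ng/ml) at time(s) t (h) after a single oral dose."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    lam, coef = disposition_terms(p)
    c = (dose / p.v_f) * np.exp(-np.outer(t, lam)) @ coef
    out = _NG_PER_ML_PER_MG_PER_L * c
    return out if out.ndim else float(out)


def conc_steady_state(p: PKParameters, r: DoseRegimen, t) -> np.ndarray | float:
    """Steady-state central concentration (ng/ml) at t hours after a dose.

    Times are reduced modulo tau, so the pre-dose trough can be queried at
    t = 0 or t = tau interchangeably (the profile is tau-periodic).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    tr = np.mod(t, r.tau)
    lam, coef = disposition_terms(p)
    acc = coef / -np.expm1(-lam * r.tau)  # geometric accumulation per exponential
    c = (r.dose / p.v_f) * np.exp(-np.outer(tr, lam)) @ acc
    out = _NG_PER_ML_PER_MG_PER_L * c
    return out if out.ndim else float(out)


def halflife_beta(m: MacroDisposition) -> float:
    """Terminal (beta-phase) half-life ln2/beta in hours."""
    if not m.beta > 0:
        raise ValueError("beta must be > 0")
    return math.log(2.0) / m.beta


def css_average(p: PKParameters, r: DoseRegimen) -> float:
    """Interval-average steady-state concentration dose/(CL/F * tau), ng/ml."""
    return _NG_PER_ML_PER_MG_PER_L * r.dose / (p.cl_f * r.tau)
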