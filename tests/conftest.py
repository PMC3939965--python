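"""Shared fixtures: reference parameter sets and ODE oracles.

The ODE oracles integrate the absorption/central/peripheral(/effect) system
with scipy and serve as the independent check on every closed-form solution.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from methapop import DoseRegimen, PKParameters

#: published population-mean PK parameters (CL/F L/h, V/F L, rates 1/h)
POP_PK_MEANS = {"cl_f": 8.39, "v_f": 131.10, "k12": 0.57, "k21": 0.25, "ka": 0.43}
POP_PK_SDS = {"cl_f": 3.62, "v_f": 28.41, "k12": 0.04, "k21": 0.05, "ka": 0.08}

#: published population PD parameters: EC50 ng/ml, Emax as a fraction
POP_PD_MEANS = {"ec50": 413.47, "emax": 0.3198}


@pytest.fixture(scope="session")
def pop_mean_params() -> PKParameters:
    return PKParameters(**POP_PK_MEANS)


@pytest.fixture(scope="session")
def regimen60() -> DoseRegimen:
    return DoseRegimen(dose=60.0, tau=24.0)


def ode_profiles(p: PKParameters, regimen: DoseRegimen, times, ke0: float | None = None,
                 n_intervals: int = 40, rtol: float = 1e-10, atol: float = 1e-12):
    """Reference (Cp, Ce) at `times` h post dose at steady state, by ODE.

    Integrates depot/central/peripheral (+ optional effect compartment)
    through `n_intervals` repeated doses, then reads the final interval.
    """
    k10 = p.k10
    ke = ke0 if ke0 is not None else 0.0

    def rhs(t, x):
        a, c1, c2, ce = x
        return [
            -p.ka * a,
            p.ka * a - (k10 + p.k12) * c1 + p.k21 * c2,
            p.k12 * c1 - p.k21 * c2,
            ke * (1000.0 * c1 / p.v_f - ce),
        ]

    x = np.zeros(4)
    for _ in range(n_intervals):
        x[0] += regimen.dose
        sol = solve_ivp(rhs, (0.0, regimen.tau), x, rtol=rtol, atol=atol)
        x = sol.y[:, -1]
    x[0] += regimen.dose
    times = np.asarray(times, dtype=float)
    sol = solve_ivp(rhs, (0.0, regimen.tau), x, rtol=rtol, atol=atol,
                    dense_output=True)
    states = sol.sol(np.clip(times, 0.0, regimen.tau))
    cp = 1000.0 * states[1] / p.v_f
    ce = states[3]
    return cp, ce


def ode_single_dose(p: PKParameters, dose: float, times, rtol=1e-10, atol=1e-12):
    """Single oral dose central concentration (ng/ml) by ODE integration."""
    k10 = p.k10

    def rhs(t, x):
        a, c1, c2 = x
        return [
            -p.ka * a,
            p.ka * a - (k10 + p.k12) * c1 + p.k21 * c2,
            p.k12 * c1 - p.k21 * c2,
        ]

    times = np.asarray(times, dtype=float)
    sol = solve_ivp(rhs, (0.0, float(times.max()) if times.size else 1.0),
                    [dose, 0.0, 0.0], rtol=rtol, atol=atol, dense_output=True)
    return 1000.0 * sol.sol(times)[1] / p.v_f


def random_pk_params(rng: np.random.Generator) -> PKParameters:
    """A random plausible two-compartment parameter set for oracle sweeps."""
    return PKParameters(
        cl_f=float(rng.uniform(2.0, 20.0)),
        v_f=float(rng.uniform(60.0, 250.0)),
        k12=float(rng.uniform(0.05, 1.2)),
        k21=float(rng.uniform(0.05, 0.8)),
        ka=float(rng.uniform(0.2, 1.5)),
    )
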