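"""Nonlinear mixed-effects estimation of population PK by MAP-EM.

Individual log-parameters carry normal random effects (diagonal covariance
Omega) around log-scale population means, i.e. log-normal inter-subject
variability, with a proportional (1/prediction^2 weighted) residual error of
variance sigma^2.  A sparse steady-state design cannot inform a random
effect on every micro-constant, so the model distinguishes

  random-effect parameters : CL/F, V/F, ka by default — subject-level MAP
      (empirical-Bayes) estimates under the population prior;
  shared parameters        : k12, k21 by default — population fixed effects
      common to all subjects, updated by likelihood-only maximization.

Estimation alternates an E-step (per-subject MAP of the random effects; the
separable subject problems are stacked into one warm-started L-BFGS-B run
with batched model evaluation) with an M-step (means of the MAP estimates;
Omega from their spread plus the posterior-curvature correction diag(H^-1);
shared parameters by pooled likelihood; sigma^2 from weighted residuals with
an effective-degrees-of-freedom correction), until the largest relative
parameter change stays below tolerance for a run of consecutive iterations.
The marginal log-likelihood for AIC model selection is the Laplace
approximation at the MAP estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .dataset import EventDataset
from .pk import PKParameters

__all__ = [
    "STRUCTURAL_PARAMS",
    "PopulationModel",
    "FitConfig",
    "PopulationFit",
    "fit_population",
    "map_individual",
    "model_aic",
    "select_model",
    "weighted_residuals",
]

logger = logging.getLogger(__name__)

LOG2PI = math.log(2.0 * math.pi)

STRUCTURAL_PARAMS = {
    "one_compartment": ("cl_f", "v_f", "ka"),
    "two_compartment": ("cl_f", "v_f", "k12", "k21", "ka"),
}

DEFAULT_RANDOM_EFFECTS = ("cl_f", "v_f", "ka")

#: literature-derived initial estimates shipped as the default preset
DEFAULT_INITIAL = {"cl_f": 8.0, "v_f": 130.0, "k12": 0.5, "k21": 0.25, "ka": 0.4}


@dataclass(frozen=True)
class PopulationModel:
    """Mixed-effects model specification / estimate.

    fixed_effects  : log-scale means, ordered as STRUCTURAL_PARAMS[structural]
    iiv_variances  : diagonal variances of the log-scale random effects
                     (entries for shared parameters are 0)
    sigma2         : proportional residual variance (squared CV)
    random_effects : parameter names carrying inter-subject variability;
                     the rest are fixed effects shared across subjects
    """

    structural: str
    fixed_effects: tuple[float, ...]
    iiv_variances: tuple[float, ...]
    sigma2: float
    random_effects: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.structural not in STRUCTURAL_PARAMS:
            raise ValueError(f"unknown structural model {self.structural!r}")
        names = STRUCTURAL_PARAMS[self.structural]
        d = len(names)
        if len(self.fixed_effects) != d or len(self.iiv_variances) != d:
            raise ValueError(f"expected {d} fixed effects and IIV variances")
        if any(v < 0 for v in self.iiv_variances):
            raise ValueError("IIV variances must be >= 0")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be > 0")
        if self.random_effects is None:
            object.__setattr__(
                self, "random_effects",
                tuple(n for n in names if n in DEFAULT_RANDOM_EFFECTS),
            )
        if any(n not in names for n in self.random_effects):
            raise ValueError("random_effects must be a subset of the structural parameters")

    @property
    def param_names(self) -> tuple[str, ...]:
        return STRUCTURAL_PARAMS[self.structural]

    @property
    def random_idx(self) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.param_names) if n in self.random_effects])

    @property
    def shared_idx(self) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.param_names) if n not in self.random_effects], dtype=int)

    @property
    def n_params(self) -> int:
        """Estimated quantities: all fixed effects + IIV variances + sigma2."""
        return len(self.fixed_effects) + len(self.random_effects) + 1

    def population_parameters(self) -> PKParameters:
        """Population-typical PKParameters (exp of the log-scale means)."""
        return self._to_pk(np.asarray(self.fixed_effects))

    def population_means(self) -> dict[str, float]:
        """Natural-scale population means under log-normal IIV: exp(mu + omega/2)."""
        mu = np.asarray(self.fixed_effects)
        om = np.asarray(self.iiv_variances)
        vals = np.exp(mu + om / 2.0)
        return dict(zip(self.param_names, vals.tolist()))

    def _to_pk(self, theta: np.ndarray) -> PKParameters:
        vals = dict(zip(self.param_names, np.exp(np.asarray(theta)).tolist()))
        if self.structural == "one_compartment":
            return PKParameters.one_compartment(vals["cl_f"], vals["v_f"], vals["ka"])
        return PKParameters(**vals)

    @classmethod
    def default_initial(
        cls, structural: str, iiv: float = 0.2, sigma2: float = 0.04,
        random_effects: tuple[str, ...] | None = None,
    ) -> "PopulationModel":
        names = STRUCTURAL_PARAMS[structural]
        if random_effects is None:
            random_effects = tuple(n for n in names if n in DEFAULT_RANDOM_EFFECTS)
        mu = tuple(math.log(DEFAULT_INITIAL[n]) for n in names)
        om = tuple(iiv if n in random_effects else 0.0 for n in names)
        return cls(structural, mu, om, sigma2, random_effects)


@dataclass(frozen=True)
class FitConfig:
    max_iter: int = 500
    rtol: float = 1e-4
    consecutive: int = 5
    seed: int = 20110601  # jittered restart on stacked-optimizer failure
    omega_floor: float = 1e-8
    sigma2_floor: float = 1e-8
    n_multistart: int = 5


@dataclass
class PopulationFit:
    """Result of a MAP-EM population fit."""

    model: PopulationModel
    individual: dict
    loglik: float
    aic: float
    converged: bool
    n_iter: int
    trace: list = field(default_factory=list)
    excluded_subjects: list = field(default_factory=list)

    @property
    def individual_frame(self) -> pd.DataFrame:
        rows = []
        for subj, p in self.individual.items():
            rows.append({"subject": subj, **{k: getattr(p, k) for k in
                         ("cl_f", "v_f", "k12", "k21", "ka")}})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# batched model evaluation


def _ss_conc_batch(TH: np.ndarray, structural: str, times: np.ndarray,
                   dose: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Steady-state concentrations (ng/ml) for a stack of subjects.

    TH : (n, d) log-parameters; times : (n, m); dose, tau : (n,).
    Same closed form as pk.conc_steady_state, vectorized over subjects.
    """
    P = np.exp(TH)
    if structural == "two_compartment":
        cl, v, k12, k21, ka = P.T
        k10 = cl / v
        s = k10 + k12 + k21
        disc = np.maximum(s * s - 4.0 * k10 * k21, 0.0)
        alpha = 0.5 * (s + np.sqrt(disc))
        beta = k10 * k21 / alpha
        near = np.minimum(np.abs(ka - alpha), np.abs(ka - beta)) < 1e-8 * alpha
        ka = np.where(near, ka * (1.0 + 1e-6), ka)
        lam = np.stack([alpha, beta, ka], axis=1)                      # (n, 3)
        coef = np.stack([
            ka * (k21 - alpha) / ((ka - alpha) * (beta - alpha)),
            ka * (k21 - beta) / ((ka - beta) * (alpha - beta)),
            ka * (k21 - ka) / ((alpha - ka) * (beta - ka)),
        ], axis=1)
        v_col = v
    else:
        cl, v, ka = P.T
        k10 = cl / v
        ka = np.where(np.abs(ka - k10) < 1e-8 * k10, ka * (1.0 + 1e-6), ka)
        c = ka / (ka - k10)
        lam = np.stack([k10, ka], axis=1)
        coef = np.stack([c, -c], axis=1)
        v_col = v
    acc = coef / -np.expm1(-lam * tau[:, None])                        # (n, K)
    tr = np.mod(times, tau[:, None])                                   # (n, m)
    E = np.exp(-tr[:, :, None] * lam[:, None, :])                      # (n, m, K)
    return 1000.0 * (dose / v_col)[:, None] * np.einsum("nmk,nk->nm", E, acc)


@dataclass
class _Stack:
    """Per-subject observation arrays padded to a common width."""

    subjects: list
    times: np.ndarray   # (n, m)
    y: np.ndarray       # (n, m)
    mask: np.ndarray    # (n, m) 1 where observed
    dose: np.ndarray    # (n,)
    tau: np.ndarray     # (n,)

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def nobs(self) -> float:
        return float(self.mask.sum())


def _nll_vec(TH, stack: _Stack, structural, sigma2) -> np.ndarray:
    """Per-subject negative log-likelihood (data terms only), (n,)."""
    F = np.maximum(_ss_conc_batch(TH, structural, stack.times, stack.dose, stack.tau), 1e-12)
    wres2 = ((stack.y - F) / F) ** 2
    return 0.5 * np.sum(
        stack.mask * (wres2 / sigma2 + math.log(sigma2) + 2.0 * np.log(F) + LOG2PI), axis=1
    )


def _nlp_vec(TH, stack, structural, mu, omega, re_idx, sigma2) -> np.ndarray:
    """Per-subject negative log posterior: likelihood + random-effect prior."""
    pr = 0.5 * np.sum(
        (TH[:, re_idx] - mu[re_idx]) ** 2 / omega[re_idx]
        + np.log(omega[re_idx]) + LOG2PI, axis=1,
    )
    return _nll_vec(TH, stack, structural, sigma2) + pr


def _map_step(TH0, stack, structural, mu, omega, re_idx, sigma2, rng, n_multistart):
    """Stacked MAP maximization of the random-effect columns; (n, d) result."""
    n = TH0.shape[0]
    k = re_idx.size
    base = TH0.copy()

    def unpack(x):
        TH = base.copy()
        TH[:, re_idx] = x.reshape(n, k)
        return TH

    def fun(x):
        TH = unpack(x)
        val = float(np.sum(_nlp_vec(TH, stack, structural, mu, omega, re_idx, sigma2)))
        G = np.empty((n, k))
        for j, col in enumerate(re_idx):
            h = 1e-6 * (1.0 + np.abs(TH[:, col]))
            TP = TH.copy(); TP[:, col] += h
            TM = TH.copy(); TM[:, col] -= h
            fp = _nlp_vec(TP, stack, structural, mu, omega, re_idx, sigma2)
            fm = _nlp_vec(TM, stack, structural, mu, omega, re_idx, sigma2)
            G[:, j] = (fp - fm) / (2.0 * h)
        return val, G.ravel()

    res = minimize(fun, TH0[:, re_idx].ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 400})
    best_x, best_f = res.x, res.fun
    if not np.isfinite(best_f):  # pragma: no cover - pathological starts
        for _ in range(n_multistart):
            jitter = TH0[:, re_idx] + rng.normal(scale=0.3, size=(n, k))
            res = minimize(fun, jitter.ravel(), jac=True, method="L-BFGS-B",
                           options={"maxiter": 400})
            if np.isfinite(res.fun) and res.fun < best_f:
                best_x, best_f = res.x, res.fun
    return unpack(best_x)


def _shared_update(TH, stack, structural, sh_idx, sigma2):
    """Likelihood-only update of the shared (fixed-effect) parameters."""
    if sh_idx.size == 0:
        return np.empty(0)

    def fun(x):
        T = TH.copy(); T[:, sh_idx] = x
        val = float(np.sum(_nll_vec(T, stack, structural, sigma2)))
        g = np.empty(sh_idx.size)
        for j, col in enumerate(sh_idx):
            h = 1e-6 * (1.0 + abs(x[j]))
            Tp = T.copy(); Tp[:, col] += h
            Tm = T.copy(); Tm[:, col] -= h
            g[j] = float(
                np.sum(_nll_vec(Tp, stack, structural, sigma2))
                - np.sum(_nll_vec(Tm, stack, structural, sigma2))
            ) / (2.0 * h)
        return val, g

    res = minimize(fun, TH[0, sh_idx], jac=True, method="L-BFGS-B")
    return res.x


def _hessian_batch(TH, stack, structural, mu, omega, re_idx, sigma2, h=1e-4):
    """Per-subject Hessians of the neg log posterior over the random effects."""
    n = TH.shape[0]
    k = re_idx.size
    H = np.empty((n, k, k))
    args = (stack, structural, mu, omega, re_idx, sigma2)
    f0 = _nlp_vec(TH, *args)
    steps = h * (1.0 + np.abs(TH[:, re_idx]))

    def at(delta_cols):
        T = TH.copy()
        for col, dv in delta_cols:
            T[:, col] = T[:, col] + dv
        return _nlp_vec(T, *args)

    for i in range(k):
        ci = re_idx[i]
        H[:, i, i] = (at([(ci, steps[:, i])]) - 2.0 * f0 + at([(ci, -steps[:, i])])) / steps[:, i] ** 2
        for j in range(i + 1, k):
            cj = re_idx[j]
            val = (
                at([(ci, steps[:, i]), (cj, steps[:, j])])
                - at([(ci, steps[:, i]), (cj, -steps[:, j])])
                - at([(ci, -steps[:, i]), (cj, steps[:, j])])
                + at([(ci, -steps[:, i]), (cj, -steps[:, j])])
            ) / (4.0 * steps[:, i] * steps[:, j])
            H[:, i, j] = H[:, j, i] = val
    return H


def _posterior_vars(H, omega_re):
    """diag(H^-1) per subject, clipped to [0, omega]; robust to indefinite H."""
    n, k, _ = H.shape
    out = np.empty((n, k))
    for i in range(n):
        try:
            var = np.diag(np.linalg.inv(H[i]))
        except np.linalg.LinAlgError:
            var = 1.0 / np.maximum(np.diag(H[i]), 1.0 / omega_re)
        out[i] = np.clip(var, 0.0, omega_re)
    return out


# ---------------------------------------------------------------------------
# public API


def map_individual(prior: PopulationModel, times, concs, regimen, config: FitConfig | None = None) -> PKParameters:
    """Empirical-Bayes (MAP) individual parameters under a population prior.

    Only the prior's random-effect parameters move; shared parameters stay at
    their population values.  With no usable observations the prior mode
    (population means) is returned.
    """
    config = config or FitConfig()
    times = np.atleast_1d(np.asarray(times, dtype=float))
    concs = np.atleast_1d(np.asarray(concs, dtype=float))
    mu = np.asarray(prior.fixed_effects, dtype=float)
    if times.size == 0:
        return prior.population_parameters()
    omega = np.maximum(np.asarray(prior.iiv_variances, dtype=float), config.omega_floor)
    stack = _Stack(
        subjects=["x"], times=times[None, :], y=concs[None, :],
        mask=np.ones((1, times.size)), dose=np.array([regimen.dose]),
        tau=np.array([regimen.tau]),
    )
    rng = np.random.default_rng(config.seed)
    TH = _map_step(mu[None, :].copy(), stack, prior.structural, mu, omega,
                   prior.random_idx, max(prior.sigma2, config.sigma2_floor),
                   rng, config.n_multistart)
    return prior._to_pk(TH[0])


def _prepare(data: EventDataset) -> tuple[_Stack, list]:
    subjects, excluded, rows = [], [], []
    for subj in data.subjects:
        rec = data.conc_records(subj, include_blq=False)
        n_blq = int(data.conc_records(subj, include_blq=True)["blq"].sum())
        if n_blq:
            logger.info("subject %s: %d BLQ observations excluded from fitting", subj, n_blq)
        if len(rec) == 0:
            logger.warning("subject %s has no usable concentration observations; excluded", subj)
            excluded.append(subj)
            continue
        reg = data.regimen(subj)
        subjects.append(subj)
        rows.append((rec["time"].to_numpy(), rec["conc"].to_numpy(), reg.dose, reg.tau))
    if not rows:
        raise ValueError("no subjects with usable observations")
    m = max(len(t) for t, *_ in rows)
    n = len(rows)
    times = np.zeros((n, m)); y = np.ones((n, m)); mask = np.zeros((n, m))
    dose = np.empty(n); tau = np.empty(n)
    for i, (t, c, d_, tu) in enumerate(rows):
        times[i, : len(t)] = t
        y[i, : len(t)] = c
        mask[i, : len(t)] = 1.0
        dose[i], tau[i] = d_, tu
    return _Stack(subjects, times, y, mask, dose, tau), excluded


def fit_population(
    data: EventDataset,
    spec: PopulationModel | str = "two_compartment",
    config: FitConfig | None = None,
) -> PopulationFit:
    """MAP-EM population fit of the specified structural model.

    `spec` may be a structural-model name (initial values then come from the
    literature preset) or a full PopulationModel of initial values.
    Deterministic given data, initial values and config; subject order does
    not affect the estimates.
    """
    config = config or FitConfig()
    if isinstance(spec, str):
        spec = PopulationModel.default_initial(spec)
    stack, excluded = _prepare(data)
    if stack.n < 2:
        raise ValueError("need at least 2 subjects with usable observations")
    structural = spec.structural
    re_idx, sh_idx = spec.random_idx, spec.shared_idx
    rng = np.random.default_rng(config.seed)

    mu = np.asarray(spec.fixed_effects, dtype=float)
    omega = np.asarray(spec.iiv_variances, dtype=float)
    omega[re_idx] = np.maximum(omega[re_idx], config.omega_floor)
    sigma2 = max(spec.sigma2, config.sigma2_floor)
    TH = np.tile(mu, (stack.n, 1))

    trace = []
    streak = 0
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        TH = _map_step(TH, stack, structural, mu, omega, re_idx, sigma2,
                       rng, config.n_multistart)
        # random effects whose variance has collapsed to the floor are
        # effectively fixed effects: update their means by pooled likelihood
        # (mean-of-MAPs cannot move once the prior pins every subject)
        collapsed = re_idx[omega[re_idx] <= 10.0 * config.omega_floor]
        eff_shared = np.unique(np.concatenate([sh_idx, collapsed])).astype(int)
        if eff_shared.size:
            sh = _shared_update(TH, stack, structural, eff_shared, sigma2)
            TH[:, eff_shared] = sh
        nlp = _nlp_vec(TH, stack, structural, mu, omega, re_idx, sigma2)
        H = _hessian_batch(TH, stack, structural, mu, omega, re_idx, sigma2)
        hvars = _posterior_vars(H, omega[re_idx])

        new_mu = mu.copy()
        new_mu[re_idx] = TH[:, re_idx].mean(axis=0)
        if eff_shared.size:
            new_mu[eff_shared] = TH[0, eff_shared]
        new_omega = omega.copy()
        new_omega[re_idx] = np.maximum(
            ((TH[:, re_idx] - new_mu[re_idx]) ** 2 + hvars).mean(axis=0),
            config.omega_floor,
        )
        F = np.maximum(_ss_conc_batch(TH, structural, stack.times, stack.dose, stack.tau), 1e-12)
        wres2 = stack.mask * ((stack.y - F) / F) ** 2
        p_eff = float(np.sum(1.0 - hvars / omega[re_idx])) + float(sh_idx.size)
        new_sigma2 = max(float(wres2.sum() / max(stack.nobs - p_eff, 1.0)), config.sigma2_floor)

        old = np.concatenate([mu, omega, [sigma2]])
        new = np.concatenate([new_mu, new_omega, [new_sigma2]])
        rel = float(np.max(np.abs(new - old) / np.maximum(np.abs(old), 1e-4)))
        mu, omega, sigma2 = new_mu, new_omega, new_sigma2
        trace.append({"iteration": n_iter, "max_rel_change": rel,
                      "objective": float(-np.sum(nlp))})

        streak = streak + 1 if rel < config.rtol else 0
        if streak >= config.consecutive:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge within %d iterations", config.max_iter)

    model = PopulationModel(structural, tuple(mu), tuple(omega), float(sigma2),
                            spec.random_effects)

    # Laplace marginal log-likelihood at the MAP estimates (random effects
    # integrated out; shared parameters are plug-in fixed effects)
    k = re_idx.size
    nlp = _nlp_vec(TH, stack, structural, mu, omega, re_idx, sigma2)
    H = _hessian_batch(TH, stack, structural, mu, omega, re_idx, sigma2)
    loglik = 0.0
    for i in range(stack.n):
        sign, logdet = np.linalg.slogdet(H[i])
        if sign <= 0:  # regularize a non-PD curvature estimate
            Hi = H[i] + np.eye(k) * (np.abs(np.diag(H[i])).max() * 1e-8 + 1e-8)
            sign, logdet = np.linalg.slogdet(Hi)
        loglik += -nlp[i] + 0.5 * k * LOG2PI - 0.5 * logdet
    aic = -2.0 * loglik + 2.0 * model.n_params

    individual = {subj: model._to_pk(TH[i]) for i, subj in enumerate(stack.subjects)}
    return PopulationFit(
        model=model, individual=individual, loglik=float(loglik), aic=float(aic),
        converged=converged, n_iter=n_iter, trace=trace, excluded_subjects=excluded,
    )


def model_aic(fit: PopulationFit) -> float:
    """AIC = -2 loglik + 2 P, P = fixed effects + IIV variances + sigma2."""
    return -2.0 * fit.loglik + 2.0 * fit.model.n_params


def select_model(fits: list[PopulationFit]) -> PopulationFit:
    """Lowest-AIC converged fit; ties broken toward fewer parameters."""
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged fits to select from")
    return min(ok, key=lambda f: (f.aic, f.model.n_params))


def weighted_residuals(fit: PopulationFit, data: EventDataset) -> pd.DataFrame:
    """Per-observation table of population/individual predictions and residuals.

    residual = (observed - individual prediction) / individual prediction,
    the proportional-error scale used in fitting.  Rows with non-positive
    predictions are flagged rather than dropped.
    """
    pop = fit.model.population_parameters()
    names = fit.model.param_names
    rows = []
    for subj in data.subjects:
        if subj not in fit.individual:
            continue
        rec = data.conc_records(subj, include_blq=False)
        reg = data.regimen(subj)
        ind = fit.individual[subj]
        th_ind = np.log([getattr(ind, k) for k in names])
        th_pop = np.log([getattr(pop, k) for k in names])
        t = rec["time"].to_numpy()
        pred_i = _ss_conc_batch(th_ind[None, :], fit.model.structural, t[None, :],
                                np.array([reg.dose]), np.array([reg.tau]))[0]
        pred_p = _ss_conc_batch(th_pop[None, :], fit.model.structural, t[None, :],
                                np.array([reg.dose]), np.array([reg.tau]))[0]
        for time, obs, pi, pp in zip(t, rec["conc"], pred_i, pred_p):
            flagged = pi <= 0
            rows.append({
                "subject": subj, "time": float(time), "observed": float(obs),
                "pred_pop": float(pp), "pred_ind": float(pi),
                "residual": float((obs - pi) / pi) if not flagged else float("nan"),
                "flagged": bool(flagged),
            })
    return pd.DataFrame(rows)
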