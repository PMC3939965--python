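"""Synthetic methadone-maintenance cohorts with known ground truth.

Emulates the design of a steady-state observational MMT study: ~60 subjects
on once-daily oral methadone (doses drawn from a truncated normal, mean 58,
SD 34, bounded to [5, 170] mg), sampled pre-dose and through 24 h post-dose.
Individual PK and PD parameters are log-normally distributed around
published population means; plasma observations carry multiplicative
log-normal noise and SOWS totals carry additive Gaussian noise before
integer rounding and clamping to [0, 64].  Every cohort is reproducible from
its seed and ships a TruthRecord for parameter-recovery experiments.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataset import EventDataset, LLOQ
from .pdlink import PDParameters, ce_steady_state, sows_effect
from .pk import DoseRegimen, PKParameters, conc_steady_state

__all__ = ["CohortConfig", "TruthRecord", "lognormal_from_moments", "sample_subject", "generate_cohort"]

#: order in which each subject's parameters are drawn from the RNG stream
PK_NAMES = ("cl_f", "v_f", "k12", "k21", "ka")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and population-truth settings for cohort simulation.

    Defaults reproduce the published study conditions: dose distribution and
    bounds, once-daily interval, a 7-point sampling grid spanning the
    interval (pre-dose plus up to 24 h), published population PK and PD
    moments, 15% proportional assay CV and an additive
    SOWS noise SD of 3 points.
    """

    n_subjects: int = 60
    dose_mean: float = 58.0
    dose_sd: float = 34.0
    dose_min: float = 5.0
    dose_max: float = 170.0
    tau: float = 24.0
    sampling_times: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 6.0, 10.0, 24.0)
    pk_mean: dict = field(
        default_factory=lambda: {"cl_f": 8.39, "v_f": 131.10, "k12": 0.57, "k21": 0.25, "ka": 0.43}
    )
    pk_sd: dict = field(
        default_factory=lambda: {"cl_f": 3.62, "v_f": 28.41, "k12": 0.04, "k21": 0.05, "ka": 0.08}
    )
    e0_mean: float = 25.0
    e0_sd: float = 8.0
    emax_mean: float = 0.3198
    emax_sd: float = 0.1237
    ec50_mean: float = 413.47
    ec50_sd: float = 108.97
    n_hill: float = 1.0
    ke0: float = 0.5
    conc_cv: float = 0.15
    sows_sd: float = 3.0
    lloq: float = LLOQ
    seed: int = 20110601

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(sd < 0 for sd in (self.dose_sd, self.e0_sd, self.emax_sd, self.ec50_sd,
                                 self.conc_cv, self.sows_sd, *self.pk_sd.values())):
            raise ValueError("all SDs must be >= 0")
        if any(t < 0 or t > self.tau for t in self.sampling_times):
            raise ValueError("sampling times must lie within [0, tau]")
        if not self.dose_min <= self.dose_mean <= self.dose_max:
            raise ValueError("dose bounds must bracket the mean")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class TruthRecord:
    """Per-subject generating parameters plus the population-level truths."""

    subjects: pd.DataFrame  # one row per subject: dose + true PK and PD parameters
    config: CohortConfig

    def pk_parameters(self, subject) -> PKParameters:
        r = self.subjects.set_index("subject").loc[subject]
        return PKParameters(**{k: float(r[k]) for k in PK_NAMES})

    def pd_parameters(self, subject) -> PDParameters:
        r = self.subjects.set_index("subject").loc[subject]
        return PDParameters(
            e0=float(r["e0"]), emax=float(r["emax"]), ec50=float(r["ec50"]),
            n=self.config.n_hill, ke0=self.config.ke0,
        )


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of the log-normal with the given natural moments.

    sigma^2 = ln(1 + (sd/mean)^2), mu = ln(mean) - sigma^2/2.
    """
    if mean <= 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def _draw_lognormal(rng, mean, sd):
    mu, sigma = lognormal_from_moments(mean, sd)
    return float(np.exp(rng.normal(mu, sigma)))


def _draw_truncated(draw, lo, hi, max_tries=1000):
    for _ in range(max_tries):
        x = draw()
        if lo < x < hi:
            return x
    raise RuntimeError("truncated sampling failed to land in bounds")


def sample_subject(config: CohortConfig, rng: np.random.Generator):
    """Draw one subject's regimen and true PK/PD parameters.

    Dose: truncated normal via resample-until-in-bounds; PK parameters and
    e0/ec50: moment-matched log-normals; emax: log-normal truncated to (0, 1).
    """
    dose = _draw_truncated(
        lambda: rng.normal(config.dose_mean, config.dose_sd), config.dose_min, config.dose_max
    )
    pk = PKParameters(**{
        name: _draw_lognormal(rng, config.pk_mean[name], config.pk_sd[name])
        for name in PK_NAMES
    })
    e0 = min(_draw_lognormal(rng, config.e0_mean, config.e0_sd), 64.0)
    emax = _draw_truncated(
        lambda: _draw_lognormal(rng, config.emax_mean, config.emax_sd), 0.0, 1.0
    )
    ec50 = _draw_lognormal(rng, config.ec50_mean, config.ec50_sd)
    pd_params = PDParameters(e0=e0, emax=emax, ec50=ec50, n=config.n_hill, ke0=config.ke0)
    return pk, pd_params, DoseRegimen(dose=dose, tau=config.tau)


def generate_cohort(config: CohortConfig | None = None) -> tuple[EventDataset, TruthRecord]:
    """Simulate a steady-state cohort and return it with its ground truth.

    A single RNG stream seeded from config.seed is consumed in subject-major
    order (parameters, then concentration noise, then SOWS noise), so the
    same seed reproduces the dataset bit for bit.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.sampling_times, dtype=float)
    # mean-one multiplicative log-normal noise at the configured CV
    sig_c = float(np.sqrt(np.log1p(config.conc_cv**2)))

    rows, truth_rows = [], []
    for i in range(config.n_subjects):
        subject = f"sub-{i + 1:03d}"
        pk, pdp, reg = sample_subject(config, rng)
        conc_noise = rng.normal(size=times.size)
        sows_noise = rng.normal(scale=config.sows_sd, size=times.size) if config.sows_sd > 0 else np.zeros(times.size)

        cp = np.atleast_1d(conc_steady_state(pk, reg, times))
        obs_c = cp * np.exp(sig_c * conc_noise - 0.5 * sig_c**2)
        ce = np.atleast_1d(ce_steady_state(pk, config.ke0, reg, times))
        sows_clean = np.atleast_1d(sows_effect(pdp, ce))
        obs_s = np.clip(np.rint(sows_clean + sows_noise), 0, 64).astype(int)

        rows.append({"subject": subject, "event": "dose", "time": 0.0,
                     "amount": reg.dose, "tau": reg.tau})
        for t, c in zip(times, obs_c):
            rows.append({"subject": subject, "event": "conc", "time": float(t),
                         "conc": float(c), "blq": bool(c < config.lloq)})
        for t, s in zip(times, obs_s):
            rows.append({"subject": subject, "event": "sows", "time": float(t), "sows": int(s)})

        truth_rows.append({
            "subject": subject, "dose": reg.dose,
            **{k: getattr(pk, k) for k in PK_NAMES},
            "e0": pdp.e0, "emax": pdp.emax, "ec50": pdp.ec50,
        })

    meta = {"generator": "methapop.simulate", "seed": str(config.seed),
            "config_hash": config.config_hash()}
    ds = EventDataset(events=pd.DataFrame(rows), meta=meta)
    truth = TruthRecord(subjects=pd.DataFrame(truth_rows), config=config)
    return ds, truth
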