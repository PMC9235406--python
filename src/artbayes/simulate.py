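"""Synthetic agents, cohorts and covariates.

Generators mirror the structure the inference stage assumes: individual
parameters are lognormal around group-level natural-scale means, play is
simulated decision-by-decision from the cognitive model, and covariates are
built with exact target correlations to the generating parameters so the
association statistics can be validated against known effect sizes.

All randomness flows from a single seed through named substreams (design,
parameters, decisions, covariates), so each component is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from artbayes.model import (
    COLLECTED,
    FORCED_FAIL,
    POINTS_PER_CAST,
    ModelParams,
    SubjectPlay,
    TrialOutcome,
    cast_probability,
    optimal_casts,
)
from artbayes.task import TaskDesign

__all__ = [
    "GroupSpec",
    "CovariateSpec",
    "substream",
    "simulate_subject",
    "simulate_cohort",
    "simulate_covariates",
]

_STREAMS = ("design", "parameters", "decisions", "covariates")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, mutually independent child stream of a master seed."""
    if name not in _STREAMS:
        raise ValueError(f"unknown substream {name!r}; expected one of {_STREAMS}")
    key = _STREAMS.index(name)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class GroupSpec:
    """Population-level description of one simulated group.

    Means are on the natural parameter scale; between-subject spread is a
    lognormal SD on the log scale.  The latent location is set to
    ``log(mean) - sd**2 / 2`` so the population mean equals ``*_mean``
    exactly.
    """

    n_subjects: int
    gamma_mean: float
    beta_mean: float
    log_sd_gamma: float
    log_sd_beta: float
    label: str

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.gamma_mean <= 0 or self.beta_mean <= 0:
            raise ValueError("group means must be positive")
        if self.log_sd_gamma < 0 or self.log_sd_beta < 0:
            raise ValueError("log-scale SDs must be >= 0")


@dataclass(frozen=True)
class CovariateSpec:
    """A covariate with a target correlation to one generating parameter.

    ``target_param`` names the parameter the covariate tracks: risk
    propensity on its natural scale, consistency on the log scale (matching
    the downstream log transform), or ``"none"`` for pure noise.
    """

    name: str
    target_param: str
    correlation: float
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.target_param not in ("gamma_plus", "beta", "none"):
            raise ValueError(f"unknown target_param {self.target_param!r}")
        if not -1.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def simulate_subject(
    params: ModelParams,
    design: TaskDesign,
    seed: int | np.random.Generator,
    subject_id: str = "s1",
    group: str = "sim",
) -> SubjectPlay:
    """Play every trial of a design by sequential Bernoulli cast decisions.

    Casting continues until a collect is drawn or the pre-generated maximum
    cast is reached, at which point the loss fish is caught (forced fail,
    zero points).  Collected trials bank 5 points per cast.
    """
    rng = np.random.default_rng(seed)
    p_arr = design.schedule.as_array()
    trials = []
    for k in range(design.n_trials):
        p = float(p_arr[k])
        max_c = design.max_casts[k]
        omega = optimal_casts(params.gamma_plus, p)
        n_casts = None
        ended_by = None
        for l in range(1, max_c + 1):
            if rng.random() < cast_probability(params.beta, omega, l):
                if l == max_c:  # the loss fish bites on the final allowed cast
                    n_casts, ended_by = max_c, FORCED_FAIL
                    break
            else:
                n_casts, ended_by = l - 1, COLLECTED
                break
        if ended_by == COLLECTED:
            points = POINTS_PER_CAST * n_casts
        else:
            points = 0
        trials.append(
            TrialOutcome(
                p_yellow=p,
                n_casts=n_casts,
                ended_by=ended_by,
                points_banked=points,
                max_casts=max_c,
            )
        )
    return SubjectPlay(
        subject_id=subject_id,
        group=group,
        version_label=design.version_label,
        trials=tuple(trials),
    )


def _draw_lognormal(rng: np.random.Generator, mean: float, log_sd: float, n: int) -> np.ndarray:
    # location chosen so E[exp(X)] equals the requested natural-scale mean
    loc = np.log(mean) - 0.5 * log_sd**2
    return np.exp(loc + log_sd * rng.standard_normal(n))


def simulate_cohort(
    groups: list[GroupSpec],
    design: TaskDesign,
    seed: int,
) -> tuple[list[SubjectPlay], pd.DataFrame]:
    """Simulate a multi-group cohort and return plays plus the ground truth.

    Returns
    -------
    plays
        One :class:`SubjectPlay` per subject, groups concatenated in spec
        order.
    truth
        Tidy table ``subject_id, group, gamma_plus, beta`` of the generating
        per-subject parameters, for recovery checks.
    """
    param_rng = substream(seed, "parameters")
    decision_rng = substream(seed, "decisions")
    plays: list[SubjectPlay] = []
    rows = []
    counter = 0
    for spec in groups:
        gammas = _draw_lognormal(param_rng, spec.gamma_mean, spec.log_sd_gamma, spec.n_subjects)
        betas = _draw_lognormal(param_rng, spec.beta_mean, spec.log_sd_beta, spec.n_subjects)
        for g, b in zip(gammas, betas):
            counter += 1
            sid = f"s{counter:03d}"
            plays.append(
                simulate_subject(
                    ModelParams(gamma_plus=float(g), beta=float(b)),
                    design,
                    decision_rng,
                    subject_id=sid,
                    group=spec.label,
                )
            )
            rows.append({"subject_id": sid, "group": spec.label,
                         "gamma_plus": float(g), "beta": float(b)})
    return plays, pd.DataFrame(rows)


def simulate_covariates(
    truth: pd.DataFrame,
    specs: list[CovariateSpec],
    seed: int,
) -> pd.DataFrame:
    """Build covariate columns with exact target correlations to the truth.

    Each covariate is a linear blend ``rho * z_target + sqrt(1 - rho^2) *
    noise`` of the standardised target series and independent standard
    normal noise, rescaled to the requested mean/sd, so the population
    Pearson correlation on the stated scale is exactly ``rho``.
    """
    rng = substream(seed, "covariates")
    n = len(truth)
    out = truth[["subject_id"]].copy()
    for spec in specs:
        noise = rng.standard_normal(n)
        if spec.target_param == "none" or spec.correlation == 0.0:
            z = noise
        else:
            if spec.target_param == "gamma_plus":
                target = truth["gamma_plus"].to_numpy(dtype=float)
            else:  # consistency enters on the log scale
                target = np.log(truth["beta"].to_numpy(dtype=float))
            sd_t = target.std(ddof=0)
            if sd_t == 0.0:
                raise ValueError(
                    f"target {spec.target_param!r} is constant; correlation undefined"
                )
            zt = (target - target.mean()) / sd_t
            rho = spec.correlation
            z = rho * zt + np.sqrt(1.0 - rho**2) * noise
        out[spec.name] = spec.mean + spec.sd * z
    return out
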