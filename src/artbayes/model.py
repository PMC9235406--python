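"""The 2-parameter cognitive model of casts-until-loss play.

An agent with risk propensity ``gamma_plus`` and behavioural consistency
``beta`` holds, on a trial with loss probability ``p``, an internal cast
target

    omega = -gamma_plus / log(1 - p)

and at each opportunity ``l`` = 1, 2, ... casts with probability

    p_cast(l) = 1 / (1 + exp(beta * (l - omega)))

i.e. a logistic in the distance from the target: above chance before the
target, exactly 0.5 at ``l == omega``, below chance past it, and a coin flip
everywhere when ``beta == 0``.

Each opportunity is a Bernoulli cast/collect decision.  A trial ends either
by a voluntary collect (the collect decision is observed and contributes
``log(1 - p_cast)``) or by the loss fish being caught at the pre-generated
maximum cast, which censors the never-made collect decision: only the cast
decisions up to and including the final cast are scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit

__all__ = [
    "COLLECTED",
    "FORCED_FAIL",
    "POINTS_PER_CAST",
    "ModelParams",
    "TrialOutcome",
    "SubjectPlay",
    "optimal_casts",
    "cast_probability",
    "trial_loglik",
    "subject_loglik",
]

COLLECTED = "collected"
FORCED_FAIL = "forced_fail"
POINTS_PER_CAST = 5


@dataclass(frozen=True)
class ModelParams:
    """Risk propensity and behavioural consistency for one agent."""

    gamma_plus: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.gamma_plus >= 0.0):
            raise ValueError("gamma_plus must be >= 0")
        if not (self.beta >= 0.0):
            raise ValueError("beta must be >= 0")


@dataclass(frozen=True)
class TrialOutcome:
    """One trial's observed play.

    ``max_casts`` is optional context from the design; when present it is
    used to validate the censoring invariants (a forced fail ends exactly at
    the maximum cast, a voluntary collect strictly before it).
    """

    p_yellow: float
    n_casts: int
    ended_by: str
    points_banked: int
    max_casts: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_yellow < 1.0):
            raise ValueError("p_yellow must lie strictly in (0, 1)")
        if self.ended_by not in (COLLECTED, FORCED_FAIL):
            raise ValueError(f"unknown outcome label {self.ended_by!r}")
        if self.n_casts < 0:
            raise ValueError("n_casts must be >= 0")
        if self.ended_by == FORCED_FAIL:
            if self.n_casts < 1:
                raise ValueError("a forced-fail trial has at least one cast")
            if self.points_banked != 0:
                raise ValueError("forced-fail trials bank zero points")
            if self.max_casts is not None and self.n_casts != self.max_casts:
                raise ValueError(
                    f"forced fail at {self.n_casts} casts but max_casts={self.max_casts}"
                )
        else:
            expected = POINTS_PER_CAST * self.n_casts
            if self.points_banked != expected:
                raise ValueError(
                    f"collected trial with {self.n_casts} casts banks {expected} points, "
                    f"got {self.points_banked}"
                )
            if self.max_casts is not None and self.n_casts >= self.max_casts:
                raise ValueError(
                    "collected trials end strictly before the maximum cast"
                )


@dataclass(frozen=True)
class SubjectPlay:
    """One subject's full run through a task version."""

    subject_id: str
    group: str
    version_label: str
    trials: tuple[TrialOutcome, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def optimal_casts(gamma_plus: float, p_yellow) -> float | np.ndarray:
    """Internal cast target: ``-gamma_plus / log(1 - p_yellow)``.

    Increasing in risk propensity, decreasing in the loss probability.
    Accepts a scalar or array of probabilities.
    """
    if gamma_plus < 0.0:
        raise ValueError("gamma_plus must be >= 0")
    p = np.asarray(p_yellow, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("p_yellow must lie strictly in (0, 1)")
    omega = -gamma_plus / np.log1p(-p)
    return float(omega) if np.isscalar(p_yellow) else omega


def cast_probability(beta: float, omega, l) -> float | np.ndarray:
    """Probability of casting at opportunity ``l`` given target ``omega``.

    Evaluated as ``sigmoid(beta * (omega - l))`` via a numerically stable
    logistic, so large ``beta * |l - omega|`` saturates without overflow.
    """
    if beta < 0.0:
        raise ValueError("beta must be >= 0")
    out = expit(beta * (np.asarray(omega, dtype=float) - np.asarray(l, dtype=float)))
    return float(out) if out.ndim == 0 else out


def trial_loglik(params: ModelParams, trial: TrialOutcome) -> float:
    """Log-likelihood of one trial's decision sequence.

    A collected trial with ``c`` casts contributes ``c`` cast decisions plus
    the collect decision at opportunity ``c + 1``; a forced fail with ``m``
    casts contributes only its ``m`` cast decisions (the collect is
    censored).
    """
    omega = optimal_casts(params.gamma_plus, trial.p_yellow)
    c = trial.n_casts
    ll = float(np.sum(log_expit(params.beta * (omega - np.arange(1, c + 1)))))
    if trial.ended_by == COLLECTED:
        ll += float(log_expit(params.beta * ((c + 1) - omega)))
    return ll


def subject_loglik(params: ModelParams, play: SubjectPlay) -> float:
    """Sum of trial log-likelihoods (trials are conditionally independent)."""
    return sum(trial_loglik(params, t) for t in play.trials)


def packed_decisions(plays: list[SubjectPlay]) -> "PackedDecisions":
    """Flatten plays into arrays for vectorised likelihood evaluation."""
    subj_idx: list[int] = []
    slope: list[float] = []
    opportunity: list[float] = []
    sign: list[float] = []
    for i, play in enumerate(plays):
        for t in play.trials:
            a = -1.0 / np.log1p(-t.p_yellow)  # omega = gamma * a
            c = t.n_casts
            for l in range(1, c + 1):
                subj_idx.append(i)
                slope.append(a)
                opportunity.append(float(l))
                sign.append(1.0)
            if t.ended_by == COLLECTED:
                subj_idx.append(i)
                slope.append(a)
                opportunity.append(float(c + 1))
                sign.append(-1.0)
    return PackedDecisions(
        n_subjects=len(plays),
        subj_idx=np.asarray(subj_idx, dtype=np.intp),
        slope=np.asarray(slope, dtype=float),
        opportunity=np.asarray(opportunity, dtype=float),
        sign=np.asarray(sign, dtype=float),
    )


@dataclass(frozen=True)
class PackedDecisions:
    """Decision-level arrays for a cohort; see :func:`packed_decisions`.

    Each decision contributes ``log_sigmoid(sign * beta * (gamma * slope -
    opportunity))`` for its subject: sign +1 for casts, -1 for collects.
    """

    n_subjects: int
    subj_idx: np.ndarray
    slope: np.ndarray
    opportunity: np.ndarray
    sign: np.ndarray

    def loglik(self, gamma: np.ndarray, beta: np.ndarray) -> np.ndarray:
        """Per-subject log-likelihood for per-subject parameter vectors."""
        g = np.asarray(gamma, dtype=float)[self.subj_idx]
        b = np.asarray(beta, dtype=float)[self.subj_idx]
        terms = log_expit(self.sign * b * (g * self.slope - self.opportunity))
        return np.bincount(self.subj_idx, weights=terms, minlength=self.n_subjects)
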