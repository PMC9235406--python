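"""Task construction: probability schedule, max-cast generation, versions.

The game board is a sequence of trials.  Each trial has a fixed probability
that a cast hits the loss fish, and a pre-generated maximum number of casts:
the cast at which the loss fish is guaranteed to be caught.  The canonical
design has 30 trials in 6 blocks of 5, with the loss probability starting at
0.05 and stepping up by 0.05 per block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProbabilitySchedule",
    "TaskDesign",
    "build_schedule",
    "canonical_schedule",
    "expected_max_casts",
    "generate_max_casts",
    "make_versions",
]


@dataclass(frozen=True)
class ProbabilitySchedule:
    """Per-trial loss-fish probability with a block structure.

    Parameters
    ----------
    p_yellow
        Per-trial probability of catching the loss fish, each in (0, 1).
    block_size
        Number of consecutive trials sharing one probability level.
    """

    p_yellow: tuple[float, ...]
    block_size: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p_yellow, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("p_yellow must be a non-empty 1-d sequence")
        if np.any(p <= 0.0) or np.any(p >= 1.0):
            raise ValueError("all probabilities must lie strictly in (0, 1)")
        if self.block_size < 1 or p.size % self.block_size:
            raise ValueError(
                f"schedule length {p.size} not divisible by block_size {self.block_size}"
            )
        blocks = p.reshape(-1, self.block_size)
        if not np.all(blocks == blocks[:, :1]):
            raise ValueError("probability must be constant within each block")
        object.__setattr__(self, "p_yellow", tuple(float(x) for x in p))

    @property
    def n_trials(self) -> int:
        return len(self.p_yellow)

    @property
    def n_blocks(self) -> int:
        return self.n_trials // self.block_size

    def as_array(self) -> np.ndarray:
        return np.asarray(self.p_yellow, dtype=float)


@dataclass(frozen=True)
class TaskDesign:
    """A playable design: schedule plus the pre-generated max casts per trial."""

    schedule: ProbabilitySchedule
    max_casts: tuple[int, ...]
    version_label: str = "A"

    def __post_init__(self) -> None:
        m = np.asarray(self.max_casts)
        if m.size != self.schedule.n_trials:
            raise ValueError("max_casts length must equal schedule length")
        if m.size and (np.any(m < 1) or np.any(m != np.floor(m))):
            raise ValueError("max_casts must be positive integers")
        object.__setattr__(self, "max_casts", tuple(int(x) for x in m))

    @property
    def n_trials(self) -> int:
        return self.schedule.n_trials


def build_schedule(
    n_trials: int,
    p_start: float,
    p_increment: float,
    block_size: int,
) -> ProbabilitySchedule:
    """Build a blocked, stepwise-increasing loss-probability schedule.

    Block ``b`` (0-indexed) gets probability ``p_start + b * p_increment`` on
    every one of its ``block_size`` trials.  The final block's probability
    must remain strictly below 1.
    """
    if n_trials < 1 or block_size < 1:
        raise ValueError("n_trials and block_size must be positive")
    if n_trials % block_size:
        raise ValueError(f"n_trials {n_trials} not divisible by block_size {block_size}")
    n_blocks = n_trials // block_size
    levels = p_start + p_increment * np.arange(n_blocks)
    if levels[0] <= 0.0:
        raise ValueError("starting probability must be positive")
    if levels[-1] >= 1.0:
        raise ValueError(
            f"final block probability {levels[-1]:.3f} must be strictly below 1"
        )
    p = np.repeat(levels, block_size)
    return ProbabilitySchedule(p_yellow=tuple(p), block_size=block_size)


def canonical_schedule() -> ProbabilitySchedule:
    """The 30-trial design: 6 blocks of 5, probabilities 0.05 to 0.30."""
    return build_schedule(n_trials=30, p_start=0.05, p_increment=0.05, block_size=5)


def expected_max_casts(schedule: ProbabilitySchedule) -> tuple[np.ndarray, float]:
    """Expected max casts per trial (the reciprocal 1/p) and the design mean."""
    per_trial = 1.0 / schedule.as_array()
    return per_trial, float(per_trial.mean())


def generate_max_casts(
    schedule: ProbabilitySchedule,
    seed: int | np.random.Generator,
    version_label: str = "A",
) -> TaskDesign:
    """Draw max casts from a geometric distribution on {1, 2, ...}.

    With per-cast loss probability ``p`` the cast on which the loss fish is
    first caught is geometric with mean ``1/p``, matching the design target.
    """
    rng = np.random.default_rng(seed)
    p = schedule.as_array()
    draws = rng.geometric(p)
    return TaskDesign(schedule=schedule, max_casts=tuple(int(x) for x in draws),
                      version_label=version_label)


def make_versions(
    design: TaskDesign,
    n_versions: int,
    seed: int | np.random.Generator,
    labels: tuple[str, ...] | None = None,
) -> list[TaskDesign]:
    """Reorder max casts within probability blocks to make equivalent versions.

    Version 1 is the input ordering; each further version independently
    shuffles the max casts within each block, so per-block multisets are
    preserved exactly.
    """
    if n_versions < 1:
        raise ValueError("n_versions must be >= 1")
    if labels is None:
        labels = tuple(chr(ord("A") + i) for i in range(n_versions))
    if len(labels) != n_versions:
        raise ValueError("labels length must equal n_versions")
    rng = np.random.default_rng(seed)
    block = design.schedule.block_size
    base = np.asarray(design.max_casts).reshape(-1, block)
    out = [TaskDesign(design.schedule, design.max_casts, version_label=labels[0])]
    for v in range(1, n_versions):
        shuffled = base.copy()
        for row in shuffled:
            rng.shuffle(row)
        out.append(
            TaskDesign(design.schedule, tuple(int(x) for x in shuffled.ravel()),
                       version_label=labels[v])
        )
    return out
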