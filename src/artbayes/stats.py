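"""Outcome measures and group/association statistics.

Covers the adjusted score (mean casts over voluntarily collected trials),
default-prior (JZS) Bayes factors for two-sample and one-way designs,
two-sample permutation tests, Pearson associations with an optional log
transform, and intracranial-volume normalisation of regional volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps

from artbayes.model import COLLECTED, SubjectPlay

__all__ = [
    "AssociationResult",
    "adjusted_score",
    "associate",
    "bf_anova_oneway",
    "bf_interpretation",
    "bf_ttest",
    "cohort_table",
    "permutation_test",
    "tiv_correct",
]

DEFAULT_TTEST_SCALE = math.sqrt(2.0) / 2.0
DEFAULT_ANOVA_SCALE = 0.5


def adjusted_score(play: SubjectPlay) -> float:
    """Mean casts over collected trials; NaN when every trial was a forced fail.

    The missing state is deliberate: a subject who never voluntarily
    collected has no defined adjusted score, and NaN propagates as missing
    through downstream statistics rather than as a zero.
    """
    casts = [t.n_casts for t in play.trials if t.ended_by == COLLECTED]
    if not casts:
        return float("nan")
    return float(np.mean(casts))


def _two_sample_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, int]:
    n1, n2 = x.size, y.size
    nu = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / nu
    if sp2 <= 0.0:
        raise ValueError("zero pooled variance; Bayes factor undefined")
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return t, n1, n2


def bf_ttest(
    x,
    y,
    cauchy_scale: float = DEFAULT_TTEST_SCALE,
) -> float:
    """JZS Bayes factor BF10 for a two-sample mean difference.

    Cauchy(0, ``cauchy_scale``) prior on the standardised effect,
    equivalently a normal prior with inverse-gamma(1/2, scale^2/2) mixing on
    its variance g; the one-dimensional g integral is evaluated by adaptive
    quadrature.  Values below 1 favour the null.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    t, n1, n2 = _two_sample_t(x, y)
    return bf_ttest_from_t(t, n1, n2, cauchy_scale)


def bf_ttest_from_t(
    t: float,
    n1: int,
    n2: int,
    cauchy_scale: float = DEFAULT_TTEST_SCALE,
) -> float:
    """JZS BF10 from a two-sample t statistic and group sizes."""
    nu = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)
    r2 = cauchy_scale**2

    def integrand(g: float) -> float:
        shrink = 1.0 + n_eff * g
        like = shrink**-0.5 * (1.0 + t * t / (shrink * nu)) ** (-(nu + 1) / 2.0)
        prior = sps.invgamma.pdf(g, 0.5, scale=r2 / 2.0)
        return like * prior

    num, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    den = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    return float(num / den)


def _sum_to_zero_basis(k: int) -> np.ndarray:
    """Orthonormal k x (k-1) basis of the sum-to-zero subspace."""
    c = np.eye(k) - np.full((k, k), 1.0 / k)
    vals, vecs = np.linalg.eigh(c)
    return vecs[:, vals > 0.5]


def bf_anova_oneway(
    samples: list,
    prior_scale: float = DEFAULT_ANOVA_SCALE,
) -> float:
    """Default-prior one-way Bayes factor BF10 against the grand-mean null.

    Group effects get a g-prior on sum-to-zero contrasts (normal with
    inverse-gamma(1/2, scale^2/2) mixing on g); location flat, error
    variance Jeffreys.  The marginal-likelihood ratio conditional on g is
    closed-form for the linear model, leaving a one-dimensional g integral
    evaluated by quadrature.
    """
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    for a in arrays:
        if a.size < 2:
            raise ValueError("each group needs n >= 2")
        if not np.all(np.isfinite(a)):
            raise ValueError("samples must be finite")
    y = np.concatenate(arrays)
    n_total = y.size
    k = len(arrays)
    g_idx = np.repeat(np.arange(k), [a.size for a in arrays])
    indicator = np.zeros((n_total, k))
    indicator[np.arange(n_total), g_idx] = 1.0
    x = indicator @ _sum_to_zero_basis(k)

    yc = y - y.mean()
    xc = x - x.mean(axis=0)
    s0 = float(yc @ yc)
    if s0 <= 0.0:
        raise ValueError("degenerate data: zero total variance")
    xtx = xc.T @ xc
    xty = xc.T @ yc
    r2 = prior_scale**2
    p = k - 1

    def ratio(g: float) -> float:
        a = xtx + np.eye(p) / g
        sign, logdet = np.linalg.slogdet(a)
        s1 = s0 - float(xty @ np.linalg.solve(a, xty))
        log_ratio = (
            -0.5 * p * math.log(g)
            - 0.5 * logdet
            - 0.5 * (n_total - 1) * (math.log(s1) - math.log(s0))
        )
        return math.exp(log_ratio)

    def integrand(g: float) -> float:
        return ratio(g) * sps.invgamma.pdf(g, 0.5, scale=r2 / 2.0)

    bf, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return float(bf)


def permutation_test(
    x,
    y,
    statistic: str = "mean_diff",
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    exact: bool = False,
) -> float:
    """Two-sided label-permutation p-value.

    Monte-Carlo mode uses the add-one convention ``p = (b + 1) / (n_perm +
    1)`` where ``b`` counts permuted statistics at least as extreme (in
    absolute value) as the observed one, so p is never exactly zero.  With
    ``exact=True`` all distinct label assignments are enumerated and p is
    the exact tail fraction (feasible only for small samples).
    """
    if statistic != "mean_diff":
        raise ValueError(f"unknown statistic {statistic!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pool = np.concatenate([x, y])
    n1 = x.size
    obs = abs(x.mean() - y.mean())
    if exact:
        from itertools import combinations

        total = 0
        b = 0
        pool_sum = pool.sum()
        n2 = y.size
        for idx in combinations(range(pool.size), n1):
            sx = pool[list(idx)].sum()
            d = sx / n1 - (pool_sum - sx) / n2
            total += 1
            b += abs(d) >= obs - 1e-12
        return float(b / total)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, pool.size)), axis=1)
    permuted = pool[order]
    diffs = permuted[:, :n1].mean(axis=1) - permuted[:, n1:].mean(axis=1)
    b = int(np.sum(np.abs(diffs) >= obs - 1e-12))
    return float((b + 1) / (n_perm + 1))


@dataclass(frozen=True)
class AssociationResult:
    """A Pearson association between two cohort columns."""

    x: str
    y: str
    n: int
    r: float
    p: float
    transform: str
    family: int | None = None
    p_bonferroni: float | None = None
    note: str = ""


def associate(
    table: pd.DataFrame,
    x_name: str,
    y_name: str,
    transform_y: str = "none",
    family: int | None = None,
) -> AssociationResult:
    """Pearson correlation on complete cases, optionally log-transforming y.

    A Bonferroni-adjusted p is reported only when ``family`` declares the
    number of tests in the family; otherwise the nominal p stands alone.
    """
    if transform_y not in ("none", "log"):
        raise ValueError(f"unknown transform {transform_y!r}")
    sub = table[[x_name, y_name]].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 complete pairs")
    x = sub[x_name].to_numpy(dtype=float)
    y = sub[y_name].to_numpy(dtype=float)
    if transform_y == "log":
        if np.any(y <= 0.0):
            raise ValueError(
                f"log transform of {y_name!r} requires strictly positive values"
            )
        y = np.log(y)
    if x.std(ddof=0) == 0.0 or y.std(ddof=0) == 0.0:
        raise ValueError("constant input; correlation undefined")
    r, p = sps.pearsonr(x, y)
    p_bonf = min(1.0, p * family) if family else None
    return AssociationResult(
        x=x_name, y=y_name, n=len(sub), r=float(r), p=float(p),
        transform=transform_y, family=family, p_bonferroni=p_bonf,
    )


def tiv_correct(volume: float, tiv: float) -> float:
    """Regional volume divided by total intracranial volume."""
    if tiv <= 0.0:
        raise ValueError("total intracranial volume must be positive")
    if volume < 0.0:
        raise ValueError("volume must be >= 0")
    return volume / tiv


def bf_interpretation(bf: float) -> str:
    """Report annotation for a BF10 on the conventional evidence bands."""
    if bf > 10.0:
        return "strong evidence for the alternative"
    if bf > 3.0:
        return "moderate evidence for the alternative"
    if bf > 1.0:
        return "anecdotal evidence for the alternative"
    if bf > 1.0 / 3.0:
        return "anecdotal evidence for the null"
    if bf > 0.1:
        return "moderate evidence for the null"
    return "strong evidence for the null"


def cohort_table(
    plays: list[SubjectPlay],
    estimates: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the one-row-per-subject analysis table.

    Joins adjusted scores with the posterior point estimates
    (``subject_id, group, gamma_hat, beta_hat``) and any covariate table on
    ``subject_id``.
    """
    ids = [p.subject_id for p in plays]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_ids in plays")
    base = pd.DataFrame(
        {
            "subject_id": ids,
            "group": [p.group for p in plays],
            "adjusted_score": [adjusted_score(p) for p in plays],
        }
    )
    if estimates is not None:
        base = base.merge(estimates.drop(columns=["group"], errors="ignore"),
                          on="subject_id", how="left")
    if covariates is not None:
        base = base.merge(covariates, on="subject_id", how="left")
    return base
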