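"""Hierarchical Bayesian estimation of risk propensity and consistency.

Model, per group g with subjects i:

    log gamma_i ~ Normal(mu_g_gamma, sigma_g_gamma)
    log beta_i  ~ Normal(mu_g_beta,  sigma_g_beta)
    mu ~ Normal(prior_loc_mean, prior_loc_sd)      [one per group x parameter]
    sigma ~ HalfNormal(prior_scale)
    data | gamma_i, beta_i  via the censored Bernoulli cast likelihood

Groups are fitted independently (each gets its own location/scale pair per
parameter).  Sampling is an adaptive Metropolis-within-Gibbs scheme:

 * per-subject joint random-walk updates of (log gamma_i, log beta_i),
   vectorised across subjects;
 * conjugate Gibbs draws of each location mu;
 * random-walk updates of each log sigma (prior-only conditional);
 * an interweaved non-centred joint update of all four hyperparameters
   holding the standardised subject effects fixed, which removes the funnel
   coupling at small n.

Proposal scales adapt during warmup toward standard acceptance targets and
are frozen afterwards.  The group-level natural-scale mean is computed per
draw as exp(mu + sigma^2/2); the per-draw average of the sampled individual
parameters is emitted alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from artbayes.diagnostics import convergence_report, effective_sample_size, split_rhat
from artbayes.model import SubjectPlay, packed_decisions

__all__ = [
    "HierarchicalModelSpec",
    "FitResult",
    "fit_hierarchical",
    "point_estimates",
]

_ACC_SUBJECT = 0.30
_ACC_SCALAR = 0.44
_ACC_HYPER = 0.25


@dataclass(frozen=True)
class HierarchicalModelSpec:
    """Priors, chain configuration and convergence threshold for a fit."""

    prior_loc_mean: float = 0.0
    prior_loc_sd: float = 1.5
    prior_scale: float = 1.0
    n_chains: int = 4
    n_warmup: int = 2000
    n_samples: int = 2000
    seed: int = 0
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for split-chain diagnostics")
        if self.n_samples < 1 or self.n_warmup < 0:
            raise ValueError("n_samples must be >= 1 and n_warmup >= 0")
        if self.prior_loc_sd <= 0 or self.prior_scale <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class FitResult:
    """Posterior summaries, raw draws and diagnostics for a cohort fit."""

    summary: pd.DataFrame
    draws: dict[str, dict[str, np.ndarray]]
    diagnostics: pd.DataFrame
    converged: bool


def _halfnormal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return -0.5 * (x / scale) ** 2


class _GroupSampler:
    """One chain of the Metropolis-within-Gibbs sampler for a single group."""

    def __init__(self, packed, spec: HierarchicalModelSpec, rng: np.random.Generator):
        self.packed = packed
        self.spec = spec
        self.rng = rng
        n = packed.n_subjects
        # state: latent logs and hypers [0] = gamma, [1] = beta
        self.mu = spec.prior_loc_mean + 0.5 * rng.standard_normal(2)
        self.log_sigma = np.log(0.5) + 0.3 * rng.standard_normal(2)
        self.theta = self.mu[0] + 0.3 * rng.standard_normal(n)
        self.phi = self.mu[1] + 0.3 * rng.standard_normal(n)
        self.ll = self._loglik(self.theta, self.phi)
        if not np.all(np.isfinite(self.ll)):
            raise ValueError("non-finite initial likelihood; check gameplay data")
        # adaptive proposal scales; per-subject proposals additionally adapt a
        # 2x2 empirical covariance of (log gamma, log beta)
        self.log_step_subj = np.full(n, np.log(0.8))
        self.subj_mean = np.stack([self.theta, self.phi], axis=1)
        self.subj_cov = np.tile(0.05 * np.eye(2), (n, 1, 1))
        self.log_step_sigma = np.full(2, np.log(0.5))
        # non-centred hyper moves: translation of mu, rescale of sigma
        self.log_step_trans = np.full(2, np.log(0.2))
        self.log_step_rescale = np.full(2, np.log(0.2))
        # joint non-centred update of (mu_gamma, mu_beta, log sigma_gamma,
        # log sigma_beta) along an adapted 4x4 covariance; handles the ridge
        # where the likelihood constrains beta * gamma much better than
        # either factor alone, and the coupling between the group scales
        self.log_step_joint = np.log(0.2)
        self.joint_mean = np.concatenate([self.mu, self.log_sigma])
        self.joint_cov = 0.05 * np.eye(4)

    def _loglik(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        # clip keeps stray warmup proposals from overflowing exp; at |50| the
        # likelihood is already effectively -inf/flat so inference is unaffected
        return self.packed.loglik(
            np.exp(np.clip(theta, -50.0, 50.0)), np.exp(np.clip(phi, -50.0, 50.0))
        )

    def _update_subjects(self, adapt: bool, eta: float) -> None:
        n = self.packed.n_subjects
        step = np.exp(self.log_step_subj)
        # vectorised 2x2 Cholesky of the adapted per-subject covariances
        a = self.subj_cov[:, 0, 0] + 1e-8
        b = self.subj_cov[:, 0, 1]
        c = self.subj_cov[:, 1, 1] + 1e-8
        l11 = np.sqrt(a)
        l21 = b / l11
        l22 = np.sqrt(np.maximum(c - l21**2, 1e-10))
        z1 = self.rng.standard_normal(n)
        z2 = self.rng.standard_normal(n)
        prop_theta = self.theta + step * l11 * z1
        prop_phi = self.phi + step * (l21 * z1 + l22 * z2)
        ll_prop = self._loglik(prop_theta, prop_phi)
        sig = np.exp(self.log_sigma)
        logp_cur = (
            self.ll
            - 0.5 * ((self.theta - self.mu[0]) / sig[0]) ** 2
            - 0.5 * ((self.phi - self.mu[1]) / sig[1]) ** 2
        )
        logp_prop = (
            ll_prop
            - 0.5 * ((prop_theta - self.mu[0]) / sig[0]) ** 2
            - 0.5 * ((prop_phi - self.mu[1]) / sig[1]) ** 2
        )
        accept = np.log(self.rng.random(n)) < logp_prop - logp_cur
        self.theta = np.where(accept, prop_theta, self.theta)
        self.phi = np.where(accept, prop_phi, self.phi)
        self.ll = np.where(accept, ll_prop, self.ll)
        if adapt:
            self.log_step_subj += eta * (accept.astype(float) - _ACC_SUBJECT)
            state = np.stack([self.theta, self.phi], axis=1)
            delta = state - self.subj_mean
            self.subj_mean += eta * delta
            outer = delta[:, :, None] * delta[:, None, :]
            self.subj_cov += eta * (outer - self.subj_cov)

    def _update_mu(self) -> None:
        spec = self.spec
        sig = np.exp(self.log_sigma)
        for j, latent in enumerate((self.theta, self.phi)):
            n = latent.size
            prec = n / sig[j] ** 2 + 1.0 / spec.prior_loc_sd**2
            mean = (latent.sum() / sig[j] ** 2 + spec.prior_loc_mean / spec.prior_loc_sd**2) / prec
            self.mu[j] = mean + self.rng.standard_normal() / np.sqrt(prec)

    def _update_sigma(self, adapt: bool, eta: float) -> None:
        for j, latent in enumerate((self.theta, self.phi)):
            n = latent.size
            resid2 = float(np.sum((latent - self.mu[j]) ** 2))

            def logpost(u: float) -> float:
                s = np.exp(u)
                return (
                    -n * u
                    - 0.5 * resid2 / s**2
                    + _halfnormal_logpdf(s, self.spec.prior_scale)
                    + u  # Jacobian of the log transform
                )

            u_cur = self.log_sigma[j]
            u_prop = u_cur + np.exp(self.log_step_sigma[j]) * self.rng.standard_normal()
            acc = np.log(self.rng.random()) < logpost(u_prop) - logpost(u_cur)
            if acc:
                self.log_sigma[j] = u_prop
            if adapt:
                self.log_step_sigma[j] += eta * (float(acc) - _ACC_SCALAR)

    def _try_latent_move(self, j: int, latent_prop: np.ndarray,
                         hyper_delta: float) -> bool:
        """MH accept/reject for a move of one side's latents plus hypers.

        ``hyper_delta`` is the change in the hyperprior log-density plus any
        Jacobian terms; the conditional N(latent | mu, sigma) factor cancels
        by construction of the non-centred moves.
        """
        if j == 0:
            ll_prop = self._loglik(latent_prop, self.phi)
        else:
            ll_prop = self._loglik(self.theta, latent_prop)
        log_ratio = float(ll_prop.sum() - self.ll.sum()) + hyper_delta
        if np.log(self.rng.random()) < log_ratio:
            if j == 0:
                self.theta = latent_prop
            else:
                self.phi = latent_prop
            self.ll = ll_prop
            return True
        return False

    def _update_mu_joint(self, adapt: bool, eta: float) -> None:
        """Covariance-adapted joint non-centred update of all four hypers.

        Proposes (mu_gamma, mu_beta, log sigma_gamma, log sigma_beta) from
        an adapted 4x4 covariance while holding the standardised subject
        effects fixed, so the latents move with the hypers, the conditional
        priors cancel, and the move can track posterior ridges between the
        group locations and scales.
        """
        spec = self.spec
        sig = np.exp(self.log_sigma)
        z_theta = (self.theta - self.mu[0]) / sig[0]
        z_phi = (self.phi - self.mu[1]) / sig[1]
        cov = self.joint_cov + 1e-8 * np.eye(4)
        delta = np.exp(self.log_step_joint) * (
            np.linalg.cholesky(cov) @ self.rng.standard_normal(4)
        )
        mu_prop = self.mu + delta[:2]
        log_sig_prop = self.log_sigma + delta[2:]
        sig_prop = np.exp(log_sig_prop)
        prop_theta = mu_prop[0] + sig_prop[0] * z_theta
        prop_phi = mu_prop[1] + sig_prop[1] * z_phi
        ll_prop = self._loglik(prop_theta, prop_phi)

        def hyper_logp(mu: np.ndarray, log_sig: np.ndarray) -> float:
            out = float(
                np.sum(-0.5 * ((mu - spec.prior_loc_mean) / spec.prior_loc_sd) ** 2)
            )
            for ls in log_sig:
                out += _halfnormal_logpdf(np.exp(ls), spec.prior_scale) + ls
            return out

        log_ratio = (
            float(ll_prop.sum() - self.ll.sum())
            + hyper_logp(mu_prop, log_sig_prop)
            - hyper_logp(self.mu, self.log_sigma)
        )
        acc = np.log(self.rng.random()) < log_ratio
        if acc:
            self.mu = mu_prop
            self.log_sigma = log_sig_prop
            self.theta = prop_theta
            self.phi = prop_phi
            self.ll = ll_prop
        if adapt:
            self.log_step_joint += eta * (float(acc) - _ACC_HYPER)
            state = np.concatenate([self.mu, self.log_sigma])
            d = state - self.joint_mean
            self.joint_mean += eta * d
            self.joint_cov += eta * (np.outer(d, d) - self.joint_cov)

    def _update_hypers_noncentred(self, adapt: bool, eta: float) -> None:
        """Non-centred hyper moves holding standardised effects fixed.

        For each side j (0 = risk propensity, 1 = consistency):

        * translation: shift mu_j and all latents by the same delta, which
          leaves the conditional prior invariant, so only the likelihood and
          the mu hyperprior enter the acceptance ratio;
        * rescale: multiply sigma_j and the latent deviations from mu_j by a
          common factor, likewise cancelling the conditional prior.

        These are the moves that break the slow centred random walk between
        the group location/scale and the subject effects at small n.
        """
        spec = self.spec
        for j in range(2):
            latent = self.theta if j == 0 else self.phi
            # translation move on mu_j
            delta = np.exp(self.log_step_trans[j]) * self.rng.standard_normal()
            mu_prop = self.mu[j] + delta
            prior_delta = (
                -0.5 * ((mu_prop - spec.prior_loc_mean) / spec.prior_loc_sd) ** 2
                + 0.5 * ((self.mu[j] - spec.prior_loc_mean) / spec.prior_loc_sd) ** 2
            )
            acc = self._try_latent_move(j, latent + delta, prior_delta)
            if acc:
                self.mu[j] = mu_prop
            if adapt:
                self.log_step_trans[j] += eta * (float(acc) - _ACC_SCALAR)

            # rescale move on sigma_j
            latent = self.theta if j == 0 else self.phi
            du = np.exp(self.log_step_rescale[j]) * self.rng.standard_normal()
            log_sig_prop = self.log_sigma[j] + du
            sig_old, sig_new = np.exp(self.log_sigma[j]), np.exp(log_sig_prop)
            prior_delta = (
                _halfnormal_logpdf(sig_new, spec.prior_scale)
                - _halfnormal_logpdf(sig_old, spec.prior_scale)
                + du  # Jacobian of the log parameterisation
            )
            latent_prop = self.mu[j] + (sig_new / sig_old) * (latent - self.mu[j])
            acc = self._try_latent_move(j, latent_prop, prior_delta)
            if acc:
                self.log_sigma[j] = log_sig_prop
            if adapt:
                self.log_step_rescale[j] += eta * (float(acc) - _ACC_SCALAR)

    def run(self) -> dict[str, np.ndarray]:
        spec = self.spec
        n = self.packed.n_subjects
        kept = spec.n_samples
        out = {
            "theta": np.empty((kept, n)),
            "phi": np.empty((kept, n)),
            "mu": np.empty((kept, 2)),
            "sigma": np.empty((kept, 2)),
        }
        total = spec.n_warmup + kept
        for it in range(total):
            adapt = it < spec.n_warmup
            eta = (it + 1) ** -0.6
            self._update_subjects(adapt, eta)
            self._update_mu()
            self._update_sigma(adapt, eta)
            for _ in range(2):
                self._update_hypers_noncentred(adapt, eta)
                self._update_mu_joint(adapt, eta)
            if it >= spec.n_warmup:
                j = it - spec.n_warmup
                out["theta"][j] = self.theta
                out["phi"][j] = self.phi
                out["mu"][j] = self.mu
                out["sigma"][j] = np.exp(self.log_sigma)
        return out


def _fit_group(
    plays: list[SubjectPlay],
    spec: HierarchicalModelSpec,
    seeds: list[np.random.SeedSequence],
) -> dict[str, np.ndarray]:
    """Run all chains for one group; returns (chains, draws[, ...]) arrays."""
    packed = packed_decisions(plays)
    chains = []
    for ss in seeds:
        sampler = _GroupSampler(packed, spec, np.random.default_rng(ss))
        chains.append(sampler.run())
    n = packed.n_subjects
    kept = spec.n_samples
    c = spec.n_chains
    theta = np.stack([ch["theta"] for ch in chains])  # (c, kept, n)
    phi = np.stack([ch["phi"] for ch in chains])
    mu = np.stack([ch["mu"] for ch in chains])  # (c, kept, 2)
    sigma = np.stack([ch["sigma"] for ch in chains])
    draws: dict[str, np.ndarray] = {}
    for i, play in enumerate(plays):
        draws[f"gamma_plus[{play.subject_id}]"] = np.exp(theta[:, :, i])
        draws[f"beta[{play.subject_id}]"] = np.exp(phi[:, :, i])
    draws["mu_gamma"] = mu[:, :, 0]
    draws["mu_beta"] = mu[:, :, 1]
    draws["sigma_gamma"] = sigma[:, :, 0]
    draws["sigma_beta"] = sigma[:, :, 1]
    # population mean exp(mu + sigma^2/2), plus the finite-cohort average
    draws["group_mean_gamma"] = np.exp(mu[:, :, 0] + 0.5 * sigma[:, :, 0] ** 2)
    draws["group_mean_beta"] = np.exp(mu[:, :, 1] + 0.5 * sigma[:, :, 1] ** 2)
    draws["cohort_avg_gamma"] = np.exp(theta).mean(axis=2)
    draws["cohort_avg_beta"] = np.exp(phi).mean(axis=2)
    return draws


def _summarise(
    group: str,
    draws: dict[str, np.ndarray],
    subject_ids: list[str],
) -> pd.DataFrame:
    rows = []

    def row(level, subject_id, parameter, arr):
        flat = arr.reshape(-1)
        q25, q975 = np.quantile(flat, [0.025, 0.975])
        rows.append(
            {
                "level": level,
                "group": group,
                "subject_id": subject_id,
                "parameter": parameter,
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)),
                "q2.5": float(q25),
                "q97.5": float(q975),
                "rhat": split_rhat(arr),
                "ess": effective_sample_size(arr),
            }
        )

    for sid in subject_ids:
        row("individual", sid, "gamma_plus", draws[f"gamma_plus[{sid}]"])
        row("individual", sid, "beta", draws[f"beta[{sid}]"])
    for name in (
        "mu_gamma", "mu_beta", "sigma_gamma", "sigma_beta",
        "group_mean_gamma", "group_mean_beta",
        "cohort_avg_gamma", "cohort_avg_beta",
    ):
        row("group", "", name, draws[name])
    return pd.DataFrame(rows)


def fit_hierarchical(
    plays: list[SubjectPlay],
    spec: HierarchicalModelSpec | None = None,
    groups: list[str] | None = None,
) -> FitResult:
    """Fit the hierarchical model, independently per group.

    Parameters
    ----------
    plays
        Validated subject play records; every subject needs >= 1 trial.
    spec
        Priors and chain configuration; defaults are weakly informative.
    groups
        Optional explicit group labels (one per play) overriding the labels
        carried by the plays.

    Returns
    -------
    FitResult with a tidy summary table (individual and group levels), raw
    draws keyed by group, a diagnostics table and an overall convergence
    flag.  Failure to reach the R-hat threshold is reported via the flag and
    the diagnostics, never silently ignored.
    """
    if spec is None:
        spec = HierarchicalModelSpec()
    if not plays:
        raise ValueError("no subjects to fit")
    if groups is None:
        labels = [p.group for p in plays]
    else:
        if len(groups) != len(plays):
            raise ValueError("groups must have one label per play")
        labels = list(groups)
    # zero-trial subjects are allowed: their likelihood is empty, so their
    # posterior reduces to the hierarchical prior (prior-predictive checks)
    order = list(dict.fromkeys(labels))
    master = np.random.SeedSequence(spec.seed)
    group_seeds = master.spawn(len(order))
    all_draws: dict[str, dict[str, np.ndarray]] = {}
    summaries = []
    for g, gseed in zip(order, group_seeds):
        gplays = [p for p, lab in zip(plays, labels) if lab == g]
        draws = _fit_group(gplays, spec, gseed.spawn(spec.n_chains))
        all_draws[g] = draws
        summaries.append(_summarise(g, draws, [p.subject_id for p in gplays]))
    summary = pd.concat(summaries, ignore_index=True)

    diag_rows = []
    for g, draws in all_draws.items():
        rep = convergence_report(draws, rhat_threshold=spec.rhat_threshold)
        rep.insert(0, "group", g)
        diag_rows.append(rep)
    diagnostics = pd.concat(diag_rows, ignore_index=True)
    converged = bool(diagnostics["converged"].all())
    return FitResult(summary=summary, draws=all_draws,
                     diagnostics=diagnostics, converged=converged)


def point_estimates(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-subject posterior means as plain columns for the statistics stage."""
    ind = summary[summary["level"] == "individual"]
    wide = ind.pivot_table(
        index=["subject_id", "group"], columns="parameter", values="mean"
    ).reset_index()
    wide.columns.name = None
    return wide.rename(columns={"gamma_plus": "gamma_hat", "beta": "beta_hat"})[
        ["subject_id", "group", "gamma_hat", "beta_hat"]
    ]
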