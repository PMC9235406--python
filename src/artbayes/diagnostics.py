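"""MCMC convergence diagnostics: split R-hat and effective sample size."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["split_rhat", "effective_sample_size", "convergence_report"]


def _split_chains(draws: np.ndarray) -> np.ndarray:
    """Split each chain in half, giving a (2*chains, draws//2) array."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("draws must be (chains, iterations)")
    n = draws.shape[1] // 2
    return np.concatenate([draws[:, :n], draws[:, n : 2 * n]], axis=0)


def split_rhat(draws: np.ndarray) -> float:
    """Potential scale reduction factor on split chains.

    R-hat = sqrt(((n-1)/n * W + B/n) / W) with B the between-split-chain
    variance of means and W the mean within-chain variance (ddof=1).
    Requires at least 2 chains and 4 draws per chain.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need a (chains, iterations) array with >= 2 chains")
    if draws.shape[1] < 4:
        raise ValueError("need at least 4 draws per chain for split R-hat")
    split = _split_chains(draws)
    m, n = split.shape
    chain_means = split.mean(axis=1)
    b = n * chain_means.var(ddof=1)
    w = split.var(axis=1, ddof=1).mean()
    if w == 0.0:
        return 1.0 if b == 0.0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def effective_sample_size(draws: np.ndarray) -> float:
    """Bulk ESS from autocorrelations with Geyer's initial positive sequence.

    Autocovariances are estimated per split chain via FFT, combined across
    chains, and summed over consecutive lag pairs while the pair sums stay
    positive.
    """
    split = _split_chains(np.asarray(draws, dtype=float))
    m, n = split.shape
    if n < 4:
        raise ValueError("need at least 4 draws per chain")
    centered = split - split.mean(axis=1, keepdims=True)
    # FFT autocovariance per chain
    size = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, n=size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), n=size, axis=1)[:, :n].real / n
    w = split.var(axis=1, ddof=1).mean()
    chain_means = split.mean(axis=1)
    b_over_n = chain_means.var(ddof=1)
    var_plus = (n - 1) / n * w + b_over_n
    if var_plus == 0.0:
        return float(m * n)
    mean_acov = acov.mean(axis=0)
    rho = 1.0 - (w - mean_acov) / var_plus
    # Geyer initial monotone positive sequence over lag pairs
    tau = 1.0
    prev_pair = np.inf
    for t in range(1, n - 1, 2):
        pair = rho[t] + rho[t + 1] if t + 1 < n else rho[t]
        if pair < 0.0:
            break
        pair = min(pair, prev_pair)
        prev_pair = pair
        tau += 2.0 * pair
    return float(m * n / tau)


def convergence_report(
    draws: dict[str, np.ndarray],
    rhat_threshold: float = 1.05,
) -> pd.DataFrame:
    """Per-parameter split R-hat, ESS and a pass flag at the threshold.

    ``draws`` maps parameter name to a (chains, iterations) array; single
    chains are rejected because split R-hat across chains is undefined.
    """
    rows = []
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError(f"parameter {name!r}: need >= 2 chains")
        r = split_rhat(arr)
        ess = effective_sample_size(arr)
        rows.append(
            {"parameter": name, "rhat": r, "ess": ess,
             "converged": bool(r < rhat_threshold)}
        )
    return pd.DataFrame(rows)
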