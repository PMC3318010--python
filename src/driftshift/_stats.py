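"""Small shared statistical utilities: HPD intervals and marginal-likelihood
estimators on the natural-log scale."""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

__all__ = ["hpd_interval", "ln_harmonic_mean", "ln_stepping_stone"]


def hpd_interval(samples, mass: float = 0.95):
    """Shortest interval containing ``mass`` of an empirical sample.

    Ties are broken toward the interval with the smaller lower bound.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    k = max(1, int(np.ceil(mass * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 + np.arange(n - k + 1)] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first (smallest lower bound)
    return float(x[i]), float(x[i + k - 1])


def ln_harmonic_mean(ln_likelihoods) -> float:
    """Harmonic-mean estimator of the ln marginal likelihood.

    Computed from posterior-sample log likelihoods as
    ``ln N - logsumexp(-lnL)``. This estimator is notoriously high-variance
    (it can be dominated by a few low-likelihood draws); it is provided to
    mirror harmonic-mean-based Bayes-factor workflows, with
    :func:`ln_stepping_stone` as the better-behaved alternative.
    """
    lnl = np.asarray(ln_likelihoods, dtype=float)
    if lnl.size == 0 or not np.all(np.isfinite(lnl)):
        raise ValueError("ln likelihoods must be a non-empty finite array")
    return float(np.log(lnl.size) - logsumexp(-lnl))


def ln_stepping_stone(ln_likelihood_by_rung) -> float:
    """Stepping-stone ln marginal likelihood from power-posterior samples.

    ``ln_likelihood_by_rung`` maps inverse-temperature rungs
    ``0 = b_0 < b_1 < ... < b_K = 1`` to arrays of lnL sampled from the
    power posterior at that rung; the estimate sums
    ``logmeanexp((b_{k+1}-b_k) * lnL_k)`` over rungs (samples at b_K unused).
    """
    rungs = sorted(ln_likelihood_by_rung)
    if rungs[0] != 0.0 or rungs[-1] != 1.0:
        raise ValueError("rungs must span [0, 1]")
    total = 0.0
    for b0, b1 in zip(rungs[:-1], rungs[1:]):
        lnl = np.asarray(ln_likelihood_by_rung[b0], dtype=float)
        total += float(logsumexp((b1 - b0) * lnl) - np.log(lnl.size))
    return total
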