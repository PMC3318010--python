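"""Slow dense reference implementation of the two-tip likelihood.

Used only for validation: integrates the backward equations with a dense
transfer matrix (trapezoid quadrature of the Gaussian transition kernel,
row-normalized for mass conservation) and explicit Euler sub-steps for the
birth-death terms, on a much finer grid and time step than the production
FFT path. No code is shared with the fast implementation.
"""

from __future__ import annotations

import math

import numpy as np

from .quasse import QuasseParams

__all__ = ["dense_two_tip_loglik"]


def dense_two_tip_loglik(trait_a: float, trait_b: float, branch_t: float,
                         params: QuasseParams, lo: float, hi: float,
                         n_points: int, n_steps: int, tip_sd: float,
                         root_mode: str = "obs",
                         condition_surv: bool = True) -> float:
    """Log-likelihood of the tree (A:t,B:t); with traits a, b.

    Dense transfer-matrix integration: per time step, an explicit Euler
    update of the birth-death terms followed by multiplication with the
    quadrature matrix of the Gaussian drift-diffusion kernel.
    """
    x = np.linspace(lo, hi, n_points)
    dx = x[1] - x[0]
    lam = params.speciation(x)
    mu, s2, th = params.mu, params.sigma2, params.theta
    h = branch_t / n_steps

    # transfer matrix: row i gives E[f(x_i + theta h + z)], z ~ N(0, s2 h)
    kernel_sd = math.sqrt(s2 * h)
    diff = x[None, :] - (x[:, None] + th * h)
    T = np.exp(-0.5 * (diff / kernel_sd) ** 2)
    T *= dx / (kernel_sd * math.sqrt(2.0 * math.pi))
    T /= T.sum(axis=1, keepdims=True)  # conserve mass despite truncation

    def tip_density(trait):
        return np.exp(-0.5 * ((x - trait) / tip_sd) ** 2) / (
            tip_sd * math.sqrt(2.0 * math.pi))

    # Euler sub-steps for the stiff birth-death part within each kernel step
    n_sub = 20
    hs = h / n_sub
    E = np.zeros(n_points)
    DA, DB = tip_density(trait_a), tip_density(trait_b)
    for _ in range(n_steps):
        for _ in range(n_sub):
            dE = mu - (lam + mu) * E + lam * E * E
            DA = DA + hs * (-(lam + mu) * DA + 2.0 * lam * E * DA)
            DB = DB + hs * (-(lam + mu) * DB + 2.0 * lam * E * DB)
            E = np.clip(E + hs * dE, 0.0, 1.0)
        block = T @ np.vstack([E, DA, DB]).T
        E = np.clip(block[:, 0], 0.0, 1.0)
        DA = np.maximum(block[:, 1], 0.0)
        DB = np.maximum(block[:, 2], 0.0)

    D = DA * DB * lam
    total = np.trapezoid(D, dx=dx)
    if root_mode == "obs":
        w = D / total
    else:
        w = np.full(n_points, 1.0 / (hi - lo))
    value = np.trapezoid(w * D, dx=dx)
    if condition_surv:
        value /= np.trapezoid(w * lam * (1.0 - E) ** 2, dx=dx)
    return float(np.log(value))
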