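"""Reproducible simulation studies: drift recovery, null calibration, and
the lambda round trip.

These functions define the package's standard simulation experiments at
study scale (drift-linear generator, target 100 extant tips; see
:mod:`driftshift.synthetic` for the generator parameters). They are used
both as validation experiments and as the basis of the reported numbers.
"""

from __future__ import annotations

import random
from typing import Dict

import dendropy
import numpy as np
from scipy.stats import chi2 as chi2_dist

from .quasse import fit_battery
from .signal import fit_lambda
from .synthetic import (STUDY_ROOT_TRAIT, SimulationConfig,
                        simulate_quasse_forward, simulate_traits,
                        study_constant_params, study_drift_linear_params)
from .treeio import TraitTable

__all__ = [
    "drift_recovery_experiment",
    "null_calibration_experiment",
    "lambda_roundtrip_experiment",
]

# scaled numerical settings for the replicate grids: coarse but shared by
# every model within a replicate, so comparisons stay internally consistent
_FIT_KW = dict(grid_n=128, dt_frac=0.03, maxfun=80)


def drift_recovery_experiment(n_replicates: int = 50, seed: int = 0,
                              theta: float = 0.3, max_tips: int = 100,
                              progress: bool = False) -> Dict:
    """Simulate under drift-linear and refit {Full, Drift Linear} per tree.

    Returns the per-replicate ML drift estimates, their median, the fraction
    with the generating (positive) sign, and how often the drift model wins
    AIC against the constant-rate model.
    """
    gen = study_drift_linear_params(theta)
    thetas, dl_wins = [], []
    for r in range(n_replicates):
        sim_seed = (seed * 7919 + r) % (2**31 - 1)
        tree, traits = simulate_quasse_forward(
            gen, SimulationConfig(seed=sim_seed, x0=STUDY_ROOT_TRAIT,
                                  max_tips=max_tips))
        fits = fit_battery(tree, traits, models=["full", "drift-linear"],
                           seed=sim_seed, **_FIT_KW)
        thetas.append(fits["drift-linear"].params.theta)
        dl_wins.append(fits["drift-linear"].aic < fits["full"].aic)
        if progress:
            print(f"replicate {r}: theta_hat {thetas[-1]:+.3f} "
                  f"drift_wins {dl_wins[-1]}", flush=True)
    thetas = np.array(thetas)
    return {
        "theta_true": theta,
        "n_replicates": n_replicates,
        "theta_hat": thetas,
        "median_theta": float(np.median(thetas)),
        "frac_theta_positive": float(np.mean(thetas > 0)),
        "drift_aic_win_fraction": float(np.mean(dl_wins)),
    }


def null_calibration_experiment(n_replicates: int = 50, seed: int = 0,
                                max_tips: int = 100,
                                progress: bool = False) -> Dict:
    """Simulate under the constant-rate null and test drift vs Full.

    The likelihood-ratio statistic 2*(lnL_DL - lnL_Full) is referred to a
    chi-square with 2 degrees of freedom (slope + drift); returns the
    fraction of replicates exceeding the 5% critical value.
    """
    gen = study_constant_params()
    crit = float(chi2_dist.ppf(0.95, df=2))
    rejections = []
    for r in range(n_replicates):
        sim_seed = (seed * 104729 + r) % (2**31 - 1)
        tree, traits = simulate_quasse_forward(
            gen, SimulationConfig(seed=sim_seed, x0=STUDY_ROOT_TRAIT,
                                  max_tips=max_tips))
        fits = fit_battery(tree, traits, models=["full", "drift-linear"],
                           seed=sim_seed, **_FIT_KW)
        stat = 2.0 * (fits["drift-linear"].ln_likelihood
                      - fits["full"].ln_likelihood)
        rejections.append(stat > crit)
        if progress:
            print(f"null replicate {r}: chi2 {stat:.2f} reject {rejections[-1]}",
                  flush=True)
    return {
        "n_replicates": n_replicates,
        "critical_value": crit,
        "reject_fraction": float(np.mean(rejections)),
    }


def _yule_tree(n_tips: int, seed: int, birth_rate: float = 0.3):
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_tips,
        taxon_namespace=taxa, rng=random.Random(seed))
    # break the zero-length cherry left by stopping exactly at an event
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += 0.02 / birth_rate
    return tree


def lambda_roundtrip_experiment(n_replicates: int = 100, seed: int = 0,
                                n_tips: int = 50, sigma2: float = 0.1) -> Dict:
    """Brownian traits on a fixed tree recover lambda ~ 1; shuffling the
    traits across tips destroys the signal (lambda ~ 0)."""
    tree = _yule_tree(n_tips, seed=seed + 1)
    rng = np.random.default_rng(seed)
    high, low = [], []
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    for r in range(n_replicates):
        traits = simulate_traits(tree, sigma2=sigma2, lam=1.0,
                                 x0=STUDY_ROOT_TRAIT,
                                 seed=(seed * 613 + r) % (2**31 - 1))
        res = fit_lambda(tree, traits, mode="ml")
        high.append(res.lam)
        vals = list(traits.values.values())
        rng.shuffle(vals)
        shuffled = TraitTable(dict(zip(labels, vals)))
        low.append(fit_lambda(tree, shuffled, mode="ml").lam)
    high, low = np.array(high), np.array(low)
    return {
        "n_replicates": n_replicates,
        "lambda_brownian": high,
        "lambda_shuffled": low,
        "frac_brownian_ge_0.9": float(np.mean(high >= 0.9)),
        "frac_shuffled_le_0.1": float(np.mean(low <= 0.1)),
    }
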