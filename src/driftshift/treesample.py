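"""Run the model battery over a Bayesian tree sample and aggregate.

Each tree of the sample is fitted independently (the sample encodes
phylogenetic uncertainty; no joint inference across trees). Aggregates:
per-model mean drift with its 95% HPD across trees, and a sample-level
Bayes-factor matrix on the 2*Delta(mean lnL) scale, supplemented by the
fraction of trees each model wins by AIC so the sample-level conclusion is
checkable two ways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._stats import hpd_interval
from .errors import ValidationError
from .quasse import MODEL_KINDS, QuasseFit, fit_quasse
from .treeio import TraitTable, TreeSample

__all__ = [
    "SampleFitTable",
    "DriftSummary",
    "SampleBfMatrix",
    "fit_over_sample",
    "aggregate_drift",
    "sample_bayes_factor",
    "sample_bf_matrix",
]


@dataclass
class SampleFitTable:
    """Per (tree index, model) fits over a tree sample."""

    fits: Dict[Tuple[int, str], QuasseFit]
    n_trees: int
    models: List[str]
    failures: List[Tuple[int, str, str]] = field(default_factory=list)

    def fit(self, tree_index: int, model: str) -> QuasseFit:
        return self.fits[(tree_index, model)]

    def lnl_array(self, model: str) -> np.ndarray:
        return np.array([self.fits[(i, model)].ln_likelihood
                         for i in range(self.n_trees)])

    def theta_array(self, model: str) -> np.ndarray:
        return np.array([self.fits[(i, model)].params.theta
                         for i in range(self.n_trees)])

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for (i, m), f in sorted(self.fits.items()):
            rows.append({
                "tree": i, "model": m, "Df": f.df, "LnLik": f.ln_likelihood,
                "AIC": f.aic, "Drift": f.params.theta if f.drift else np.nan,
                "sigma2": f.params.sigma2, "mu": f.params.mu,
            })
        return pd.DataFrame(rows)


@dataclass
class DriftSummary:
    """Mean drift and 95% HPD of per-tree ML theta estimates, per model."""

    mean_theta: Dict[str, float]
    hpd: Dict[str, Tuple[float, float]]
    skew_note: Dict[str, str]

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.mean_theta:
            lo, hi = self.hpd[m]
            rows.append({"model": m, "mean_drift": self.mean_theta[m],
                         "hpd_lo": lo, "hpd_hi": hi, "note": self.skew_note[m]})
        return pd.DataFrame(rows)


@dataclass
class SampleBfMatrix:
    """Pairwise sample-level Bayes factors (2*Delta mean-lnL scale)."""

    models: List[str]
    matrix: np.ndarray           # antisymmetric
    aic_win_fraction: Dict[str, float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.models, columns=self.models)


def fit_over_sample(sample: TreeSample, traits: TraitTable,
                    models: Sequence[str] = MODEL_KINDS,
                    seed: int = 0, max_failure_fraction: float = 0.10,
                    **fit_kwargs) -> SampleFitTable:
    """Fit each requested model on each tree of the sample independently.

    Per-tree failures are recorded, not fatal, unless more than
    ``max_failure_fraction`` of all (tree, model) fits fail. Results do not
    depend on execution order; the per-fit seed is derived from ``seed`` and
    the (tree, model) cell.
    """
    models = list(models)
    bad = set(models) - set(MODEL_KINDS)
    if bad:
        raise ValidationError(f"unknown models: {sorted(bad)}")
    fits, failures = {}, []
    for i, tree in enumerate(sample):
        for j, m in enumerate(models):
            cell_seed = (seed * 100_003 + i * 101 + j) % (2**31 - 1)
            try:
                fits[(i, m)] = fit_quasse(tree, traits, m, seed=cell_seed,
                                          **fit_kwargs)
            except Exception as e:  # recorded per contract
                failures.append((i, m, f"{type(e).__name__}: {e}"))
    total = len(sample) * len(models)
    if len(failures) > max_failure_fraction * total:
        raise ValidationError(
            f"{len(failures)}/{total} fits failed (> {max_failure_fraction:.0%}); "
            f"first failure: {failures[0]}"
        )
    if failures:
        warnings.warn(f"{len(failures)} of {total} fits failed; they are "
                      "recorded in SampleFitTable.failures")
    return SampleFitTable(fits=fits, n_trees=len(sample), models=models,
                          failures=failures)


def aggregate_drift(table: SampleFitTable, mass: float = 0.95) -> DriftSummary:
    """Mean and shortest 95% interval of per-tree theta, per drift model."""
    drift_models = [m for m in table.models if m.startswith("drift-")]
    if not drift_models:
        raise ValidationError("aggregate_drift requires at least one drift model")
    mean_t, hpd, note = {}, {}, {}
    for m in drift_models:
        th = table.theta_array(m)
        mean_t[m] = float(np.mean(th))
        lo, hi = hpd_interval(th, mass)
        hpd[m] = (lo, hi)
        note[m] = "" if lo <= mean_t[m] <= hi else "skewed: mean outside HPD"
    return DriftSummary(mean_theta=mean_t, hpd=hpd, skew_note=note)


def sample_bayes_factor(table: SampleFitTable, m1: str, m2: str) -> float:
    """BF = 2 * (mean-over-trees lnL_m1 - mean-over-trees lnL_m2)."""
    for m in (m1, m2):
        if m not in table.models:
            raise ValidationError(f"model {m!r} not present in the fit table")
    missing = [(i, m) for m in (m1, m2) for i in range(table.n_trees)
               if (i, m) not in table.fits]
    if missing:
        raise ValidationError(f"missing fits for cells {missing[:5]}")
    return float(2.0 * (table.lnl_array(m1).mean() - table.lnl_array(m2).mean()))


def sample_bf_matrix(table: SampleFitTable) -> SampleBfMatrix:
    """Full antisymmetric BF matrix plus per-model AIC win fractions."""
    ms = table.models
    k = len(ms)
    M = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            bf = sample_bayes_factor(table, ms[i], ms[j])
            M[i, j], M[j, i] = bf, -bf
    aics = np.stack([np.array([table.fits[(t, m)].aic for m in ms])
                     for t in range(table.n_trees)])
    winners = np.argmin(aics, axis=1)
    win_frac = {m: float(np.mean(winners == i)) for i, m in enumerate(ms)}
    return SampleBfMatrix(models=list(ms), matrix=M, aic_win_fraction=win_frac)
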