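"""Synthetic generators with the statistical structure the analysis assumes.

Three generators: (1) forward-time trait-dependent birth-death simulation
with drift-diffusion character evolution, returning the reconstructed
ultrametric tree of extant tips plus their traits; (2) multivariate-normal
tip traits on a fixed tree under the lambda-scaled Brownian covariance;
(3) Jukes-Cantor DNA alignments of tunable divergence for the saturation
diagnostic. Everything is driven by explicit seeds: a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import dendropy
import numpy as np

from .errors import SimulationExtinctError, ValidationError
from .quasse import QuasseParams
from .signal import lambda_transform, phylo_covariance
from .treeio import Phylogeny, TraitTable, assert_ultrametric

__all__ = [
    "SimulationConfig",
    "simulate_quasse_forward",
    "simulate_traits",
    "simulate_alignment",
    "study_drift_linear_params",
    "study_constant_params",
    "STUDY_ROOT_TRAIT",
]

#: Root trait for the study-scale generators: ln(90 mm), a mid-sized rodent.
STUDY_ROOT_TRAIT = 4.5


def study_drift_linear_params(theta: float = 0.3):
    """Drift-linear generator at the package's study scales.

    Speciation 0.45/Myr at the root state rising by 0.4 per ln-mm,
    extinction 0.05/Myr, diffusion 0.08 ln-mm^2/Myr, drift +0.3 ln-mm/Myr:
    the scales of a recent small-mammal radiation (tens of species within
    ~10 Myr, body lengths spanning roughly 60-250 mm).
    """
    from .quasse import QuasseParams, SpeciationFunction

    return QuasseParams(
        speciation=SpeciationFunction("linear", {"a": -1.35, "b": 0.4}),
        mu=0.05, sigma2=0.08, theta=theta,
    )


def study_constant_params():
    """Constant-rate (null) generator matched to the drift-linear scales."""
    from .quasse import QuasseParams, SpeciationFunction

    return QuasseParams(
        speciation=SpeciationFunction("constant", {"c": 0.45}),
        mu=0.05, sigma2=0.08, theta=0.0,
    )


@dataclass
class SimulationConfig:
    """Forward birth-death simulation settings.

    ``dt`` is the Euler step (Myr); if None it defaults to 0.005 of the
    expected depth implied by the stop condition. Exactly one of
    ``max_tips`` / ``max_time`` must be the binding stop condition
    (``max_time`` may also cap a tip-count run).
    """

    seed: int = 0
    x0: float = 0.0                 # root trait, ln mm
    max_tips: Optional[int] = None  # stop when this many extant lineages exist
    max_time: Optional[float] = None
    dt: Optional[float] = None
    max_attempts: int = 100         # retries after total extinction

    def __post_init__(self):
        if self.max_tips is None and self.max_time is None:
            raise ValidationError("need a stop condition: max_tips or max_time")
        if self.dt is not None and self.dt <= 0:
            raise ValidationError("time step must be > 0")


def _default_dt(params: QuasseParams, cfg: SimulationConfig) -> float:
    lam0 = float(params.speciation(np.array([cfg.x0]))[0])
    lam0 = max(lam0, 1e-3)
    if cfg.max_time is not None:
        horizon = cfg.max_time
    else:
        horizon = math.log(max(cfg.max_tips, 3)) / lam0
    return 0.005 * horizon


def _attempt(params: QuasseParams, cfg: SimulationConfig, rng) -> Tuple[Phylogeny, TraitTable]:
    dt = cfg.dt if cfg.dt is not None else _default_dt(params, cfg)
    fn, mu, s2, th = params.speciation, params.mu, params.sigma2, params.theta
    sig_dt = math.sqrt(s2 * dt)

    # per-lineage records: parent index, birth time, death time (nan = alive)
    parent = [-1]
    t_birth = [0.0]
    t_death = [math.nan]
    trait = np.array([cfg.x0])
    alive = [0]
    t = 0.0
    guard_steps = 0
    # Once the tip-count target is reached the process keeps running until
    # just before the *next* event: stopping exactly at the triggering
    # speciation would place a node at the present and bias rate estimates
    # ("pull of the present" artifact).
    extending = False
    while True:
        n_alive = len(alive)
        if n_alive == 0:
            raise SimulationExtinctError("all lineages extinct", attempts=1)
        if cfg.max_tips is not None and n_alive >= cfg.max_tips:
            extending = True
        if cfg.max_time is not None and t >= cfg.max_time:
            break
        guard_steps += 1
        if guard_steps > 5_000_000:
            raise ValidationError("simulation exceeded the step guard; check rates")
        x = trait[alive]
        lam = fn(x)
        # first-order Euler: cap per-step event probabilities at 0.1 by
        # refining the step locally
        pmax = float(np.max(lam) + mu) * dt
        sub = max(1, int(math.ceil(pmax / 0.1)))
        h = dt / sub
        stop = False
        for _ in range(sub):
            x = trait[alive]
            lam = fn(x)
            u = rng.random(len(alive))
            p_spec = lam * h
            p_ext = mu * h
            speciate = u < p_spec
            extinct = (u >= p_spec) & (u < p_spec + p_ext)
            if extending and (speciate.any() or extinct.any()):
                stop = True  # stop just before the first post-target event
                break
            # character update for survivors
            trait[alive] = x + th * h + rng.normal(0.0, math.sqrt(s2 * h), len(alive))
            t += h
            if extinct.any():
                for i in np.nonzero(extinct)[0]:
                    t_death[alive[i]] = t
            if speciate.any():
                for i in np.nonzero(speciate)[0]:
                    pa = alive[i]
                    t_death[pa] = t
                    for _c in range(2):
                        parent.append(pa)
                        t_birth.append(t)
                        t_death.append(math.nan)
                        trait = np.append(trait, trait[pa])
            if speciate.any() or extinct.any():
                drop = set(np.nonzero(speciate | extinct)[0])
                kept = [a for j, a in enumerate(alive) if j not in drop]
                alive = kept + list(range(len(parent) - 2 * int(speciate.sum()),
                                          len(parent)))
            if cfg.max_tips is not None and len(alive) >= cfg.max_tips:
                extending = True
            if len(alive) == 0:
                raise SimulationExtinctError("all lineages extinct", attempts=1)
            if cfg.max_time is not None and t >= cfg.max_time:
                stop = True
                break
        if stop:
            break

    # reconstructed tree: lineages with extant descendants only
    stop_time = t
    n = len(parent)
    extant = [math.isnan(t_death[i]) for i in range(n)]
    keep = list(extant)
    children = [[] for _ in range(n)]
    for i in range(1, n):
        children[parent[i]].append(i)
    for i in range(n - 1, -1, -1):  # children have larger indices than parents
        if any(keep[c] for c in children[i]):
            keep[i] = True
    if not keep[0]:
        raise SimulationExtinctError("no extant descendants", attempts=1)

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    node_of = {}
    tip_traits = {}
    tip_no = [0]

    def build(i):
        nd = dendropy.Node()
        node_of[i] = nd
        kids = [c for c in children[i] if keep[c]]
        end = t_death[i] if not math.isnan(t_death[i]) else stop_time
        if not kids:
            tip_no[0] += 1
            label = f"t{tip_no[0]}"
            nd.taxon = taxon_ns.new_taxon(label)
            tip_traits[label] = float(trait_final[i])
        for c in kids:
            child = build(c)
            child.edge.length = (t_death[c] if not math.isnan(t_death[c]) else stop_time) - t_birth[c]
            nd.add_child(child)
        return nd

    trait_final = trait
    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * n + 1000))
    try:
        root = build(0)
    finally:
        sys.setrecursionlimit(old_limit)
    tree.seed_node = root
    # collapse the unary pass-through nodes left after pruning
    tree.suppress_unifurcations()
    traits = TraitTable({k: v for k, v in tip_traits.items()})
    return tree, traits


def simulate_quasse_forward(params: QuasseParams, cfg: SimulationConfig
                            ) -> Tuple[Phylogeny, TraitTable]:
    """Forward-time simulation of the trait-dependent birth-death process.

    Per lineage per step the trait takes a drift-diffusion increment
    ``theta dt + N(0, sigma2 dt)``; the lineage speciates with probability
    ``lambda_S(x) dt`` and goes extinct with probability ``mu dt`` (per-step
    probabilities capped at 0.1 by automatic local step refinement). The
    returned tree is the reconstructed tree of extant tips (extinct lineages
    pruned), ultrametric by construction, with tip traits at the stop time.

    Raises :class:`SimulationExtinctError` (with the attempt count) if the
    process dies out ``cfg.max_attempts`` times in a row.
    """
    rng = np.random.default_rng(cfg.seed)
    last = None
    for attempt in range(1, cfg.max_attempts + 1):
        try:
            tree, traits = _attempt(params, cfg, rng)
        except SimulationExtinctError as e:
            last = e
            continue
        if len(tree.leaf_nodes()) >= 2:
            return tree, traits
        last = SimulationExtinctError("fewer than 2 extant tips", attempts=attempt)
    raise SimulationExtinctError(
        f"simulation went extinct in all {cfg.max_attempts} attempts",
        attempts=cfg.max_attempts,
    ) from last


def simulate_traits(tree: Phylogeny, sigma2: float, lam: float, x0: float,
                    seed: int = 0) -> TraitTable:
    """Tip traits from N(x0 * 1, sigma2 * V_lambda) on an ultrametric tree."""
    assert_ultrametric(tree)
    if not (0.0 <= lam <= 1.0):
        raise ValidationError("lambda must lie in [0, 1]")
    if sigma2 < 0:
        raise ValidationError("sigma2 must be >= 0")
    V = lambda_transform(phylo_covariance(tree), lam)
    rng = np.random.default_rng(seed)
    n = len(V.labels)
    if sigma2 == 0:
        y = np.full(n, x0)
    else:
        M = sigma2 * V.matrix
        try:
            L = np.linalg.cholesky(M + 1e-12 * np.trace(M) / n * np.eye(n))
        except np.linalg.LinAlgError as e:
            raise ValidationError("transformed covariance is not positive definite") from e
        y = x0 + L @ rng.standard_normal(n)
    return TraitTable(dict(zip(V.labels, map(float, y))))


_BASES = np.array(list("ACGT"))


def simulate_alignment(tree: Phylogeny, rate: float, length: int, seed: int = 0):
    """Jukes-Cantor site-by-site simulation down a tree.

    ``rate`` is in substitutions/site/Myr; the root sequence is uniform over
    {A, C, G, T}. Returns a dict species label -> sequence string (the
    alignment container used by :mod:`driftshift.diagnostics`).
    """
    if length < 1:
        raise ValidationError("alignment length must be >= 1")
    if rate < 0:
        raise ValidationError("substitution rate must be >= 0")
    rng = np.random.default_rng(seed)
    seqs = {}
    root_states = rng.integers(0, 4, size=length)

    # P(change to each specific other base) under JC over branch length t
    def evolve(states, t):
        p_diff = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * t))
        u = rng.random(length)
        change = u < p_diff
        if change.any():
            shift = rng.integers(1, 4, size=int(change.sum()))
            states = states.copy()
            states[change] = (states[change] + shift) % 4
        return states

    stack = [(tree.seed_node, root_states)]
    while stack:
        node, states = stack.pop()
        for child in node.child_nodes():
            child_states = evolve(states, child.edge.length or 0.0)
            if child.is_leaf():
                seqs[child.taxon.label] = "".join(_BASES[child_states])
            else:
                stack.append((child, child_states))
    return seqs
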