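"""Pre-analysis diagnostics: entropy-based substitution saturation (Iss vs
Iss.c) and the node-density artifact test (beta*, delta).

Saturation. Site-wise Shannon entropy of the base frequencies measures how
scrambled an alignment is; fully saturated sequences approach the entropy of
independent draws from the overall base composition. The observed saturation
index Iss is the mean site entropy divided by that full-saturation
expectation (estimated by column-wise randomization preserving base
composition). The critical index Iss.c -- the saturation level at which
phylogenetic structure stops being recoverable -- is calibrated here by
Monte Carlo: alignments are simulated on a balanced symmetric topology over
a ladder of divergences and Iss.c is the Iss at which neighbor-joining
split recovery drops through 95%. The calibration is this module's own
(the published tables of the original tool are not reproduced exactly) and
is recorded in the result metadata.

Node density. Trees inferred with sparse taxon sampling can show spuriously
short paths in sparsely sampled regions. Fitting node count n = beta * x**delta
against root-to-tip path length x detects this: no artifact when beta is
significantly positive and delta <= 1. Perfectly ultrametric trees (all x
equal) are not testable and return a not-applicable result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import optimize, stats

from .errors import ValidationError
from .treeio import Phylogeny, TreeSample, tip_path_profile

__all__ = [
    "Alignment",
    "SaturationResult",
    "NodeDensityResult",
    "read_alignment",
    "saturation_test",
    "node_density_test",
    "node_density_over_sample",
]

_ALPHABET = set("ACGT-N")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class Alignment:
    """Equal-length DNA sequences over {A, C, G, T, -, N} keyed by species."""

    sequences: Dict[str, str]

    def __post_init__(self):
        if len(self.sequences) < 4:
            raise ValidationError("alignment needs at least 4 sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValidationError(f"unequal sequence lengths: {sorted(lengths)}")
        for name, s in self.sequences.items():
            bad = set(s.upper()) - _ALPHABET
            if bad:
                raise ValidationError(f"{name!r}: illegal characters {sorted(bad)}")
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def matrix(self) -> np.ndarray:
        """(sequences x sites) integer matrix; -1 for gaps/ambiguity."""
        out = np.full((self.n_sequences, self.length), -1, dtype=np.int8)
        for i, s in enumerate(self.sequences.values()):
            out[i] = [_BASE_INDEX.get(c, -1) for c in s]
        return out


def read_alignment(path: str, format: str = "fasta") -> Alignment:
    """Read a FASTA or Nexus alignment via Biopython."""
    from Bio import AlignIO

    aln = AlignIO.read(path, format)
    return Alignment({rec.id: str(rec.seq) for rec in aln})


@dataclass
class SaturationResult:
    iss: float
    iss_c: float
    p_value: float
    n_otu: int
    n_sites: int
    saturated: bool
    metadata: dict = field(default_factory=dict)


@dataclass
class NodeDensityResult:
    applicable: bool
    beta: Optional[float] = None
    delta: Optional[float] = None
    beta_p_value: Optional[float] = None
    artifact: Optional[bool] = None
    note: str = ""


def _site_entropies(M: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) of base frequencies per column; gaps ignored."""
    n_sites = M.shape[1]
    H = np.zeros(n_sites)
    for j in range(n_sites):
        col = M[:, j]
        col = col[col >= 0]
        if col.size == 0:
            continue
        counts = np.bincount(col, minlength=4).astype(float)
        p = counts[counts > 0] / counts.sum()
        H[j] = float(-(p * np.log(p)).sum())
    return H


def _full_saturation_entropy(M: np.ndarray, replicates: int, rng) -> float:
    """Mean site entropy when every column is an iid draw from the overall
    base composition (the full-saturation expectation)."""
    flat = np.sort(M[M >= 0])  # sorted: invariant to sequence order
    n_seq, n_sites = M.shape
    vals = []
    for _ in range(replicates):
        draw = rng.choice(flat, size=(n_seq, n_sites))
        vals.append(_site_entropies(draw).mean())
    return float(np.mean(vals))


def _balanced_tree(n_taxa: int, branch: float):
    import dendropy

    taxa = [f"x{i}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)

    def build(lo, hi):
        nd = dendropy.Node()
        nd.edge.length = branch
        if hi - lo == 1:
            nd.taxon = ns.get_taxon(taxa[lo])
        else:
            mid = (lo + hi) // 2
            nd.add_child(build(lo, mid))
            nd.add_child(build(mid, hi))
        return nd

    root = dendropy.Node()
    mid = n_taxa // 2
    root.add_child(build(0, mid))
    root.add_child(build(mid, n_taxa))
    tree.seed_node = root
    return tree


def _nj_split_recovery(aln_dict: Dict[str, str], true_tree) -> float:
    """Fraction of true internal splits recovered by neighbor joining on
    Jukes-Cantor distances."""
    import dendropy
    from skbio import DistanceMatrix
    from skbio.tree import nj

    names = list(aln_dict)
    k = len(names)
    arrs = {n: np.frombuffer(aln_dict[n].encode(), dtype=np.uint8) for n in names}
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            p = float(np.mean(arrs[names[i]] != arrs[names[j]]))
            p = min(p, 0.7499)
            d = -0.75 * math.log(1.0 - 4.0 / 3.0 * p)
            D[i, j] = D[j, i] = d
    import io

    est = nj(DistanceMatrix(D, ids=names))
    buf = io.StringIO()
    est.write(buf, format="newick")
    est_newick = buf.getvalue()
    tns = true_tree.taxon_namespace
    est_dp = dendropy.Tree.get(data=est_newick, schema="newick",
                               taxon_namespace=tns)
    true_b = {b.split_bitmask for b in _nontrivial_bipartitions(true_tree)}
    est_b = {b.split_bitmask for b in _nontrivial_bipartitions(est_dp)}
    if not true_b:
        return 1.0
    return len(true_b & est_b) / len(true_b)


def _nontrivial_bipartitions(tree):
    tree.encode_bipartitions()
    n = len(tree.taxon_namespace)
    out = []
    for b in tree.bipartition_encoding:
        size = bin(b.split_bitmask).count("1")
        if 1 < size < n - 1:
            out.append(b)
    return out


def _calibrate_iss_c(n_otu: int, n_sites: int, replicates: int, rng) -> float:
    """Monte-Carlo Iss.c: Iss at the divergence where NJ split recovery on a
    balanced symmetric topology crosses 95%."""
    from .synthetic import simulate_alignment

    n_taxa = 1 << max(2, min(5, int(math.log2(max(n_otu, 4)))))  # 4..32, 2^k
    sites = int(min(max(n_sites, 100), 600))
    reps = max(3, replicates // 64)
    branches = np.array([0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2])
    iss_level, recov_level = [], []
    for br in branches:
        tree = _balanced_tree(n_taxa, br)
        iss_vals, rec_vals = [], []
        for r in range(reps):
            seed = int(rng.integers(0, 2**31 - 1))
            aln = simulate_alignment(tree, rate=1.0, length=sites, seed=seed)
            M = Alignment(aln).matrix()
            h = _site_entropies(M).mean()
            hfss = _full_saturation_entropy(M, 3, rng)
            iss_vals.append(h / hfss if hfss > 0 else 0.0)
            rec_vals.append(_nj_split_recovery(aln, tree))
        iss_level.append(float(np.mean(iss_vals)))
        recov_level.append(float(np.mean(rec_vals)))
    iss_level = np.array(iss_level)
    recov_level = np.array(recov_level)
    # walk up the divergence ladder to the first crossing below 95% recovery
    for i in range(1, len(branches)):
        if recov_level[i] < 0.95 <= recov_level[i - 1]:
            f = (recov_level[i - 1] - 0.95) / (recov_level[i - 1] - recov_level[i])
            return float(iss_level[i - 1] + f * (iss_level[i] - iss_level[i - 1]))
    if recov_level[0] < 0.95:  # already unrecoverable at the lowest divergence
        return float(iss_level[0])
    return float(iss_level[-1])    # never lost: critical index at the top


def saturation_test(aln: Alignment, replicates: int = 1000, seed: int = 0
                    ) -> SaturationResult:
    """Entropy-based substitution-saturation test.

    Iss is the mean site entropy relative to the full-saturation expectation;
    Iss.c the Monte-Carlo critical value for this OTU count and length; the
    p-value is a one-sample t-test of the per-site saturation ratios against
    Iss.c (small p with Iss < Iss.c means significantly unsaturated).
    """
    import warnings as _warnings

    rng = np.random.default_rng(seed)
    M = aln.matrix()
    if aln.length < 50:
        _warnings.warn("alignment shorter than 50 sites: saturation test has "
                       "little power")
    h_sites = _site_entropies(M)
    h_fss = _full_saturation_entropy(M, max(10, replicates // 50), rng)
    if h_fss <= 0:
        raise ValidationError("degenerate alignment: zero full-saturation entropy")
    ratios = h_sites / h_fss
    iss = float(ratios.mean())
    iss_c = _calibrate_iss_c(aln.n_sequences, aln.length, replicates, rng)
    t, p = stats.ttest_1samp(ratios, iss_c)
    return SaturationResult(
        iss=iss, iss_c=iss_c, p_value=float(p), n_otu=aln.n_sequences,
        n_sites=aln.length, saturated=not (iss < iss_c and p < 0.05),
        metadata={
            "seed": seed, "replicates": replicates,
            "note": ("Iss.c from in-package Monte-Carlo calibration "
                     "(balanced topology, NJ split recovery at 95%); "
                     "not numerically identical to the original tool"),
        },
    )


def node_density_test(tree: Phylogeny, permutations: int = 1000, seed: int = 0
                      ) -> NodeDensityResult:
    """Fit node count n = beta * x**delta against root-to-tip path length x.

    beta significance is assessed by permuting node counts against path
    lengths (association test); verdict: no artifact iff beta significantly
    positive and delta <= 1.
    """
    prof = tip_path_profile(tree)
    x, n = prof.path_lengths, prof.node_counts.astype(float)
    if len(x) < 4:
        raise ValidationError("node-density test needs >= 4 tips")
    spread = np.unique(np.round(x, 10))
    if len(spread) < 3:
        return NodeDensityResult(
            applicable=False,
            note="fewer than 3 distinct root-to-tip path lengths (tree is "
                 "effectively ultrametric); node-density test not applicable",
        )

    def model(xv, beta, delta):
        return beta * np.power(xv, delta)

    try:
        (beta, delta), _ = optimize.curve_fit(
            model, x, n, p0=[n.mean() / max(x.mean(), 1e-9), 1.0],
            maxfev=10000)
    except RuntimeError:
        return NodeDensityResult(applicable=False, note="power-law fit failed")

    rng = np.random.default_rng(seed)
    if np.ptp(n) == 0:
        # constant node counts: no association to test
        p_beta = 1.0
    else:
        obs = stats.pearsonr(x, n).statistic
        perm = np.empty(permutations)
        n_perm = n.copy()
        for i in range(permutations):
            rng.shuffle(n_perm)
            perm[i] = np.corrcoef(x, n_perm)[0, 1]
        p_beta = float((1 + np.sum(perm >= obs)) / (permutations + 1))
    return NodeDensityResult(
        applicable=True, beta=float(beta), delta=float(delta),
        beta_p_value=p_beta,
        artifact=not (p_beta < 0.05 and beta > 0 and delta <= 1.0),
    )


def node_density_over_sample(sample: TreeSample, permutations: int = 200,
                             seed: int = 0) -> dict:
    """Percentages of trees in each (beta significant) x (delta <= 1) cell."""
    cells = {"sig_delta_le1": 0, "sig_delta_gt1": 0,
             "nonsig_delta_le1": 0, "nonsig_delta_gt1": 0, "not_applicable": 0}
    for i, tree in enumerate(sample):
        res = node_density_test(tree, permutations=permutations,
                                seed=seed + i)
        if not res.applicable:
            cells["not_applicable"] += 1
            continue
        sig = res.beta_p_value < 0.05 and res.beta > 0
        le1 = res.delta <= 1.0
        key = ("sig" if sig else "nonsig") + ("_delta_le1" if le1 else "_delta_gt1")
        cells[key] += 1
    total = len(sample)
    return {k: 100.0 * v / total for k, v in cells.items()}
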