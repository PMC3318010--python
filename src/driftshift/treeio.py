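"""Tree and trait-table I/O plus the path/node structure used downstream.

Trees are handled as :class:`dendropy.Tree` objects with branch lengths in
millions of years (Myr). All trait analyses in this package require rooted,
ultrametric, time-calibrated trees; this module is where those contracts are
enforced so that downstream likelihood code can assume them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import dendropy
import numpy as np
import pandas as pd

from .errors import TreeFormatError, UltrametricityError, ValidationError

__all__ = [
    "Phylogeny",
    "TreeSample",
    "TraitTable",
    "TipPathProfile",
    "read_tree",
    "read_tree_sample",
    "write_tree",
    "read_trait_table",
    "write_trait_table",
    "assert_ultrametric",
    "tip_path_profile",
    "tree_depth",
]

#: A rooted phylogeny with branch lengths in Myr.
Phylogeny = dendropy.Tree

# Default relative tolerance on tip-depth spread: Bayesian posterior samples
# carry floating-point jitter at roughly this level.
DEFAULT_ULTRAMETRIC_RTOL = 1e-3


@dataclass
class TreeSample:
    """An ordered sample of trees over one common tip set.

    Typically a Bayesian posterior sample, a consensus tree, or an ML tree;
    ``provenance`` records which.
    """

    trees: List[Phylogeny]
    provenance: str = "posterior"

    def __post_init__(self):
        if len(self.trees) < 1:
            raise ValidationError("TreeSample requires at least one tree")
        ref = tip_labels(self.trees[0])
        for i, t in enumerate(self.trees[1:], start=1):
            if tip_labels(t) != ref:
                raise ValidationError(
                    f"tree {i} has a different tip set from tree 0 "
                    f"({sorted(tip_labels(t) ^ ref)} differ)"
                )

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @property
    def taxa(self) -> set:
        return tip_labels(self.trees[0])


@dataclass
class TraitTable:
    """Species -> trait value (ln mm), with optional measurement SD (ln mm)."""

    values: Dict[str, float]
    sd: Optional[Dict[str, float]] = None

    def __post_init__(self):
        for k, v in self.values.items():
            if not math.isfinite(v):
                raise ValidationError(f"non-finite trait value for {k!r}")
        if self.sd is not None:
            for k, v in self.sd.items():
                if not (math.isfinite(v) and v >= 0):
                    raise ValidationError(f"invalid trait sd for {k!r}")

    def __len__(self):
        return len(self.values)

    def __getitem__(self, label):
        return self.values[label]

    def labels(self) -> List[str]:
        return list(self.values)

    def vector(self, order: List[str]) -> np.ndarray:
        try:
            return np.array([self.values[l] for l in order], dtype=float)
        except KeyError as e:
            raise ValidationError(f"trait table missing species {e.args[0]!r}") from e

    def covers(self, labels) -> bool:
        return set(labels) <= set(self.values)


@dataclass
class TipPathProfile:
    """Per-tip root-to-tip path length and internal-node count.

    The node count includes the root and excludes the tip itself, so a star
    tree gives every tip count 1: it counts the speciation events witnessed
    along the path.
    """

    labels: List[str]
    path_lengths: np.ndarray
    node_counts: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tip": self.labels, "path_length": self.path_lengths, "nodes": self.node_counts}
        )


def tip_labels(tree: Phylogeny) -> set:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _validate_tree(tree: Phylogeny, index: int = 0) -> None:
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(l is None for l in labels):
        raise ValidationError(f"tree {index}: unlabeled tip")
    if len(labels) != len(set(labels)):
        raise ValidationError(f"tree {index}: duplicate tip labels")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        el = node.edge.length
        if el is None:
            raise ValidationError(f"tree {index}: missing branch length")
        if not math.isfinite(el) or el < 0:
            raise ValidationError(f"tree {index}: invalid branch length {el}")


def read_tree(path: str, format: str = "newick") -> Phylogeny:
    """Read a single rooted tree (first tree in the file)."""
    return read_tree_sample(path, format=format).trees[0]


def read_tree_sample(path: str, format: str = "newick", provenance: str = "posterior") -> TreeSample:
    """Read all trees from a Newick or Nexus file into a :class:`TreeSample`.

    Nexus TRANSLATE tables are resolved by the reader. All trees must share
    one tip-label set; a mismatch raises :class:`ValidationError` naming the
    offending tree.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    try:
        tl = dendropy.TreeList.get(path=path, schema=format, rooting="default-rooted")
    except Exception as e:  # dendropy raises several parse error types
        raise TreeFormatError(f"could not parse {path!r} as {format}: {e}") from e
    if len(tl) == 0:
        raise TreeFormatError(f"no trees found in {path!r}")
    trees = []
    for i, t in enumerate(tl):
        _validate_tree(t, i)
        trees.append(t)
    return TreeSample(trees=trees, provenance=provenance)


def write_tree(tree: Phylogeny, path: str, format: str = "newick") -> None:
    tree.write(path=path, schema=format, suppress_rooting=True,
               real_value_format_specifier=".12g")


def read_trait_table(path: str) -> TraitTable:
    """Read a trait table: TSV, ``species<TAB>value[<TAB>sd]``, '#' comments."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
    if df.shape[1] < 2:
        raise ValidationError(f"{path!r}: expected at least two tab-separated columns")
    labels = df[0].tolist()
    if len(labels) != len(set(labels)):
        raise ValidationError(f"{path!r}: duplicate species labels")
    values = dict(zip(labels, df[1].astype(float)))
    sd = None
    if df.shape[1] >= 3 and not df[2].isna().all():
        sd = dict(zip(labels, df[2].astype(float)))
    return TraitTable(values=values, sd=sd)


def write_trait_table(table: TraitTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# species\ttrait_ln_mm" + ("\tsd" if table.sd else "") + "\n")
        for k, v in table.values.items():
            if table.sd:
                fh.write(f"{k}\t{v:.10g}\t{table.sd[k]:.10g}\n")
            else:
                fh.write(f"{k}\t{v:.10g}\n")


def _tip_depths(tree: Phylogeny) -> Dict[str, float]:
    depths = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


def tree_depth(tree: Phylogeny) -> float:
    """Mean root-to-tip distance."""
    return float(np.mean(list(_tip_depths(tree).values())))


def assert_ultrametric(tree: Phylogeny, rel_tol: float = DEFAULT_ULTRAMETRIC_RTOL) -> float:
    """Check that all tips are equidistant from the root; return the depth.

    The depth returned is the mean root-to-tip distance; every tip must lie
    within ``rel_tol * depth`` of it.
    """
    if len(tree.leaf_nodes()) < 2:
        raise ValidationError("ultrametricity check requires >= 2 tips")
    depths = _tip_depths(tree)
    mean_depth = float(np.mean(list(depths.values())))
    worst_tip, worst_dev = None, 0.0
    for label, d in depths.items():
        dev = abs(d - mean_depth)
        if dev > worst_dev:
            worst_dev, worst_tip = dev, label
    if mean_depth <= 0:
        raise UltrametricityError("tree has zero depth", worst_tip, worst_dev)
    if worst_dev > rel_tol * mean_depth:
        raise UltrametricityError(
            f"tree is not ultrametric: tip {worst_tip!r} deviates by "
            f"{worst_dev:.6g} from mean depth {mean_depth:.6g} "
            f"(rel_tol={rel_tol})",
            worst_tip,
            worst_dev,
        )
    return mean_depth


def tip_path_profile(tree: Phylogeny) -> TipPathProfile:
    """Root-to-tip path length and internal-node count per tip.

    Counts internal nodes on the path including the root, excluding the tip.
    """
    labels, lengths, counts = [], [], []
    for leaf in tree.leaf_node_iter():
        d, n = 0.0, 0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length
            node = node.parent_node
            n += 1  # each parent passed is an internal node on the path
        labels.append(leaf.taxon.label)
        lengths.append(d)
        counts.append(n)
    return TipPathProfile(
        labels=labels,
        path_lengths=np.array(lengths, dtype=float),
        node_counts=np.array(counts, dtype=int),
    )
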