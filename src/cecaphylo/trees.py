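"""Phylogenies, branch-length assignment schemes, and phylogenetic covariance.

Trees are :class:`dendropy.Tree` objects throughout; this module adds the
operations the comparative analysis needs on top of them:

* parsing/writing newick and nexus with validation (unique tips, nonnegative
  branch lengths, a single root);
* Pagel's arbitrary-ultrametric branch lengths and unity branch lengths, the
  two schemes used when a composite topology carries no usable branch-length
  information;
* the Brownian-motion variance-covariance matrix ``C`` (shared root-to-MRCA
  path lengths) and its transformations under the evolution models compared
  in the regression ladder: statistical independence, Brownian motion,
  Ornstein-Uhlenbeck, and Pagel's lambda.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np


class TreeError(ValueError):
    """Malformed or invalid phylogeny."""


# ---------------------------------------------------------------------------
# parsing / writing / validation
# ---------------------------------------------------------------------------

def parse_tree(text: str, schema: str | None = None) -> dendropy.Tree:
    """Parse a rooted phylogeny from a newick string or a nexus TREES block.

    The schema is auto-detected (``#NEXUS`` header => nexus) unless given.
    Trees are treated as rooted; polytomies are retained.

    Raises
    ------
    TreeError
        On malformed input (message names the position where the reader
        failed) or duplicate/empty tip labels.
    """
    if schema is None:
        schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema=schema,
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise TreeError(f"could not parse {schema} tree: {exc}") from exc
    validate_tree(tree)
    return tree


def read_tree(path) -> dendropy.Tree:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_tree(fh.read())


def write_tree(tree: dendropy.Tree, path=None, schema: str = "newick") -> str:
    """Serialize a tree; returns the string and optionally writes ``path``."""
    text = tree.as_string(schema=schema, suppress_rooting=(schema == "newick"))
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def validate_tree(tree: dendropy.Tree) -> None:
    labels = tip_labels(tree)
    if any(lab is None or str(lab).strip() == "" for lab in labels):
        raise TreeError("tip labels must be nonempty")
    seen, dupes = set(), set()
    for lab in labels:
        if lab in seen:
            dupes.add(lab)
        seen.add(lab)
    if dupes:
        raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeError(f"negative branch length {edge.length} on edge to "
                            f"{edge.head_node.taxon.label if edge.head_node.is_leaf() else 'internal node'}")
    zero_terminals = [lf.taxon.label for lf in tree.leaf_node_iter()
                      if lf.edge.length == 0]
    if zero_terminals:
        warnings.warn(f"zero-length terminal branches: {zero_terminals}",
                      stacklevel=2)


# ---------------------------------------------------------------------------
# branch-length schemes
# ---------------------------------------------------------------------------

def pagel_branch_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign arbitrary ultrametric ("time-proportional") branch lengths.

    Every internal edge gets length 1 and each terminal edge is stretched so
    that all tips sit at the same depth, equal to the maximum number of edges
    on any root-to-tip path.  This is the scheme used for composite
    topologies whose source trees carry no branch-length information; the
    output is exactly ultrametric.  Input branch lengths are ignored.
    """
    if tree.is_rooted is False:
        raise TreeError("Pagel branch lengths require a rooted tree")
    out = tree.clone(depth=1)
    rank = {out.seed_node: 0}
    max_depth = 0
    for node in out.preorder_node_iter():
        if node is out.seed_node:
            continue
        rank[node] = rank[node.parent_node] + 1
        if node.is_leaf():
            max_depth = max(max_depth, rank[node])
    for node in out.preorder_node_iter():
        if node is out.seed_node:
            node.edge.length = None
        elif node.is_leaf():
            node.edge.length = float(max_depth - rank[node.parent_node])
        else:
            node.edge.length = 1.0
    return out


def unity_branches(tree: dendropy.Tree) -> dendropy.Tree:
    """Set every edge length to exactly 1 (topology unchanged)."""
    out = tree.clone(depth=1)
    for node in out.preorder_node_iter():
        node.edge.length = None if node is out.seed_node else 1.0
    return out


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length for every tip (missing lengths count as 0)."""
    depth = {tree.seed_node: 0.0}
    out = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            out[node.taxon.label] = depth[node]
    return out


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-12) -> bool:
    depths = list(tip_depths(tree).values())
    return max(depths) - min(depths) <= tol


# ---------------------------------------------------------------------------
# evolution models and covariance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvolutionModel:
    """Residual-evolution model used to weight the GLS fit.

    kind
        ``independent`` (no phylogenetic structure), ``brownian`` (covariance
        grows linearly with shared history), ``ou`` (correlation decays
        exponentially with patristic distance at rate ``alpha``), or
        ``lambda`` (off-diagonal shrinkage by ``lam``).
    """

    kind: str
    alpha: float | None = None
    lam: float | None = None

    _KINDS = ("independent", "brownian", "ou", "lambda")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; "
                             f"expected one of {self._KINDS}")
        if self.kind == "ou":
            # alpha=None means "profile alpha by ML" in the GLS fitter
            if self.alpha is not None and self.alpha <= 0:
                raise ValueError("OU model requires alpha > 0")
        if self.kind == "lambda":
            if self.lam is None or self.lam < 0:
                raise ValueError("lambda model requires lam >= 0")

    @classmethod
    def independent(cls) -> "EvolutionModel":
        return cls("independent")

    @classmethod
    def brownian(cls) -> "EvolutionModel":
        return cls("brownian")

    @classmethod
    def ou(cls, alpha: float) -> "EvolutionModel":
        return cls("ou", alpha=alpha)

    @classmethod
    def pagel(cls, lam: float) -> "EvolutionModel":
        return cls("lambda", lam=lam)


@dataclass
class PhyloCovariance:
    """Among-species covariance implied by a tree: C_ij = depth of MRCA(i,j)."""

    taxa: list[str]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("covariance shape does not match taxa")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def reorder(self, taxa: list[str]) -> "PhyloCovariance":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(list(taxa), self.matrix[np.ix_(idx, idx)])

    def patristic(self) -> np.ndarray:
        """Tip-to-tip path-length matrix: d_ij = C_ii + C_jj - 2 C_ij."""
        d = np.diag(self.matrix)
        return d[:, None] + d[None, :] - 2.0 * self.matrix

    def write_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa).to_csv(
            path, sep="\t")


def vcv(tree: dendropy.Tree) -> PhyloCovariance:
    """Brownian-motion variance-covariance matrix of a rooted tree.

    ``C_ij`` is the path length from the root to the most recent common
    ancestor of tips *i* and *j*; the diagonal holds tip depths.  Polytomies
    are handled natively.
    """
    validate_tree(tree)
    taxa = tip_labels(tree)
    index = {lab: k for k, lab in enumerate(taxa)}
    n = len(taxa)
    C = np.zeros((n, n))
    depth = {tree.seed_node: 0.0}
    tipsets: dict = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            k = index[node.taxon.label]
            C[k, k] = depth[node]
            tipsets[node] = [k]
        else:
            children = [tipsets.pop(ch) for ch in node.child_nodes()]
            d = depth[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        C[i, children[b]] = d
                        C[children[b], i] = d
            tipsets[node] = [i for ch in children for i in ch]
    return PhyloCovariance(taxa, C)


def lam_max(C: PhyloCovariance) -> float:
    """Largest lambda keeping the off-diagonal shrinkage interpretable.

    Defined as max(diag C) / max(off-diag C), which permits values slightly
    above 1 on near-ultrametric trees.  Infinite on a star phylogeny (all
    off-diagonals zero), where lambda is unidentifiable anyway.
    """
    M = C.matrix
    off = M[~np.eye(C.n, dtype=bool)]
    m = off.max(initial=0.0)
    if m <= 0:
        return np.inf
    return float(np.diag(M).max() / m)


def transform_covariance(C: PhyloCovariance,
                         model: EvolutionModel) -> PhyloCovariance:
    """Apply an evolution model to a Brownian covariance matrix.

    independent -> keep the diagonal only; brownian -> unchanged;
    lambda -> multiply off-diagonals by ``lam`` (diagonal untouched);
    ou -> correlation matrix exp(-alpha * d_ij) on patristic distances,
    with a unit diagonal (the stationary-variance scale is absorbed into
    the GLS residual variance).
    """
    M = C.matrix
    if model.kind == "brownian":
        out = M.copy()
    elif model.kind == "independent":
        out = np.diag(np.diag(M)).copy()
    elif model.kind == "lambda":
        lmax = lam_max(C)
        if model.lam > lmax:
            raise ValueError(f"lambda {model.lam} exceeds lam_max {lmax:.6g}")
        out = M * model.lam
        np.fill_diagonal(out, np.diag(M))
    elif model.kind == "ou":
        if model.alpha is None:
            raise ValueError("OU transform requires a fixed alpha > 0")
        out = np.exp(-model.alpha * C.patristic())
        np.fill_diagonal(out, 1.0)
    else:  # pragma: no cover - guarded by EvolutionModel
        raise ValueError(model.kind)
    return PhyloCovariance(list(C.taxa), out)
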