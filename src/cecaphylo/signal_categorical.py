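"""Phylogenetic signal in categorical traits: parsimony length and the PTP test.

The permutation tail probability (PTP) test asks whether a multistate
character needs fewer evolutionary steps on the study tree than on random
trees.  Steps are counted by unordered (unit-cost) parsimony; the null
distribution maps the observed character onto random pure-birth (Yule)
topologies of depth 10 — branch lengths are irrelevant to the step count,
but the depth matches the randomization setting used for the study.  The
p-value is the fraction of permutations whose length is <= the observed
length; when that count is zero the convention p = 10 / n_perm is reported
rather than an exact zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .trees import TreeError, tip_labels, validate_tree


def fitch_length(tree: dendropy.Tree, states) -> int:
    """Minimum number of unordered state changes explaining the tip states.

    ``states`` maps each tip label to a (hashable) state, or is a sequence in
    the tree's tip order.  Polytomies are scored exactly: at a node whose m
    children carry candidate-state sets, each state is counted across the
    child sets, the node keeps the states attaining the maximum count k, and
    m - k changes are charged.  On bifurcating trees this reduces to the
    familiar intersection/union rule; the count is invariant to branch
    lengths.
    """
    labels = tip_labels(tree)
    if not isinstance(states, Mapping):
        if len(states) != len(labels):
            raise ValueError("state sequence length does not match tip count")
        states = dict(zip(labels, states))
    missing = [lab for lab in labels if lab not in states]
    if missing:
        raise ValueError(f"missing tip states for: {missing[:5]}")

    steps = 0
    node_sets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node_sets[node] = frozenset([states[node.taxon.label]])
        else:
            counts: dict = {}
            children = node.child_nodes()
            for ch in children:
                for s in node_sets.pop(ch):
                    counts[s] = counts.get(s, 0) + 1
            k = max(counts.values())
            steps += len(children) - k
            node_sets[node] = frozenset(s for s, c in counts.items() if c == k)
    return steps


def yule_tree(n_tips: int, depth: float = 10.0, seed=None, rng=None,
              taxon_labels: Sequence[str] | None = None) -> dendropy.Tree:
    """Simulate a pure-birth tree rescaled to a fixed root-to-tip depth.

    Lineages split at unit rate with exponential waiting times; the lineage
    that splits is chosen uniformly, which yields the Yule distribution over
    labeled topologies.  After the last split one further waiting time sets
    the present, then all node times are rescaled so every tip sits at
    ``depth``.  Tip labels are a random permutation of ``taxon_labels``
    (defaults to ``t1..tn``).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed) if rng is None else rng
    if taxon_labels is None:
        taxon_labels = [f"t{i + 1}" for i in range(n_tips)]
    elif len(set(taxon_labels)) != n_tips:
        raise ValueError("taxon_labels must be n_tips unique labels")

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = True
    birth = {tree.seed_node: 0.0}
    t = 0.0
    active = []
    for _ in range(2):
        ch = tree.seed_node.new_child()
        birth[ch] = 0.0
        active.append(ch)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(rng.integers(len(active)))
        node.edge.length = t - birth[node]
        for _ in range(2):
            ch = node.new_child()
            birth[ch] = t
            active.append(ch)
    present = t + rng.exponential(1.0 / len(active))
    for node in active:
        node.edge.length = present - birth[node]

    scale = depth / present
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= scale

    perm = rng.permutation(n_tips)
    leaves = [node for node in tree.leaf_node_iter()]
    for node, j in zip(leaves, perm):
        node.taxon = taxon_namespace.require_taxon(str(taxon_labels[j]))
    return tree


def ptp_pvalue(observed: int, null_lengths: np.ndarray, n_perm: int) -> float:
    """Counting rule: p = #{null <= observed} / n_perm, with the small-p
    convention p = 10 / n_perm when the count is zero."""
    count = int(np.sum(np.asarray(null_lengths) <= observed))
    if count == 0:
        return 10.0 / n_perm
    return count / n_perm


@dataclass
class PTPResult:
    observed_steps: int
    null_lengths: np.ndarray = field(repr=False)
    n_perm: int
    p_value: float
    seed: int | None
    null_scheme: str

    def significant(self, threshold: float = 0.05) -> bool:
        return self.p_value < threshold

    def __str__(self) -> str:
        return (f"PTP: observed {self.observed_steps} steps, "
                f"null {self.null_lengths.min()}-{self.null_lengths.max()} "
                f"over {self.n_perm} permutations, p = {self.p_value:.4g}")


def ptp_test(tree: dendropy.Tree, states, n_perm: int = 9999,
             seed: int | None = None,
             null_scheme: str = "random_yule_topology") -> PTPResult:
    """Permutation tail probability test for one categorical character.

    null_scheme
        ``random_yule_topology`` (default): recount the character on
        independent Yule topologies over the same taxa, depth 10.
        ``shuffle_tip_states``: classical permutation of states across the
        tips of the observed tree.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if null_scheme not in ("random_yule_topology", "shuffle_tip_states"):
        raise ValueError(f"unknown null scheme {null_scheme!r}")
    validate_tree(tree)
    labels = tip_labels(tree)
    if not isinstance(states, Mapping):
        states = dict(zip(labels, states))
    observed = fitch_length(tree, states)

    if len(set(states[lab] for lab in labels)) < 2:
        warnings.warn("single-state character: PTP test is uninformative",
                      stacklevel=2)
        return PTPResult(observed_steps=0,
                         null_lengths=np.zeros(n_perm, dtype=int),
                         n_perm=n_perm, p_value=1.0, seed=seed,
                         null_scheme=null_scheme)

    rng = np.random.default_rng(seed)
    null_lengths = np.empty(n_perm, dtype=int)
    if null_scheme == "random_yule_topology":
        for b in range(n_perm):
            rand_tree = yule_tree(len(labels), depth=10.0, rng=rng,
                                  taxon_labels=labels)
            null_lengths[b] = fitch_length(rand_tree, states)
    else:
        values = [states[lab] for lab in labels]
        for b in range(n_perm):
            perm = rng.permutation(len(labels))
            shuffled = {labels[i]: values[perm[i]] for i in range(len(labels))}
            null_lengths[b] = fitch_length(tree, shuffled)

    p = ptp_pvalue(observed, null_lengths, n_perm)
    return PTPResult(observed_steps=observed, null_lengths=null_lengths,
                     n_perm=n_perm, p_value=p, seed=seed,
                     null_scheme=null_scheme)
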