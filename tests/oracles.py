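"""Brute-force reference implementations used only to cross-check the package.

These stay deliberately independent of the library's algorithms: parsimony
length by Sankoff dynamic programming over explicit per-state cost vectors,
and GLS coefficients by direct normal equations with explicit inverses.
"""

import numpy as np

from cecaphylo.trees import tip_labels


def sankoff_length(tree, states) -> int:
    """Exact unit-cost unordered parsimony length by dynamic programming.

    cost[node][s] = minimum changes in node's subtree if node is in state s;
    for each child the transition adds min_t(cost[child][t] + [s != t]).
    Handles polytomies natively.
    """
    state_space = sorted(set(states.values()))
    idx = {s: i for i, s in enumerate(state_space)}
    k = len(state_space)
    INF = 10 ** 9
    cost = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            v = np.full(k, INF)
            v[idx[states[node.taxon.label]]] = 0
        else:
            v = np.zeros(k)
            for ch in node.child_nodes():
                c = cost.pop(ch)
                # min over child state: stay free, switch costs 1
                v = v + np.minimum(c, c.min() + 1)
        cost[node] = v
    return int(cost[tree.seed_node].min())


def ols_oracle(y, X, V=None):
    """Normal-equations GLS: beta = (X'V^-1 X)^-1 X'V^-1 y via explicit
    inverses (numerically naive on purpose), plus sigma2_ml = r'V^-1 r / n."""
    n = len(y)
    Vi = np.eye(n) if V is None else np.linalg.inv(V)
    XtVi = X.T @ Vi
    beta = np.linalg.inv(XtVi @ X) @ (XtVi @ y)
    r = y - X @ beta
    sigma2 = (r @ Vi @ r) / n
    return beta, sigma2
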