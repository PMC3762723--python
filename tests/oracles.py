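"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own pruning/message-passing code
paths: ancestral states come from an explicit linear solve, and the root
estimate from an explicit covariance-matrix GLS.
"""

import numpy as np

from pelagia.trees import node_ages, tree_to_graph


def gls_ancestral_states(tree, tip_values):
    """Joint ML ancestral states by an explicit (Laplacian) linear solve.

    Minimizes sum over edges of (x_i - x_j)^2 / length with tips fixed;
    for a Gaussian (Brownian) model the joint mode equals the marginal
    (re-rooted contrasts) estimates.
    """
    adj, leaves, internals = tree_to_graph(tree)
    idx = {lab: i for i, lab in enumerate(internals)}
    A = np.zeros((len(internals), len(internals)))
    b = np.zeros(len(internals))
    for lab in internals:
        i = idx[lab]
        for nbr, length in adj[lab]:
            w = 1.0 / length
            A[i, i] += w
            if nbr in idx:
                A[i, idx[nbr]] -= w
            else:
                b[i] += w * tip_values[nbr]
    x = np.linalg.solve(A, b)
    return {lab: x[idx[lab]] for lab in internals}


def gls_root_estimate(tree, tip_values):
    """Root state by explicit GLS with the BM tip covariance matrix."""
    depths = {}
    for node in tree.preorder_node_iter():
        depths[node.label] = (
            0.0
            if node.parent_node is None
            else depths[node.parent_node.label] + (node.edge.length or 0.0)
        )
    ancestors = {}
    for leaf in tree.leaf_node_iter():
        chain, nd = [], leaf
        while nd is not None:
            chain.append(nd.label)
            nd = nd.parent_node
        ancestors[leaf.taxon.label] = chain
    leaves = sorted(ancestors)
    n = len(leaves)
    C = np.zeros((n, n))
    for i, li in enumerate(leaves):
        for j, lj in enumerate(leaves):
            common = next(lab for lab in ancestors[li] if lab in set(ancestors[lj]))
            C[i, j] = depths[common]
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    y = np.array([tip_values[l] for l in leaves])
    return float(one @ Ci @ y / (one @ Ci @ one))


def uniform_record(rng, origin, end, n, family="sim"):
    """A fossil record of n horizons uniform on the true range."""
    from pelagia.fossilrec import FamilyFossilRecord

    ages = rng.uniform(end, origin, size=n)
    return FamilyFossilRecord(family=family, horizons=tuple(sorted(ages, reverse=True)))
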