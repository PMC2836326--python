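"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's pruning/outside-pass machinery:
likelihoods are computed by exhaustive enumeration of interior-node state
assignments, and bootstrap distributions by exhaustive multinomial
enumeration, so they can certify the fast implementations.
"""

import itertools
from math import factorial

import numpy as np
from scipy.linalg import expm

from mitophylo.alignment import tip_partials
from mitophylo.treeio import TreeIndex


def enum_site_lnl(tree, taxa, matrix, params) -> np.ndarray:
    """Per-site log-likelihood by summing over all interior-node states."""
    tind = TreeIndex(tree, taxa)
    q_matrix = params.rate_matrix()
    cats = params.gamma_rates()
    tp = tip_partials(matrix)
    internal = [i for i in range(tind.n_nodes) if tind.children[i]]
    out = np.empty(matrix.shape[1])
    for s in range(matrix.shape[1]):
        per_cat = []
        for r in cats:
            pmats = [expm(q_matrix * tind.lengths[i] * r * params.blen_multiplier)
                     for i in range(tind.n_nodes)]
            total = 0.0
            for assign in itertools.product(range(4), repeat=len(internal)):
                st = dict(zip(internal, assign))
                pr = params.pi[st[tind.root]]
                for i in range(tind.n_nodes):
                    p = tind.parent[i]
                    if p == -1:
                        continue
                    if tind.children[i]:
                        pr *= pmats[i][st[p], st[i]]
                    else:
                        pr *= float(pmats[i][st[p]] @ tp[tind.tip_row[i], s])
                total += pr
            per_cat.append(total)
        out[s] = np.log(np.mean(per_cat))
    return out


def enum_mk_marginals(tree, taxa, trait, model):
    """Joint-likelihood marginals by enumerating interior-node states.

    Returns (marginals: clade -> length-k vector, total likelihood).
    """
    tind = TreeIndex(tree, taxa)
    k = model.k
    q_mk = np.full((k, k), model.q)
    np.fill_diagonal(q_mk, -(k - 1) * model.q)
    pmats = [expm(q_mk * tind.lengths[i]) for i in range(tind.n_nodes)]
    internal = [i for i in range(tind.n_nodes) if tind.children[i]]
    tipvec = {}
    for i in range(tind.n_nodes):
        if not tind.children[i]:
            state = trait.get(taxa[tind.tip_row[i]])
            v = np.ones(k)
            if state is not None and not (isinstance(state, float) and np.isnan(state)):
                v = np.zeros(k)
                v[int(state)] = 1.0
            tipvec[i] = v
    joint = {i: np.zeros(k) for i in internal}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = dict(zip(internal, assign))
        pr = 1.0 / k
        for i in range(tind.n_nodes):
            p = tind.parent[i]
            if p == -1:
                continue
            if tind.children[i]:
                pr *= pmats[i][st[p], st[i]]
            else:
                pr *= float(pmats[i][st[p]] @ tipvec[i])
        total += pr
        for i in internal:
            joint[i][st[i]] += pr
    marg = {}
    for i in internal:
        clade = tuple(sorted(lf.taxon.label for lf in tind.nodes[i].leaf_iter()))
        marg[clade] = joint[i] / total
    return marg, total


def enum_rell_proportions(table: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Exact RELL win proportions by enumerating every multinomial resample."""
    n_trees, m = table.shape
    n_draw = max(1, int(round(scale * m)))
    probs = np.zeros(n_trees)
    for counts in itertools.product(range(n_draw + 1), repeat=m):
        if sum(counts) != n_draw:
            continue
        w = factorial(n_draw)
        for c in counts:
            w //= factorial(c)
        p = w * (1.0 / m) ** n_draw
        sums = table @ np.array(counts, dtype=float)
        best = sums.max()
        ties = sums >= best - 1e-9 * max(1.0, abs(best))
        probs += p * ties / ties.sum()
    return probs
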