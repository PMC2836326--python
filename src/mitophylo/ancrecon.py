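"""Mk1 maximum-likelihood marginal ancestral-state reconstruction.

The Mk1 model is the k-state, single-rate generalisation of Jukes-Cantor:
every change between distinct states occurs at the same instantaneous rate
q, giving the closed-form transition probabilities

    P_stay(t)   = 1/k + (k-1)/k * exp(-k q t)
    P_change(t) = 1/k -   1/k * exp(-k q t)

Marginal reconstruction combines, at each node, the likelihood of the data
below the node (downward pass) with the likelihood of the rest of the tree
(outside pass, equivalent to rerooting at the node), under a uniform root
prior. Used here for the 4-state male sexual-parasitism character of
ceratioid anglerfishes (0 = males never attach, 1 = temporary attachment,
2 = facultative parasites, 3 = obligate parasites), but fully generic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

#: Two states whose marginal probabilities differ by less than this are
#: reported as an equivocal reconstruction at that node.
EQUIVOCAL_MARGIN = 0.05


@dataclass
class MkModel:
    k: int
    q: float

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.q < 0:
            raise ValueError("q must be >= 0")


def mk_transition_matrix(model: MkModel, t: float) -> np.ndarray:
    """k x k transition probability matrix after duration t >= 0."""
    if t < 0:
        raise ValueError("branch duration must be >= 0")
    k, q = model.k, model.q
    e = np.exp(-k * q * t)
    stay = 1.0 / k + (k - 1.0) / k * e
    change = 1.0 / k - e / k
    p = np.full((k, k), change)
    np.fill_diagonal(p, stay)
    return p


def _tip_vector(state, k: int) -> np.ndarray:
    if state is None or (isinstance(state, float) and np.isnan(state)) or state is pd.NA:
        return np.ones(k)
    s = int(state)
    if not 0 <= s < k:
        raise ValueError(f"state {s} outside 0..{k - 1}")
    v = np.zeros(k)
    v[s] = 1.0
    return v


def _down_partials(tree: dendropy.Tree, trait: pd.Series, model: MkModel) -> dict[int, np.ndarray]:
    """Conditional likelihoods of the data at/below each node given its state."""
    down: dict[int, np.ndarray] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label
            down[id(nd)] = _tip_vector(trait.get(label), model.k)
        else:
            v = np.ones(model.k)
            for child in nd.child_nodes():
                p = mk_transition_matrix(model, child.edge.length or 0.0)
                v = v * (p @ down[id(child)])
            down[id(nd)] = v
    return down


def mk_log_likelihood(tree: dendropy.Tree, trait: pd.Series, model: MkModel) -> float:
    """Pruning log-likelihood of the trait under Mk1 with a uniform root prior."""
    down = _down_partials(tree, trait, model)
    root = down[id(tree.seed_node)]
    with np.errstate(divide="ignore"):
        return float(np.log(root.mean()))  # uniform prior 1/k folds into the mean


@dataclass
class Mk1Fit:
    model: MkModel
    log_likelihood: float
    at_boundary: bool = False


def fit_mk1(tree: dendropy.Tree, trait: pd.Series, k: int | None = None,
            q_max: float | None = None) -> Mk1Fit:
    """Maximise the Mk1 likelihood over the single rate q (bounded 1-D search).

    With fewer than two distinct observed states the optimum is the q = 0
    boundary (no change required anywhere) and lnL = ln(1/k).
    """
    observed = [int(s) for s in trait.dropna()]
    if k is None:
        k = max(observed) + 1 if observed else 2
    if len(set(observed)) < 2:
        return Mk1Fit(MkModel(k=k, q=0.0), float(np.log(1.0 / k)), at_boundary=True)
    tree_len = sum(nd.edge.length or 0.0 for nd in tree if nd.parent_node is not None)
    if q_max is None:
        q_max = max(100.0 / max(tree_len, 1e-9), 10.0)

    def neg(q: float) -> float:
        return -mk_log_likelihood(tree, trait, MkModel(k=k, q=q))

    # optimise on the log scale: the likelihood peak can be orders of
    # magnitude narrower than the saturation plateau in linear q
    res = minimize_scalar(lambda x: neg(np.exp(x)),
                          bounds=(np.log(1e-9), np.log(q_max)),
                          method="bounded", options={"xatol": 1e-10})
    q_hat, lnl = float(np.exp(res.x)), -float(res.fun)
    # the bounded optimiser cannot land exactly on 0; check the boundary
    lnl0 = -neg(0.0)
    if lnl0 >= lnl:
        return Mk1Fit(MkModel(k=k, q=0.0), lnl0, at_boundary=True)
    return Mk1Fit(MkModel(k=k, q=q_hat), lnl,
                  at_boundary=q_hat <= 2e-9 or q_hat >= q_max * (1 - 1e-6))


@dataclass
class AncestralReconstruction:
    """Normalised marginal state probabilities for every node."""

    model: MkModel
    log_likelihood: float
    node_probs: dict[int, np.ndarray]          # id(node) -> length-k vector
    clades: dict[int, tuple[str, ...]]         # id(node) -> sorted leaf labels
    equivocal: dict[int, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, probs in self.node_probs.items():
            row = {"clade": ",".join(self.clades[key]),
                   "equivocal": self.equivocal.get(key, False)}
            row.update({f"P{s}": p for s, p in enumerate(probs)})
            rows.append(row)
        return pd.DataFrame(rows)


def marginal_ancestral_states(tree: dendropy.Tree, trait: pd.Series,
                              model: MkModel) -> AncestralReconstruction:
    """Marginal probability of each state at each node.

    The outside pass propagates, root to tips, the likelihood of everything
    not below a node; the marginal at a node is the normalised product of
    its inside and outside vectors. A node is flagged equivocal when its two
    best states are within EQUIVOCAL_MARGIN of each other.
    """
    k = model.k
    down = _down_partials(tree, trait, model)
    outside: dict[int, np.ndarray] = {id(tree.seed_node): np.full(k, 1.0 / k)}
    for nd in tree.preorder_node_iter():
        for child in nd.child_nodes():
            # sibling contributions seen from the parent's state
            contrib = outside[id(nd)].copy()
            for sib in nd.child_nodes():
                if sib is child:
                    continue
                p_sib = mk_transition_matrix(model, sib.edge.length or 0.0)
                contrib = contrib * (p_sib @ down[id(sib)])
            p_child = mk_transition_matrix(model, child.edge.length or 0.0)
            outside[id(child)] = p_child.T @ contrib
    total = float(down[id(tree.seed_node)] @ outside[id(tree.seed_node)])
    node_probs, clades, equivocal = {}, {}, {}
    for nd in tree.postorder_node_iter():
        joint = down[id(nd)] * outside[id(nd)]
        probs = joint / joint.sum()
        key = id(nd)
        node_probs[key] = probs
        clades[key] = tuple(sorted(lf.taxon.label for lf in nd.leaf_iter()))
        top2 = np.sort(probs)[-2:]
        equivocal[key] = bool(top2[1] - top2[0] < EQUIVOCAL_MARGIN)
    return AncestralReconstruction(model=model, log_likelihood=float(np.log(total)),
                                   node_probs=node_probs, clades=clades,
                                   equivocal=equivocal)


def reconstruct(tree: dendropy.Tree, trait: pd.Series, k: int | None = None) -> AncestralReconstruction:
    """Fit q by ML, then compute marginal ancestral states."""
    fit = fit_mk1(tree, trait, k=k)
    return marginal_ancestral_states(tree, trait, fit.model)


def load_trait_csv(path) -> pd.Series:
    """Read a taxon,state CSV (missing cells allowed) into a Series."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    return pd.Series(df[cols[1]].values, index=df[cols[0]].values, name="state")
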