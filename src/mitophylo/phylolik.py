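"""Partitioned pruning likelihood (GTR/F84 + discrete gamma) and tree search.

Per-site log-likelihoods are computed by Felsenstein's pruning algorithm
with per-node rescaling (so deep trees cannot underflow), a discrete-gamma
mixture over site rates, and independent model parameters per partition.
Branch lengths are shared across partitions up to a per-partition
multiplier. On top of the engine sit coordinate-wise branch-length
optimisation, a best-improving NNI hill-climb (with neighbour-joining
starting trees), and branch-length covariance estimation from the observed
Fisher information, which feeds the relaxed-clock dating stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import PartitionedAlignment, tip_partials
from .substmodels import EigenSystem, SubstModelParams
from .treeio import TreeIndex, jc_distance_matrix, nj_tree

ParamSpec = "SubstModelParams | dict[str, SubstModelParams]"


def _params_by_label(aln: PartitionedAlignment, params) -> dict[str, SubstModelParams]:
    labels = [lab for lab, n in aln.partition_counts().items() if n]
    if isinstance(params, SubstModelParams):
        return {lab: params for lab in labels}
    missing = set(labels) - set(params)
    if missing:
        raise ValueError(f"no model parameters for partitions {sorted(missing)}")
    return {lab: params[lab] for lab in labels}


def _partition_site_lnl(partials: np.ndarray, tindex: TreeIndex,
                        params: SubstModelParams, lengths: np.ndarray) -> np.ndarray:
    """Per-site lnL for one partition. ``partials``: (n_taxa, m, 4) tip
    vectors; ``lengths``: per-node branch lengths (TreeIndex order)."""
    m = partials.shape[1]
    eig = EigenSystem(params.rate_matrix(), params.pi)
    cats = params.gamma_rates()
    per_cat = np.empty((len(cats), m))
    blen = lengths * params.blen_multiplier
    for ci, rate in enumerate(cats):
        pmats = eig.transition_probs(blen * rate)  # (n_nodes, 4, 4)
        node_partial: list[np.ndarray | None] = [None] * tindex.n_nodes
        logscale = np.zeros(m)
        for i in range(tindex.n_nodes):
            if not tindex.children[i]:
                node_partial[i] = partials[tindex.tip_row[i]]
                continue
            acc = np.ones((m, 4))
            for c in tindex.children[i]:
                acc *= node_partial[c] @ pmats[c].T
                node_partial[c] = None
            scale = acc.max(axis=1)
            bad = scale <= 0
            if bad.any():
                scale = np.where(bad, 1.0, scale)
            acc /= scale[:, None]
            logscale += np.log(scale)
            node_partial[i] = acc
        root_l = node_partial[tindex.root] @ params.pi
        with np.errstate(divide="ignore"):
            per_cat[ci] = np.log(root_l) + logscale
    return logsumexp(per_cat, axis=0) - np.log(len(cats))


class PartitionedEngine:
    """Caches tip partials and the tree index for repeated evaluations."""

    def __init__(self, aln: PartitionedAlignment, tree: dendropy.Tree, params):
        self.aln = aln
        self.tree = tree
        self.params = _params_by_label(aln, params)
        self.tindex = TreeIndex(tree, aln.taxa)
        self._tips: dict[str, np.ndarray] = {}
        self._site_idx: dict[str, np.ndarray] = {}
        for lab in self.params:
            idx = aln.sites_where(lab)
            self._site_idx[lab] = idx
            self._tips[lab] = tip_partials(aln.matrix[:, idx])
        self.lengths = self.tindex.lengths.copy()

    def site_log_likelihoods(self, lengths: np.ndarray | None = None) -> np.ndarray:
        lengths = self.lengths if lengths is None else lengths
        out = np.empty(self.aln.n_sites)
        for lab, params in self.params.items():
            out[self._site_idx[lab]] = _partition_site_lnl(
                self._tips[lab], self.tindex, params, lengths)
        return out

    def total_log_likelihood(self, lengths: np.ndarray | None = None) -> float:
        return float(self.site_log_likelihoods(lengths).sum())


def site_log_likelihoods(aln: PartitionedAlignment, tree: dendropy.Tree,
                         params) -> np.ndarray:
    """Per-site log-likelihoods (original site order); sums to the tree lnL."""
    return PartitionedEngine(aln, tree, params).site_log_likelihoods()


def total_log_likelihood(aln: PartitionedAlignment, tree: dendropy.Tree, params) -> float:
    return float(site_log_likelihoods(aln, tree, params).sum())


@dataclass
class BranchOptResult:
    tree: dendropy.Tree
    log_likelihood: float
    converged: bool
    sweeps: int


def optimize_branch_lengths(aln: PartitionedAlignment, tree: dendropy.Tree, params,
                            tol: float = 1e-6, max_sweeps: int = 20,
                            max_blen: float = 20.0) -> BranchOptResult:
    """Coordinate-wise ML branch lengths (Brent per branch, sweeps to
    convergence). The input tree is modified in place and returned."""
    engine = PartitionedEngine(aln, tree, params)
    lengths = engine.lengths
    lnl = engine.total_log_likelihood(lengths)
    branch_ids = [i for i in range(engine.tindex.n_nodes) if engine.tindex.parent[i] != -1]
    converged = False
    sweep = 0
    for sweep in range(1, max_sweeps + 1):
        for b in branch_ids:
            def neg(x: float, b=b) -> float:
                trial = lengths.copy()
                trial[b] = x
                return -engine.total_log_likelihood(trial)
            res = minimize_scalar(neg, bounds=(0.0, max_blen), method="bounded",
                                  options={"xatol": 1e-8})
            if -res.fun > lnl:
                lengths[b] = float(res.x)
                lnl = -float(res.fun)
        new_lnl = engine.total_log_likelihood(lengths)
        if new_lnl - lnl < tol and sweep > 1:
            lnl = new_lnl
            converged = True
            break
        lnl = new_lnl
    if not converged:
        warnings.warn("branch-length optimisation hit max_sweeps without "
                      "meeting the lnL tolerance", RuntimeWarning)
    engine.tindex.set_lengths_on_tree(lengths)
    return BranchOptResult(tree=tree, log_likelihood=lnl, converged=converged,
                           sweeps=sweep)


# -- NNI search ----------------------------------------------------------

def _nni_neighbors(tree: dendropy.Tree):
    """Yield cloned trees one rooted-NNI away (covers all unrooted NNIs)."""
    nodes = list(tree.preorder_node_iter())
    for vi, v in enumerate(nodes):
        u = v.parent_node
        if u is None or v.is_leaf():
            continue
        siblings = [s for s in u.child_nodes() if s is not v]
        for ci in range(len(v.child_nodes())):
            for si in range(len(siblings)):
                clone = tree.clone(depth=1)
                cnodes = list(clone.preorder_node_iter())
                cv = cnodes[vi]
                cu = cv.parent_node
                csibs = [s for s in cu.child_nodes() if s is not cv]
                child = cv.child_nodes()[ci]
                sib = csibs[si]
                cu.remove_child(sib)
                cv.remove_child(child)
                cu.add_child(child)
                cv.add_child(sib)
                yield clone


@dataclass
class SearchResult:
    tree: dendropy.Tree
    log_likelihood: float
    n_moves: int


def nni_search(aln: PartitionedAlignment, start_tree: dendropy.Tree, params,
               tol: float = 1e-6, max_rounds: int = 50) -> SearchResult:
    """Best-improving NNI hill-climb with branch-length reoptimisation.

    Starts from ``start_tree`` (e.g. a neighbour-joining tree), accepts the
    best lnL-improving rearrangement each round, and stops at a local
    optimum. The returned lnL is never below the start tree's.
    """
    current = start_tree.clone(depth=1)
    res = optimize_branch_lengths(aln, current, params, tol=max(tol, 1e-4))
    best_lnl = res.log_likelihood
    n_moves = 0
    for _ in range(max_rounds):
        best_neighbor, best_neighbor_lnl = None, best_lnl
        for cand in _nni_neighbors(current):
            r = optimize_branch_lengths(aln, cand, params, tol=max(tol, 1e-4))
            if r.log_likelihood > best_neighbor_lnl + 1e-9:
                best_neighbor, best_neighbor_lnl = cand, r.log_likelihood
        if best_neighbor is None:
            break
        current, best_lnl = best_neighbor, best_neighbor_lnl
        n_moves += 1
    return SearchResult(tree=current, log_likelihood=best_lnl, n_moves=n_moves)


def nj_start_tree(aln: PartitionedAlignment) -> dendropy.Tree:
    """Neighbour-joining starting tree from Jukes-Cantor distances."""
    return nj_tree(aln.taxa, jc_distance_matrix(aln.matrix))


# -- branch-length covariance --------------------------------------------

@dataclass
class BranchEstimates:
    """MLE branch lengths with their covariance, for one partition.

    ``branch_clades`` identifies each entry by the leaf set below the
    branch, so estimates can be re-attached to any congruent topology.
    """

    lengths: np.ndarray
    covariance: np.ndarray
    branch_clades: list[tuple[str, ...]]
    log_likelihood: float
    singular: bool = False


def estimate_branch_covariance(aln: PartitionedAlignment, tree: dendropy.Tree,
                               params, step: float = 1e-4) -> BranchEstimates:
    """Branch-length MLEs and covariance from observed Fisher information.

    The covariance is the inverse of the numerical Hessian of -lnL at the
    optimum (central differences); a singular Hessian falls back to the
    pseudo-inverse with a warning, and the result is projected onto the
    positive semi-definite cone.
    """
    opt = optimize_branch_lengths(aln, tree, params)
    engine = PartitionedEngine(aln, tree, params)
    lengths = engine.lengths
    branch_ids = [i for i in range(engine.tindex.n_nodes) if engine.tindex.parent[i] != -1]
    nb = len(branch_ids)

    def f(vec: np.ndarray) -> float:
        trial = lengths.copy()
        trial[branch_ids] = vec
        return -engine.total_log_likelihood(trial)

    x0 = lengths[branch_ids].copy()
    h = step * (1.0 + np.abs(x0))
    hess = np.empty((nb, nb))
    f0 = f(x0)
    for i in range(nb):
        for j in range(i, nb):
            ei = np.zeros(nb); ei[i] = h[i]
            ej = np.zeros(nb); ej[j] = h[j]
            if i == j:
                val = (f(x0 + ei) - 2 * f0 + f(np.maximum(x0 - ei, 0))) / (h[i] ** 2)
            else:
                val = (f(x0 + ei + ej) - f(x0 + ei) - f(x0 + ej) + f0) / (h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    singular = False
    try:
        cov = np.linalg.inv(hess)
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        singular = True
        warnings.warn("singular Hessian; using pseudo-inverse covariance",
                      RuntimeWarning)
        cov = np.linalg.pinv(hess)
    # project to PSD
    eigval, eigvec = np.linalg.eigh((cov + cov.T) / 2.0)
    if eigval.min() < 0:
        eigval = np.clip(eigval, 0.0, None)
        cov = (eigvec * eigval) @ eigvec.T
        singular = True
    clades = []
    for b in branch_ids:
        nd = engine.tindex.nodes[b]
        clades.append(tuple(sorted(lf.taxon.label for lf in nd.leaf_iter())))
    return BranchEstimates(lengths=x0, covariance=cov, branch_clades=clades,
                           log_likelihood=opt.log_likelihood, singular=singular)
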