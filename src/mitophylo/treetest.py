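"""Topology tests from per-site log-likelihoods: RELL bootstrap and AU test.

The RELL (resampling estimated log-likelihoods) bootstrap resamples sites
with replacement and re-sums the stored per-site log-likelihoods instead of
re-optimising each replicate. The approximately unbiased (AU) test extends
this over several resample sizes (the multiscale bootstrap): for each
candidate tree the probit-transformed bootstrap proportion across scales r
is fitted by weighted least squares to

    z(r) = d * sqrt(r) + c / sqrt(r)

where d estimates the signed distance of the data to the region where the
tree is best and c its boundary curvature; the p-value is 1 - Phi(d - c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 10))
DEFAULT_REPLICATES = 10_000


def scale_seeds(seed: int, n_scales: int) -> np.ndarray:
    """Deterministic per-scale child seeds (the AU machinery's seed policy)."""
    state = np.random.SeedSequence(seed).generate_state(n_scales)
    return (state >> np.uint32(1)).astype(np.int64)  # keep below 2**31


def rell_bootstrap(table: np.ndarray, replicates: int, scale: float = 1.0,
                   seed: int = 0) -> np.ndarray:
    """Fractional bootstrap win counts per tree.

    ``table`` is (n_trees, n_sites) per-site log-likelihoods. Each replicate
    draws round(scale*m) sites with replacement, sums per-tree, and credits
    the argmax; exact ties are split 1/k among the k tied trees. The counts
    sum to ``replicates``.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 1:
        raise ValueError("need a (n_trees >= 2, n_sites >= 1) table")
    n_trees, m = table.shape
    n_draw = max(1, int(round(scale * m)))
    rng = np.random.default_rng(seed)
    out = np.zeros(n_trees)
    # resample site indices in chunks to bound memory at ~tens of MB
    chunk = max(1, min(replicates, int(2e7 / (n_trees * n_draw)) or 1))
    done = 0
    while done < replicates:
        k = min(chunk, replicates - done)
        idx = rng.integers(0, m, size=(k, n_draw))
        sums = table[:, idx].sum(axis=2).T            # (k, n_trees)
        best = sums.max(axis=1, keepdims=True)
        # ties split fractionally; the tolerance absorbs summation-order
        # round-off, far below any real lnL difference
        ties = sums >= best - 1e-9 * np.maximum(1.0, np.abs(best))
        out += (ties / ties.sum(axis=1, keepdims=True)).sum(axis=0)
        done += k
    return out


@dataclass
class AUResult:
    """Multiscale-bootstrap fit for one candidate tree."""

    diff_lnl: float     # lnL deficit vs the best tree (best tree: 0)
    bp: float           # bootstrap proportion at scale 1.0
    d: float            # signed distance
    c: float            # curvature
    p_au: float
    degenerate: bool    # bp pinned at 0/1 across scales; p clamped


def _fit_au(bps: np.ndarray, scales: np.ndarray, replicates: int) -> tuple[float, float, float, bool]:
    valid = (bps > 0.0) & (bps < 1.0)
    if valid.sum() < 2:
        p = 1.0 if bps.mean() > 0.5 else 0.0
        return np.nan, np.nan, p, True
    r = scales[valid]
    bp = bps[valid]
    z = norm.ppf(1.0 - bp)
    w = replicates * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    x = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    xtw = x.T * w
    d, c = np.linalg.solve(xtw @ x, xtw @ z)
    return float(d), float(c), float(1.0 - norm.cdf(d - c)), False


def au_test(table: np.ndarray, scales=DEFAULT_SCALES,
            replicates: int = DEFAULT_REPLICATES, seed: int = 0) -> pd.DataFrame:
    """AU test over candidate trees from their per-site log-likelihoods.

    Returns a DataFrame indexed like the table rows with columns diff_lnl,
    bp (scale-1.0 bootstrap proportion), d, c, p_au and degenerate.
    """
    table = np.asarray(table, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    n_trees = table.shape[0]
    seeds = scale_seeds(seed, len(scales))
    bps = np.empty((len(scales), n_trees))
    for i, (r, s) in enumerate(zip(scales, seeds)):
        bps[i] = rell_bootstrap(table, replicates, scale=r, seed=int(s)) / replicates
    totals = table.sum(axis=1)
    diff = totals.max() - totals
    idx_one = int(np.argmin(np.abs(scales - 1.0)))
    rows = []
    for t in range(n_trees):
        d, c, p, degen = _fit_au(bps[:, t], scales, replicates)
        rows.append(AUResult(diff_lnl=float(diff[t]), bp=float(bps[idx_one, t]),
                             d=d, c=c, p_au=p, degenerate=degen))
    return pd.DataFrame([vars(r) for r in rows])


def constrained_vs_unconstrained_report(table: np.ndarray, labels: list[str],
                                        alpha: float = 0.05,
                                        scales=DEFAULT_SCALES,
                                        replicates: int = DEFAULT_REPLICATES,
                                        seed: int = 0) -> pd.DataFrame:
    """Ranked comparison of topological hypotheses.

    One row per hypothesis (its per-site lnL row in ``table``), sorted by
    lnL deficit, with the AU p-value and a rejection flag at ``alpha``.
    """
    if len(labels) != table.shape[0]:
        raise ValueError("one label per table row required")
    res = au_test(table, scales=scales, replicates=replicates, seed=seed)
    res.insert(0, "hypothesis", labels)
    res["rejected"] = res["p_au"] < alpha
    return res.sort_values("diff_lnl").reset_index(drop=True)


# -- constrained tree search ---------------------------------------------

def contains_clades(tree, clades: list[set]) -> bool:
    """True if every constraint clade is a (possibly unrooted) split of the
    tree, i.e. some edge separates exactly that leaf set."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    splits = set()
    for nd in tree.postorder_node_iter():
        if nd.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        splits.add(below)
        splits.add(frozenset(leaves - below))
    return all(frozenset(c) in splits for c in clades)


def constrained_nni_search(aln, start_tree, params, clades: list[set],
                           **kwargs):
    """NNI hill-climb restricted to trees containing the given clades
    (the in-package counterpart of a constrained ML search)."""
    from . import phylolik

    if not contains_clades(start_tree, clades):
        raise ValueError("start tree violates the topological constraint")
    result = phylolik.optimize_branch_lengths(
        aln, start_tree.clone(depth=1), params, tol=1e-4)
    current, best_lnl = result.tree, result.log_likelihood
    improved = True
    while improved:
        improved = False
        best_neighbor, best_neighbor_lnl = None, best_lnl
        for cand in phylolik._nni_neighbors(current):
            if not contains_clades(cand, clades):
                continue
            r = phylolik.optimize_branch_lengths(aln, cand, params, tol=1e-4)
            if r.log_likelihood > best_neighbor_lnl + 1e-9:
                best_neighbor, best_neighbor_lnl = cand, r.log_likelihood
        if best_neighbor is not None:
            current, best_lnl = best_neighbor, best_neighbor_lnl
            improved = True
    return phylolik.SearchResult(tree=current, log_likelihood=best_lnl, n_moves=0)


def write_site_lnl_table(table: np.ndarray, labels: list[str], path) -> None:
    pd.DataFrame(table, index=labels).to_csv(path, sep="\t", header=False)


def read_site_lnl_table(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]
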