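"""Bayesian autocorrelated relaxed-clock divergence dating.

A two-step design in the multidivtime tradition: per-partition branch
lengths and their covariance are estimated once on a fixed rooted topology
(:func:`mitophylo.phylolik.estimate_branch_covariance`), and the dating MCMC
then works only with that multivariate-normal summary -- the likelihood of
a proposed chronogram is the MVN density of the estimated branch lengths
around their expectations (branch duration times the arithmetic mean of the
endpoint node rates), summed over partitions with unlinked rates.

The rate model is geometric Brownian motion: each node carries a log rate
that diffuses with variance nu per Myr along branches. Priors follow the
multidivtime parameterisation -- gamma distributions specified by (mean, sd)
for the root age (rttm, rttmsd), root rate (rtrate, rtratesd) and Brownian
constant (brownmean, brownsd) -- and node ages are bounded by fossil or
biogeographic calibration constraints, every retained sample respecting
every bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import dendropy
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .phylolik import BranchEstimates
from .treeio import TreeIndex

_EPS_DT = 1e-8  # floor on branch durations inside the Brownian prior


@dataclass
class ChronosPriors:
    """Gamma priors by (mean, sd), multidivtime style. Units: Myr and
    substitutions/site/Myr (convert from 100-Myr units at the config
    boundary if needed)."""

    rttm: float = 420.0
    rttmsd: float = 420.0
    rtrate: float = 7.4e-4
    rtratesd: float = 7.4e-4
    brownmean: float = 0.005
    brownsd: float = 0.005

    def __post_init__(self) -> None:
        for name in ("rttm", "rttmsd", "rtrate", "rtratesd", "brownmean", "brownsd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class CalibrationConstraint:
    """Bounds (Myr) on the age of the most recent common ancestor of
    ``taxa``; either bound may be absent."""

    taxa: tuple[str, ...]
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise ValueError("constraint needs at least one bound")
        for b in (self.lower, self.upper):
            if b is not None and b <= 0:
                raise ValueError("bounds must be > 0 Myr")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


@dataclass
class ChainSettings:
    burnin: int = 100_000
    n_samples: int = 10_000
    sample_every: int = 100
    seed: int = 0
    age_window: float = 0.15       # root-age slide, fraction of current age
    rate_step: float = 0.3         # sd of log-rate random walk
    nu_step: float = 0.5           # half-width of log-multiplier for nu
    scale_step: float = 0.05       # half-width of log tree-scale factor
    ridge_step: float = 0.2        # half-width of the joint age-up/rate-down move


class InfeasibleConstraintsError(ValueError):
    pass


def gamma_shape_rate(mean: float, sd: float) -> tuple[float, float]:
    return (mean / sd) ** 2, mean / sd ** 2


def _gamma_logpdf(x: float, mean: float, sd: float) -> float:
    a, b = gamma_shape_rate(mean, sd)
    if x <= 0:
        return -np.inf
    return a * np.log(b) - gammaln(a) + (a - 1) * np.log(x) - b * x


def derive_root_rate_prior(tree: dendropy.Tree, rttm: float) -> tuple[float, float]:
    """Root-rate prior mean from the data: average tip-to-root path length
    (substitutions/site) divided by the root-age prior mean; the sd is set
    equal to the mean."""
    if not tree.is_rooted or len(tree.seed_node.child_nodes()) != 2:
        raise ValueError("a rooted bifurcating tree is required")
    depths = []
    for lf in tree.leaf_node_iter():
        d, nd = 0.0, lf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        depths.append(d)
    rtrate = float(np.mean(depths)) / rttm
    return rtrate, rtrate


# -- posterior container -------------------------------------------------

@dataclass
class ChronosPosterior:
    """Thinned MCMC samples of node ages (Myr), per-partition log rates and
    Brownian constants, with the constraint bookkeeping used to run."""

    internal_clades: list[tuple[str, ...]]
    ages: np.ndarray               # (n_samples, n_internal)
    nus: np.ndarray                # (n_samples, n_partitions)
    root_rates: np.ndarray         # (n_samples, n_partitions)
    bounds: dict[int, tuple[float, float]]   # internal-node column -> (lo, hi)
    settings: ChainSettings
    rhat_root_age: float | None = None
    convergence_warning: bool = False

    def summary(self) -> pd.DataFrame:
        mean = self.ages.mean(axis=0)
        lo, hi = np.percentile(self.ages, [2.5, 97.5], axis=0)
        return pd.DataFrame({
            "clade": [",".join(c) for c in self.internal_clades],
            "age_mean": mean, "age_lo95": lo, "age_hi95": hi,
        })

    def all_samples_within_bounds(self) -> bool:
        for col, (lo, hi) in self.bounds.items():
            a = self.ages[:, col]
            if (a < lo - 1e-9).any() or (a > hi + 1e-9).any():
                return False
        return True


def split_rhat(chains: list[np.ndarray]) -> float:
    """Split-R-hat across chains for a scalar quantity."""
    halves = []
    for c in chains:
        half = len(c) // 2
        halves.extend([c[:half], c[half:2 * half]])
    arr = np.asarray(halves, dtype=float)
    m, n = arr.shape
    w = arr.var(axis=1, ddof=1).mean()
    b = n * arr.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


# -- the sampler ---------------------------------------------------------

class _DatingModel:
    """Internal state and log-posterior pieces for the dating MCMC."""

    def __init__(self, tree: dendropy.Tree, estimates: list[BranchEstimates],
                 constraints: list[CalibrationConstraint], priors: ChronosPriors,
                 use_likelihood: bool = True):
        taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
        self.tindex = TreeIndex(tree, taxa)
        t = self.tindex
        self.priors = priors
        self.use_likelihood = use_likelihood
        self.nonroot = np.array([i for i in range(t.n_nodes) if t.parent[i] != -1])
        self.par = t.parent[self.nonroot]
        self.internal = np.array(sorted(t.internal))
        self.root = t.root
        self.is_tip = np.array([not t.children[i] for i in range(t.n_nodes)])
        self.clade_of_node = [tuple(sorted(lf.taxon.label for lf in nd.leaf_iter()))
                              for nd in t.nodes]
        # map branch estimates (clade-keyed) to node order
        self.obs, self.prec, self.diag_var = [], [], []
        for est in estimates:
            pos = {clade: i for i, clade in enumerate(est.branch_clades)}
            order = []
            for i in self.nonroot:
                clade = self.clade_of_node[i]
                if clade not in pos:
                    raise ValueError(f"no branch estimate for clade {clade}")
                order.append(pos[clade])
            order = np.array(order)
            x = np.clip(est.lengths[order], 0.0, None)  # clamp negative MLEs
            cov = est.covariance[np.ix_(order, order)]
            self.obs.append(x)
            offdiag = cov - np.diag(np.diag(cov))
            if np.abs(offdiag).max() < 1e-15:
                self.diag_var.append(np.maximum(np.diag(cov), 1e-12))
                self.prec.append(None)
            else:
                self.diag_var.append(None)
                jitter = 1e-10 * np.eye(len(x))
                self.prec.append(np.linalg.pinv(cov + jitter))
        self.n_part = len(estimates)
        # constraint bounds per node
        self.lower = np.zeros(t.n_nodes)
        self.upper = np.full(t.n_nodes, np.inf)
        for con in constraints:
            node = self._mrca(con.taxa)
            if con.lower is not None:
                self.lower[node] = max(self.lower[node], con.lower)
            if con.upper is not None:
                self.upper[node] = min(self.upper[node], con.upper)
        self._check_feasibility()

    def _mrca(self, taxa: tuple[str, ...]) -> int:
        target = set(taxa)
        for i in np.sort(self.internal):
            if target <= set(self.clade_of_node[i]):
                return int(i)
        raise ValueError(f"no ancestor found for taxa {taxa}")

    def _check_feasibility(self) -> None:
        t = self.tindex
        self.min_age = self.lower.copy()
        for i in range(t.n_nodes):          # postorder: children first
            for c in t.children[i]:
                self.min_age[i] = max(self.min_age[i], self.min_age[c])
        max_age = self.upper.copy()
        for i in range(t.n_nodes - 1, -1, -1):
            p = t.parent[i]
            if p != -1:
                max_age[i] = min(max_age[i], max_age[p])
        bad = np.flatnonzero(self.min_age > max_age + 1e-12)
        if len(bad):
            msgs = [f"node {self.clade_of_node[i][:3]}...: requires age >= "
                    f"{self.min_age[i]} but an ancestor is capped at {max_age[i]}"
                    for i in bad]
            raise InfeasibleConstraintsError("; ".join(msgs))
        self.max_age = max_age

    # state: ages (n_nodes, tips 0), logr (n_part, n_nodes), nus (n_part,)
    def init_state(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = self.tindex
        ages = np.zeros(t.n_nodes)
        root_lo = self.min_age[self.root]
        root_hi = self.max_age[self.root]
        root_guess = np.clip(self.priors.rttm, root_lo * 1.0001 + 1e-6,
                             root_hi if np.isfinite(root_hi) else np.inf)
        ages[self.root] = max(root_guess, root_lo + 1e-6, 1e-3)
        for i in sorted(self.internal, reverse=True):   # preorder-ish: parents first
            if i == self.root:
                continue
            p = t.parent[i]
            lo = self.min_age[i]
            hi = min(self.max_age[i], ages[p])
            if hi <= lo:
                ages[i] = lo
            else:
                ages[i] = lo + 0.618 * (hi - lo)
        logr = np.full((self.n_part, t.n_nodes), np.log(self.priors.rtrate))
        nus = np.full(self.n_part, self.priors.brownmean)
        return ages, logr, nus

    # -- posterior components
    def loglik(self, ages: np.ndarray, logr: np.ndarray) -> float:
        if not self.use_likelihood:
            return 0.0
        dt = ages[self.par] - ages[self.nonroot]
        total = 0.0
        for p in range(self.n_part):
            rates = np.exp(logr[p])
            e = dt * 0.5 * (rates[self.par] + rates[self.nonroot])
            resid = self.obs[p] - e
            if self.prec[p] is None:
                total += -0.5 * float(np.sum(resid * resid / self.diag_var[p]))
            else:
                total += -0.5 * float(resid @ self.prec[p] @ resid)
        return total

    def log_bm_prior(self, ages: np.ndarray, logr: np.ndarray, nus: np.ndarray) -> float:
        dt = np.maximum(ages[self.par] - ages[self.nonroot], _EPS_DT)
        total = 0.0
        for p in range(self.n_part):
            var = nus[p] * dt
            z = logr[p][self.nonroot] - logr[p][self.par]
            total += float(-0.5 * np.sum(np.log(2 * np.pi * var) + z * z / var))
        return total

    def log_priors(self, ages: np.ndarray, logr: np.ndarray, nus: np.ndarray) -> float:
        pr = self.priors
        total = _gamma_logpdf(ages[self.root], pr.rttm, pr.rttmsd)
        # internal ages are uniform in proportions of the root age: the
        # order-polytope volume scales as T^k, so the density carries T^-k
        # (keeps the root-age marginal equal to its gamma prior).
        k_nr = len(self.internal) - 1
        total += -k_nr * np.log(ages[self.root])
        for p in range(self.n_part):
            rate0 = np.exp(logr[p][self.root])
            total += _gamma_logpdf(rate0, pr.rtrate, pr.rtratesd) + logr[p][self.root]
            total += _gamma_logpdf(nus[p], pr.brownmean, pr.brownsd)
        return total

    def log_posterior(self, ages, logr, nus) -> float:
        return (self.loglik(ages, logr)
                + self.log_bm_prior(ages, logr, nus)
                + self.log_priors(ages, logr, nus))

    def within_bounds(self, ages: np.ndarray) -> bool:
        a = ages[self.internal]
        return bool(np.all(a >= self.lower[self.internal] - 1e-12)
                    and np.all(a <= self.upper[self.internal] + 1e-12))


def run_dating_mcmc(
    tree: dendropy.Tree,
    estimates: list[BranchEstimates],
    constraints: list[CalibrationConstraint],
    priors: ChronosPriors,
    settings: ChainSettings | None = None,
    use_likelihood: bool = True,
    force_generic: bool = False,
) -> ChronosPosterior:
    """Metropolis-Hastings over node ages, node log-rates and nu.

    Proposals: uniform draws of each internal age within its locally
    feasible interval (symmetric, since the interval depends only on the
    neighbours), a windowed root-age slide, Gaussian log-rate walks, a nu
    multiplier, a whole-tree age scaling, and a correlated age-up/rate-down
    rescaling that travels along the time-rate ridge. Samples are recorded
    after ``burnin`` sweeps, every ``sample_every``-th sweep, and every
    retained sample satisfies every calibration bound by construction.

    With diagonal branch covariances the chain runs through a delta-update
    fast path (local moves only touch the adjacent branch terms); dense
    covariances use the generic full-recompute path. ``force_generic``
    disables the fast path (used for cross-validation of the two).
    """
    settings = settings or ChainSettings()
    model = _DatingModel(tree, estimates, constraints, priors, use_likelihood)
    diag_ok = (use_likelihood and model.n_part > 0
               and all(p is None for p in model.prec))
    if diag_ok and not force_generic:
        kept_ages, kept_nus, kept_r0 = _run_chain_diag(model, settings)
        return _package_posterior(model, settings, kept_ages, kept_nus, kept_r0)
    rng = np.random.default_rng(settings.seed)
    ages, logr, nus = model.init_state()
    fixed = np.abs(model.upper - model.lower) < 1e-12
    for i in np.flatnonzero(fixed & ~model.is_tip):
        ages[i] = model.lower[i]
    logpost = model.log_posterior(ages, logr, nus)
    t = model.tindex
    children = t.children
    internal_order = [i for i in model.internal if not fixed[i]]
    nonroot_internal = [i for i in internal_order if i != model.root]
    scale_allowed = not bool(fixed[~model.is_tip].any())
    n_sweeps = settings.burnin + settings.n_samples * settings.sample_every
    kept_ages, kept_nus, kept_r0 = [], [], []

    def metropolis(new_ages, new_logr, new_nus, extra_log_hastings=0.0):
        nonlocal ages, logr, nus, logpost
        lp = model.log_posterior(new_ages, new_logr, new_nus)
        if np.log(rng.random()) < lp - logpost + extra_log_hastings:
            ages, logr, nus, logpost = new_ages, new_logr, new_nus, lp

    for sweep in range(1, n_sweeps + 1):
        # node-age slides
        for i in nonroot_internal:
            lo = max(model.lower[i], max(ages[c] for c in children[i]))
            hi = min(model.upper[i], ages[t.parent[i]])
            if hi - lo <= 0:
                continue
            prop = ages.copy()
            prop[i] = rng.uniform(lo, hi)
            metropolis(prop, logr, nus)
        # root-age slide
        r = model.root
        if not fixed[r]:
            w = settings.age_window * max(ages[r], 1.0)
            cand = ages[r] + rng.uniform(-w, w)
            lo = max(model.lower[r], max(ages[c] for c in children[r]))
            if cand > lo and cand <= model.upper[r]:
                prop = ages.copy()
                prop[r] = cand
                metropolis(prop, logr, nus)
        # log-rate walks
        for p in range(model.n_part):
            for i in range(t.n_nodes):
                prop_r = logr.copy()
                prop_r[p, i] += rng.normal(0.0, settings.rate_step)
                metropolis(ages, prop_r, nus)
        # nu multipliers
        for p in range(model.n_part):
            m = np.exp(rng.uniform(-settings.nu_step, settings.nu_step))
            prop_n = nus.copy()
            prop_n[p] *= m
            metropolis(ages, logr, prop_n, extra_log_hastings=np.log(m))
        # whole-tree age scaling
        if scale_allowed:
            m = np.exp(rng.uniform(-settings.scale_step, settings.scale_step))
            prop = ages.copy()
            prop[~model.is_tip] *= m
            if model.within_bounds(prop):
                k = int((~model.is_tip).sum())
                metropolis(prop, logr, nus, extra_log_hastings=k * np.log(m))
        # correlated time/rate rescaling: ages up, rates down. This leaves
        # every expected branch length unchanged, so it travels along the
        # age-rate ridge that the single-parameter moves cannot cross.
        if scale_allowed:
            m = np.exp(rng.uniform(-settings.ridge_step, settings.ridge_step))
            prop = ages.copy()
            prop[~model.is_tip] *= m
            if model.within_bounds(prop):
                k = int((~model.is_tip).sum())
                metropolis(prop, logr - np.log(m), nus,
                           extra_log_hastings=k * np.log(m))
        if sweep > settings.burnin and (sweep - settings.burnin) % settings.sample_every == 0:
            kept_ages.append(ages[model.internal].copy())
            kept_nus.append(nus.copy())
            kept_r0.append(np.exp(logr[:, model.root]).copy())

    return _package_posterior(model, settings, kept_ages, kept_nus, kept_r0)


def _package_posterior(model: _DatingModel, settings: ChainSettings,
                       kept_ages, kept_nus, kept_r0) -> ChronosPosterior:
    bounds = {}
    for col, i in enumerate(model.internal):
        if model.lower[i] > 0 or np.isfinite(model.upper[i]):
            bounds[col] = (model.lower[i], model.upper[i])
    return ChronosPosterior(
        internal_clades=[model.clade_of_node[i] for i in model.internal],
        ages=np.asarray(kept_ages), nus=np.asarray(kept_nus),
        root_rates=np.asarray(kept_r0), bounds=bounds, settings=settings)


def _run_chain_diag(model: _DatingModel, settings: ChainSettings):
    """Delta-update sampler for diagonal branch-length covariances.

    Identical target and proposal kernels as the generic path; local moves
    recompute only the likelihood/Brownian terms of the branches adjacent to
    the updated node, in plain scalar arithmetic.
    """
    import math

    rng = np.random.default_rng(settings.seed)
    ages_v, logr_v, nus_v = model.init_state()
    fixed = np.abs(model.upper - model.lower) < 1e-12
    for i in np.flatnonzero(fixed & ~model.is_tip):
        ages_v[i] = model.lower[i]
    t = model.tindex
    n = t.n_nodes
    root = model.root
    n_part = model.n_part
    par = [int(x) for x in t.parent]
    kids = [list(t.children[i]) for i in range(n)]
    lower = [float(x) for x in model.lower]
    upper = [float(x) for x in model.upper]
    ages = [float(a) for a in ages_v]
    logr = [[float(x) for x in logr_v[p]] for p in range(n_part)]
    rate = [[math.exp(x) for x in row] for row in logr]
    nus = [float(x) for x in nus_v]
    x_obs = [[0.0] * n for _ in range(n_part)]
    var = [[1.0] * n for _ in range(n_part)]
    nonroot = [int(i) for i in model.nonroot]
    for p in range(n_part):
        for b, xv, vv in zip(nonroot, model.obs[p], model.diag_var[p]):
            x_obs[p][b] = float(xv)
            var[p][b] = float(vv)
    pr = model.priors
    a_t, b_t = gamma_shape_rate(pr.rttm, pr.rttmsd)
    a_r, b_r = gamma_shape_rate(pr.rtrate, pr.rtratesd)
    a_n, b_n = gamma_shape_rate(pr.brownmean, pr.brownsd)
    log = math.log
    exp = math.exp
    ln2pi = math.log(2.0 * math.pi)

    def ll_term(p: int, b: int, dt: float) -> float:
        resid = x_obs[p][b] - dt * 0.5 * (rate[p][par[b]] + rate[p][b])
        return -0.5 * resid * resid / var[p][b]

    def bm_term(p: int, b: int, dt: float) -> float:
        v = nus[p] * (dt if dt > _EPS_DT else _EPS_DT)
        z = logr[p][b] - logr[p][par[b]]
        return -0.5 * (ln2pi + log(v) + z * z / v)

    ll = [[0.0] * n for _ in range(n_part)]
    bm = [[0.0] * n for _ in range(n_part)]
    for p in range(n_part):
        for b in nonroot:
            dt = ages[par[b]] - ages[b]
            ll[p][b] = ll_term(p, b, dt)
            bm[p][b] = bm_term(p, b, dt)

    k_nr = len(model.internal) - 1  # uniform-in-proportions normalisation

    def root_age_logprior(age: float) -> float:
        return (a_t - 1.0 - k_nr) * log(age) - b_t * age

    def root_rate_logprior(p: int) -> float:
        r0 = rate[p][root]
        # gamma density on the rate plus the log-scale Jacobian
        return (a_r - 1.0) * log(r0) - b_r * r0 + logr[p][root]

    internal = [int(i) for i in model.internal]
    nonroot_internal = [i for i in internal if i != root and not fixed[i]]
    scale_allowed = not bool(fixed[~model.is_tip].any())
    root_free = not fixed[root]
    n_scaled = len(internal)
    n_sweeps = settings.burnin + settings.n_samples * settings.sample_every
    kept_ages, kept_nus, kept_r0 = [], [], []

    for sweep in range(1, n_sweeps + 1):
        # -- node-age slides (local) --------------------------------------
        for i in nonroot_internal:
            lo = lower[i]
            for c in kids[i]:
                if ages[c] > lo:
                    lo = ages[c]
            hi = upper[i]
            if ages[par[i]] < hi:
                hi = ages[par[i]]
            if hi - lo <= 0:
                continue
            cand = rng.uniform(lo, hi)
            delta = 0.0
            new_terms = []
            # branches touched: i itself and the branches of i's children
            for p in range(n_part):
                dt_i = ages[par[i]] - cand
                resid = x_obs[p][i] - dt_i * 0.5 * (rate[p][par[i]] + rate[p][i])
                nll_i = -0.5 * resid * resid / var[p][i]
                nbm_i = bm_term(p, i, dt_i)
                delta += nll_i + nbm_i - ll[p][i] - bm[p][i]
                new_terms.append((p, i, nll_i, nbm_i))
                for c in kids[i]:
                    dt_c = cand - ages[c]
                    resid = x_obs[p][c] - dt_c * 0.5 * (rate[p][i] + rate[p][c])
                    nll_c = -0.5 * resid * resid / var[p][c]
                    nbm_c = bm_term(p, c, dt_c)
                    delta += nll_c + nbm_c - ll[p][c] - bm[p][c]
                    new_terms.append((p, c, nll_c, nbm_c))
            if log(rng.random()) < delta:
                ages[i] = cand
                for p_, b_, nll_, nbm_ in new_terms:
                    ll[p_][b_] = nll_
                    bm[p_][b_] = nbm_
        # -- root-age slide ------------------------------------------------
        if root_free:
            w = settings.age_window * (ages[root] if ages[root] > 1.0 else 1.0)
            cand = ages[root] + rng.uniform(-w, w)
            lo = lower[root]
            for c in kids[root]:
                if ages[c] > lo:
                    lo = ages[c]
            if cand > lo and cand <= upper[root]:
                delta = root_age_logprior(cand) - root_age_logprior(ages[root])
                new_terms = []
                for p in range(n_part):
                    for c in kids[root]:
                        dt_c = cand - ages[c]
                        resid = x_obs[p][c] - dt_c * 0.5 * (rate[p][root] + rate[p][c])
                        nll_c = -0.5 * resid * resid / var[p][c]
                        nbm_c = bm_term(p, c, dt_c)
                        delta += nll_c + nbm_c - ll[p][c] - bm[p][c]
                        new_terms.append((p, c, nll_c, nbm_c))
                if log(rng.random()) < delta:
                    ages[root] = cand
                    for p_, b_, nll_, nbm_ in new_terms:
                        ll[p_][b_] = nll_
                        bm[p_][b_] = nbm_
        # -- log-rate walks ------------------------------------------------
        for p in range(n_part):
            for i in range(n):
                step = rng.normal(0.0, settings.rate_step)
                new_lr = logr[p][i] + step
                new_r = exp(new_lr)
                delta = 0.0
                new_terms = []
                if i == root:
                    delta += ((a_r - 1.0) * log(new_r) - b_r * new_r + new_lr) \
                        - root_rate_logprior(p)
                else:
                    dt_i = ages[par[i]] - ages[i]
                    resid = x_obs[p][i] - dt_i * 0.5 * (rate[p][par[i]] + new_r)
                    nll_i = -0.5 * resid * resid / var[p][i]
                    v = nus[p] * (dt_i if dt_i > _EPS_DT else _EPS_DT)
                    z = new_lr - logr[p][par[i]]
                    nbm_i = -0.5 * (ln2pi + log(v) + z * z / v)
                    delta += nll_i + nbm_i - ll[p][i] - bm[p][i]
                    new_terms.append((i, nll_i, nbm_i))
                for c in kids[i]:
                    dt_c = ages[i] - ages[c]
                    resid = x_obs[p][c] - dt_c * 0.5 * (new_r + rate[p][c])
                    nll_c = -0.5 * resid * resid / var[p][c]
                    v = nus[p] * (dt_c if dt_c > _EPS_DT else _EPS_DT)
                    z = logr[p][c] - new_lr
                    nbm_c = -0.5 * (ln2pi + log(v) + z * z / v)
                    delta += nll_c + nbm_c - ll[p][c] - bm[p][c]
                    new_terms.append((c, nll_c, nbm_c))
                if log(rng.random()) < delta:
                    logr[p][i] = new_lr
                    rate[p][i] = new_r
                    for b_, nll_, nbm_ in new_terms:
                        ll[p][b_] = nll_
                        bm[p][b_] = nbm_
        # -- nu multipliers ------------------------------------------------
        for p in range(n_part):
            m = exp(rng.uniform(-settings.nu_step, settings.nu_step))
            new_nu = nus[p] * m
            delta = ((a_n - 1.0) * log(new_nu) - b_n * new_nu) \
                - ((a_n - 1.0) * log(nus[p]) - b_n * nus[p]) + log(m)
            new_bm = {}
            for b in nonroot:
                dt = ages[par[b]] - ages[b]
                v = new_nu * (dt if dt > _EPS_DT else _EPS_DT)
                z = logr[p][b] - logr[p][par[b]]
                nb = -0.5 * (ln2pi + log(v) + z * z / v)
                delta += nb - bm[p][b]
                new_bm[b] = nb
            if log(rng.random()) < delta:
                nus[p] = new_nu
                for b, nb in new_bm.items():
                    bm[p][b] = nb
        # -- whole-tree age scaling ---------------------------------------
        if scale_allowed:
            m = exp(rng.uniform(-settings.scale_step, settings.scale_step))
            ok = all(lower[i] <= ages[i] * m <= upper[i] for i in internal)
            if ok:
                delta = (root_age_logprior(ages[root] * m)
                         - root_age_logprior(ages[root]) + n_scaled * log(m))
                new_terms = []
                for p in range(n_part):
                    for b in nonroot:
                        dt = (ages[par[b]] - ages[b]) * m
                        resid = x_obs[p][b] - dt * 0.5 * (rate[p][par[b]] + rate[p][b])
                        nll = -0.5 * resid * resid / var[p][b]
                        nbm = bm_term(p, b, dt)
                        delta += nll + nbm - ll[p][b] - bm[p][b]
                        new_terms.append((p, b, nll, nbm))
                if log(rng.random()) < delta:
                    for i in internal:
                        ages[i] *= m
                    for p_, b_, nll_, nbm_ in new_terms:
                        ll[p_][b_] = nll_
                        bm[p_][b_] = nbm_
        # -- correlated age-up/rate-down rescaling ------------------------
        if scale_allowed:
            m = exp(rng.uniform(-settings.ridge_step, settings.ridge_step))
            ok = all(lower[i] <= ages[i] * m <= upper[i] for i in internal)
            if ok:
                lm = log(m)
                delta = (root_age_logprior(ages[root] * m)
                         - root_age_logprior(ages[root]) + n_scaled * lm)
                new_terms = []
                for p in range(n_part):
                    r0_new = rate[p][root] / m
                    delta += ((a_r - 1.0) * log(r0_new) - b_r * r0_new
                              + logr[p][root] - lm) - root_rate_logprior(p)
                    for b in nonroot:
                        dt = (ages[par[b]] - ages[b]) * m
                        # expected lengths are invariant: ll unchanged
                        nbm = bm_term(p, b, dt)
                        delta += nbm - bm[p][b]
                        new_terms.append((p, b, nbm))
                if log(rng.random()) < delta:
                    for i in internal:
                        ages[i] *= m
                    for p in range(n_part):
                        for i in range(n):
                            logr[p][i] -= lm
                            rate[p][i] /= m
                    for p_, b_, nbm_ in new_terms:
                        bm[p_][b_] = nbm_
        # -- record --------------------------------------------------------
        if sweep > settings.burnin and (sweep - settings.burnin) % settings.sample_every == 0:
            kept_ages.append([ages[i] for i in internal])
            kept_nus.append(list(nus))
            kept_r0.append([rate[p][root] for p in range(n_part)])
    return kept_ages, kept_nus, kept_r0


# -- two-step pipeline ---------------------------------------------------

DATING_PARTITION_GROUPS = {"codon12": ["codon1", "codon2"],
                           "rRNA": ["rRNA"], "tRNA": ["tRNA"]}


def two_step_date(
    aln,
    topology: dendropy.Tree,
    constraints: list[CalibrationConstraint],
    priors: ChronosPriors | None = None,
    settings: ChainSettings | None = None,
    n_chains: int = 2,
    partition_groups: dict[str, list[str]] | None = None,
) -> ChronosPosterior:
    """Estimate branch lengths + covariance per partition (F84+Gamma, third
    codon positions excluded), then run the dating MCMC with replicate
    chains from distinct seeds; flags non-convergence by split-R-hat of the
    root age."""
    import numpy as _np

    from . import phylolik
    from .seqprep import DatasetVariant, ry_recode
    from .substmodels import SubstModelParams

    settings = settings or ChainSettings()
    groups = partition_groups or DATING_PARTITION_GROUPS
    dating_aln = ry_recode(aln, DatasetVariant("12nRTn"))  # drop codon3
    estimates = []
    for labels in groups.values():
        idx = _np.flatnonzero(_np.isin(dating_aln.partition_of_site, labels))
        if len(idx) == 0:
            continue
        sub = dating_aln.subset_sites(idx)
        params = SubstModelParams(model="F84", kappa=2.0,
                                  pi=sub.empirical_base_frequencies(), alpha=0.5)
        est = phylolik.estimate_branch_covariance(sub, topology.clone(depth=1), params)
        estimates.append(est)
    if priors is None:
        scored = topology.clone(depth=1)
        res = phylolik.optimize_branch_lengths(
            dating_aln, scored, SubstModelParams(
                model="F84", kappa=2.0,
                pi=dating_aln.empirical_base_frequencies(), alpha=0.5))
        rtrate, rtratesd = derive_root_rate_prior(res.tree, 420.0)
        priors = ChronosPriors(rtrate=rtrate, rtratesd=rtratesd)
    chains = []
    for c in range(max(n_chains, 2)):
        s = replace(settings, seed=settings.seed + 1000 * c)
        chains.append(run_dating_mcmc(topology, estimates, constraints, priors, s))
    root_col = int(np.argmax([len(c) for c in chains[0].internal_clades]))
    rhat = split_rhat([ch.ages[:, root_col] for ch in chains])
    post = chains[0]
    post.rhat_root_age = rhat
    post.convergence_warning = rhat > 1.1
    if post.convergence_warning:
        warnings.warn(f"replicate dating chains disagree (split-Rhat on root "
                      f"age = {rhat:.3f})", RuntimeWarning)
    return post


def load_constraints_csv(path) -> list[CalibrationConstraint]:
    """Constraints CSV with columns clade_taxa (semicolon-separated taxon
    labels), lower, upper (Myr; blank = unbounded)."""
    df = pd.read_csv(path)
    out = []
    for rec in df.to_dict("records"):
        lower = rec.get("lower")
        upper = rec.get("upper")
        out.append(CalibrationConstraint(
            taxa=tuple(str(rec["clade_taxa"]).split(";")),
            lower=None if pd.isna(lower) else float(lower),
            upper=None if pd.isna(upper) else float(upper)))
    return out
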