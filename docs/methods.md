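# Methods

This note documents the models, algorithms and numerical choices behind
`mitophylo`, and what its synthetic-data validation does and does not show.

## Scope and design

The package re-implements, as a tested pipeline, the computational workflow
of a mitogenomic study of anglerfish (Lophiiformes) evolution: dataset
preparation (partitioning, reading-frame overlap exclusion, RY-recoding,
diversity-proportional taxon subsampling), partitioned maximum-likelihood
phylogenetics with per-site log-likelihoods, RELL/AU topology testing, Mk1
ancestral-state reconstruction of male sexual parasitism, Bayesian
autocorrelated relaxed-clock divergence dating under calibration
constraints, and per-clade net diversification rates. The original
mitogenome sequences are not required: a synthetic-data module generates
datasets with the same statistical structure and known truth, so every
stage is validated by parameter recovery, closed forms, or exhaustive
enumeration.

## Dataset preparation (`seqprep`)

Sites carry one of five partition labels (codon positions 1-3, rRNA, tRNA),
assigned from a gene-interval table; gaps and '?' are missing data
throughout.

**Reading-frame overlaps.** Mitochondrial gene pairs such as ATPase8/6
share nucleotides through overlapping reading frames. In a gene-by-gene
concatenation those nucleotides appear twice; `exclude_frame_overlaps`
keeps them once, attributed to the upstream gene, removing the leading
sites of the downstream gene's span. Overlaps across more than two genes
are rejected.

**RY-recoding.** Third codon positions saturate quickly; recoding purines
to A and pyrimidines to C leaves only transversions informative. Three
dataset variants are supported: RY-recoded thirds (`12n3rRTn`), all
positions (`123nRTn`), and thirds excluded (`12nRTn`). Ambiguity codes
whose possibilities are all purine map to A, all pyrimidine to C; anything
mixed (N, S, W, ...) becomes missing, since RY-coding retains no other
information from it. All taxa are recoded alike; the historical practice of
exempting one outgroup existed only to satisfy a particular program's input
checks and is not needed here.

**Log-diversity subsampling.** To blunt the node-density effect in dating,
taxa are subsampled per clade in proportion to log10 of described species
diversity, with a floor of two per clade and largest-remainder rounding;
within a clade, representatives are chosen to maximise phylogenetic
diversity (greedy insertion, which is exact for the PD objective). With the
anglerfish suborder diversities and 11 slots this yields 3 representatives
for the most species-rich suborder and 2 for each of the other four. The
floor-plus-largest-remainder rule is this package's choice: the source
analyses report only the realised split, not the allocation rule.

## Likelihood engine (`phylolik`, `substmodels`)

Reversible nucleotide models (GTR by six exchangeabilities, F84 by a
transition/transversion parameter expanded to its GTR form), rate matrices
normalised to one expected substitution per site per unit branch length.
Among-site variation uses the standard discrete gamma with
equal-probability categories represented by conditional means (default 4
categories; one category reduces exactly to the homogeneous model).
Transition probabilities come from the pi^(1/2)-symmetrised eigen
decomposition.

Per-site log-likelihoods use Felsenstein pruning with per-node rescaling
(scalers accumulated in log space), so deep trees cannot underflow to
-inf. Partitions are independent: per-partition parameters and a
per-partition branch-length multiplier over shared lengths. Correctness is
certified by exhaustive enumeration of interior-node states on small trees
(the test oracle builds transition matrices through `scipy.linalg.expm`,
independent of the engine's eigen path).

Branch lengths are optimised coordinate-wise (bounded Brent per branch,
sweeps to a 1e-6 lnL tolerance). In the rooted representation of a
reversible model the two root-child lengths are identified only through
their sum; consumers that need identifiable quantities should compare that
sum. Topology search is a best-improving NNI hill-climb with branch-length
re-optimisation, started from a neighbour-joining tree; NJ is implemented
in-package (Saitou-Nei with index-ordered tie-breaking) so that repeated
runs are byte-identical. Branch-length covariance is the inverse observed
Fisher information (central-difference Hessian at the MLE), pseudo-inverted
and projected to positive semi-definite when necessary.

## Topology tests (`treetest`)

RELL bootstrap: replicates resample sites with replacement (round(scale*m)
sites at resample scale `scale`), re-sum stored per-site log-likelihoods,
and credit the best tree; exact ties are split 1/k, with a 1e-9 tolerance
absorbing summation-order round-off. The AU test fits, per tree, the probit
of the bootstrap proportion across scales r (default 0.5-1.4 in steps of
0.1, 10,000 replicates per scale) by weighted least squares to
z(r) = d*sqrt(r) + c/sqrt(r), with delta-method weights
reps*phi(z)^2/(bp(1-bp)); p = 1 - Phi(d - c). Proportions pinned at 0 or 1
across scales clamp p to 0/1 with a degenerate-fit flag. For a two-tree
table with Gaussian per-site differences this machinery has the closed form
p = Phi(S/sqrt(m v)) (S the realised lnL difference, v the per-site
variance), which the tests verify, and its type-I error on exchangeable
null tables is checked to be near the nominal 5%. Constrained hypotheses
are searched by the same NNI climb restricted to trees containing the
required splits.

## Ancestral states (`ancrecon`)

The Mk1 model (k states, one rate q) has closed-form transition
probabilities P_stay = 1/k + (k-1)/k e^(-kqt). The single rate is fitted by
bounded 1-D maximisation of the pruning likelihood with an explicit q = 0
boundary check; marginal reconstruction combines inside (downward) vectors
with outside vectors propagated from a uniform root prior — equivalent to
rerooting at each node — and is certified against exhaustive enumeration.
Missing tip states integrate out as vectors of ones. Branch lengths are
taken from the tree as given (typically the molecular tree's substitution
lengths; pass a chronogram to reconstruct on time instead). Nodes whose two
best states are within 0.05 of each other are flagged equivocal, mirroring
how basal nodes of the parasitism reconstruction are reported. For the
sexual-parasitism character, k = 4: 0 = males never attach, 1 = temporary
attachment, 2 = facultative parasitism, 3 = obligate parasitism.

## Relaxed-clock dating (`chronos`)

Two-step design: per-partition branch lengths and covariances are
estimated once on the fixed rooted topology (F84+Gamma, third codon
positions excluded; partitions codon1+2, rRNA, tRNA), and the MCMC then
uses only the multivariate-normal summary — the likelihood of a chronogram
is the MVN density of the estimated lengths around duration times the
arithmetic mean of the endpoint node rates, summed over partitions with
unlinked rates. Negative length estimates are clamped to zero.

Rates follow geometric Brownian motion: node log-rates diffuse with
variance nu per Myr (no -nu*t/2 mean correction by default; the synthetic
generator exposes a flag for it). Priors are gamma distributions specified
by mean and standard deviation, in the multidivtime parameterisation:
root age (rttm, rttmsd; defaults 420 Myr each, i.e. 4.2 in 100-Myr units),
root rate (rtrate, rtratesd; derivable from data as mean tip-root path
length divided by rttm), and Brownian constant (brownmean, brownsd;
defaults 0.005/Myr, i.e. 0.5 per 100 Myr). Internal node ages are uniform
in proportions of the root age: the density carries a T^-k normalisation
(k internal non-root nodes) so the root-age marginal equals its gamma
prior, which a prior-only run verifies. Calibration constraints truncate by
rejection; a feasibility pass (max of descendant lower bounds vs min of
ancestral upper bounds) diagnoses contradictory sets before sampling.

Proposal kernels (the originals are not published; these are declared
equivalents): uniform draws of each internal age within its locally
feasible interval, a windowed root-age slide, Gaussian log-rate walks, a nu
multiplier, a whole-tree age scaling, and a correlated move that scales all
ages up while shifting all log-rates down. The last is essential: age and
rate enter the likelihood only through their product, so without it chains
cannot traverse the age-rate ridge and credible intervals collapse well
below nominal coverage; the coverage study in the test suite verifies
calibration with the move in place. Diagonal branch covariances run through a delta-update
fast path (local moves recompute only adjacent branch terms) that is
cross-validated to produce samples identical to the generic full-recompute
path; dense covariances use the generic path. Default chain settings are
100,000 burn-in cycles and 10,000 samples taken every 100 cycles, with at
least two replicate chains from different seeds compared by split-R-hat on
the root age (warning above 1.1). Tests and the calibration study use
shorter chains (2,500 burn-in, 800 samples every 3 sweeps) on 10-taxon
trees, which the coverage study shows is sufficient at that problem size.

## Diversification rates (`divrate`)

The stem-age method-of-moments estimator r = ln(n(1-eps)+eps)/t gives the
net diversification rate (speciation minus extinction, per lineage per Myr)
for a clade of n extant species with stem age t under relative extinction
eps = d/b, evaluated at eps = 0 and eps = 0.95. Rates are reported rounded
half-up to 4 decimals and coverage percentages to 1 decimal, matching
table conventions. Two packaged fixtures carry the published inputs: the
per-family diversity table (with its printed totals row) and the per-clade
(n, t) rate inputs. Two printed high-extinction rates differ from the
values computed from the printed inputs by one unit in the fourth decimal;
the package reports the computed values (see the test suite's rate-table
docstring for the rounding analysis).

## Synthetic data (`synthgen`)

Defaults emulate the study conditions: a birth-death tree grown to 77
extant taxa (b = 0.055, d = 0.025 per lineage per Myr, giving a realistic
extinction fraction and crown ages near the Cretaceous origin of the
group); geometric-Brownian rates around 7.4e-4 subst/site/Myr with
nu = 0.005/Myr; a five-partition alignment of 14,611 sites (codon1/2/3
3,744 each, rRNA 2,273, tRNA 1,106) under partition-specific GTR+Gamma
models with mitogenome-flavoured heterogeneity (AT-rich, slow second
positions; fast, biased third positions); contiguous missing blocks in a
minority of taxa, mimicking failed sequencing of a mitogenome region; and
a 4-state Mk trait at q = 0.004/Myr. Every generator is a pure function of
parameters and a seed.

What the synthetic validation does not show: real mitogenomes violate the
simulator's assumptions (no indels, site-independence, stationarity and
homogeneity of the substitution process, a correctly specified clock
model), so passing recovery tests demonstrates the correctness of the
implementations under their own models, not robustness of the biological
conclusions to model misspecification.

## Numerical choices

- Gamma categories: equal-probability conditional means; alpha initialised
  at 0.5, empirical base frequencies as the frequency initialiser.
- Pruning rescaling at every internal node; lnL tolerance 1e-6 for branch
  optimisation; branch lengths bounded to [0, 20].
- Hessian steps 1e-4*(1+|length|); covariance PSD-projected by eigenvalue
  clipping.
- RELL tie tolerance 1e-9 (relative); AU fits require at least two scales
  with interior bootstrap proportions.
- MCMC branch-duration floor 1e-8 Myr inside the Brownian prior; fixed
  (lower = upper) calibrations pin ages exactly and disable whole-tree
  scaling moves.
- Trees are canonicalised (rooted at the first taxon's pendant edge,
  children ordered by smallest descendant label) wherever byte-stable
  output matters.

## Known limitations

- No SPR/TBR search, codon models, invariant-sites class, or heterotachy.
- No uncorrelated-rates or Dirichlet-process clocks, fossil tip-dating, or
  marginal-likelihood estimation.
- The Mk family is restricted to the symmetric single-rate model.
- The NJ implementation is O(n^3) and the NNI search re-optimises all
  branch lengths per neighbour; both are intended for the dozens-of-taxa
  scale of this workflow, not thousands of tips.
- In rooted likelihood trees the root-child branch lengths are individually
  unidentifiable; dating consumes them through clade-keyed estimates and a
  pseudo-inverse covariance when the Hessian is singular.
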