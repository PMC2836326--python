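# mitophylo

Partitioned mitogenomic phylogenetics and macroevolution for anglerfishes
(and any clade with similar data): codon-aware dataset preparation with
RY-recoding, partitioned GTR/F84+Γ likelihood with per-site scores, RELL
bootstrap and approximately unbiased (AU) topology tests, Mk1 maximum-
likelihood ancestral-state reconstruction, Bayesian autocorrelated
relaxed-clock divergence dating under fossil/biogeographic calibration
bounds, and stem-age net diversification rates.

The package is aimed at molecular systematists who analyse concatenated
mitogenome (or comparable multi-partition) alignments and want the whole
workflow — prep → tree → topology tests → character evolution → dating →
diversification — as a scripted, seeded, testable pipeline rather than a
chain of separate programs. A synthetic-data module generates study-scale
datasets (by default ~77 taxa, five partitions, 14,611 sites, a birth-death
chronogram with autocorrelated lognormal rates, and a 4-state trait) with
known truth, so every stage is validated without any sequence download.

## The models in brief

- **Likelihood.** Felsenstein pruning with per-node rescaling under GTR or
  F84 with discrete-gamma rate variation, independent parameters per
  partition (codon positions 1/2/3, rRNA, tRNA) and per-partition
  branch-length multipliers; NNI hill-climbing from a neighbour-joining
  start; branch-length covariances from the observed Fisher information.
- **Topology tests.** RELL resampling of per-site log-likelihoods; the AU
  test fits probit bootstrap proportions across resample scales r to
  z(r) = d√r + c/√r and reports p = 1 − Φ(d − c).
- **Ancestral states.** Mk1 (k states, one rate q; P_stay(t) = 1/k +
  (k−1)/k·e^(−kqt)), q fitted by ML, marginal node probabilities by the
  inside-outside (rerooting) recursion. Used for the 4-state male
  sexual-parasitism character of deep-sea anglerfishes.
- **Dating.** Two-step relaxed clock in the multidivtime tradition:
  branch-length estimates and covariances per partition, then MCMC over
  node ages, geometric-Brownian node rates and the Brownian constant ν,
  with gamma priors specified by (mean, sd) and hard calibration bounds.
- **Diversification.** The stem-age moment estimator
  r = ln(n(1−ε)+ε)/t at relative extinction ε ∈ {0, 0.95}.

See `docs/methods.md` for assumptions, priors, proposal kernels, numerical
choices and limitations.

## Worked example

Per-clade net diversification rates from the packaged diversity and
stem-age inputs (`mitophylo divrate`, or `divrate.diversification_table`):

```
          clade  n_species  stem_age_myr  r_eps0  r_eps0.95
     Lophioidei         25         134.7  0.0239     0.0059
Ogcocephaloidei         54         129.2  0.0309     0.0100
 Antennarioidei         66         125.6  0.0334     0.0115
   Chaunacoidei         15         117.2  0.0231     0.0045
    Ceratioidei        161         117.2  0.0434     0.0187
   Lophiiformes        321         157.0  0.0368     0.0180
```

Each row divides the log of the extinction-corrected species count by the
clade's stem age: under a pure-birth reading (ε = 0) the deep-sea
Ceratioidei diversified at 0.0434 lineages/lineage/Myr, roughly a third
faster than any other suborder and faster than the order-wide average
(0.0368) — the quantitative footprint of their bathypelagic radiation.

Ancestral reconstruction of male attachment mode (0 = never attach,
1 = temporary, 2 = facultative parasite, 3 = obligate parasite) on a small
time-scaled ceratioid tree:

```python
from mitophylo import ancrecon
from mitophylo.treeio import parse_newick
import pandas as pd

tree = parse_newick("(((Cryptopsaras:25,Ceratias:25):20,"
                    "(Linophryne:30,Haplophryne:30):15):15,Gigantactis:60);")
trait = pd.Series({"Cryptopsaras": 3, "Ceratias": 3, "Linophryne": 3,
                   "Haplophryne": 3, "Gigantactis": 1})
rec = ancrecon.reconstruct(tree, trait, k=4)
print(f"fitted q = {rec.model.q:.6f}  lnL = {rec.log_likelihood:.4f}")
```

```
fitted q = 0.001850  lnL = -4.3998
                                                   clade   P0    P1    P2    P3
                                   Ceratias,Cryptopsaras 0.000 0.001 0.000 0.999
                                  Haplophryne,Linophryne 0.000 0.001 0.000 0.998
            Ceratias,Cryptopsaras,Haplophryne,Linophryne 0.001 0.008 0.001 0.989
Ceratias,Cryptopsaras,Gigantactis,Haplophryne,Linophryne 0.023 0.187 0.023 0.767
```

With four obligate-parasitic tips the interior nodes reconstruct as
obligate parasitism with ≥0.99 marginal probability, while the root —
pulled toward the temporarily-attaching outgroup lineage — is less certain
(P3 = 0.767 vs P1 = 0.187), the same qualitative pattern of confident
derived nodes and equivocal basal nodes seen in the real character data.

## Command line

`mitophylo` exposes the stages as subcommands: `simulate`, `prep`
(`--variant {12n3rRTn,123nRTn,12nRTn}`), `mltree`, `sitelnl`, `autest`,
`ancrec`, `date`, `divrate`, and `run --config config.yaml` for the full
pipeline (see `examples/config.yaml`); every run writes a manifest with
the seeds and config hash, and re-running a config reproduces its outputs
byte-for-byte.

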