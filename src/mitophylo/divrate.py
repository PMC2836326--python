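"""Net diversification rates by the stem-age method-of-moments estimator.

For a clade of n extant species whose stem lineage originated t Myr ago,
the Magallon-Sanderson moment estimator of the net diversification rate
r = b - d under a relative extinction rate eps = d/b is

    r = ln(n * (1 - eps) + eps) / t        (events/lineage/Myr)

eps = 0 gives the pure-birth (no extinction) bound; eps = 0.95 a
high-extinction scenario. The module also computes taxon-coverage
percentages from a diversity table. Rates are reported to 4 decimals and
percentages to 1 decimal, rounding half-up, matching standard table
formatting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd


def round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def stem_mom_rate(n: int, t: float, epsilon: float = 0.0) -> float:
    """Method-of-moments net diversification rate from a stem age.

    n: extant species count (>= 1); t: stem age in Myr (> 0);
    epsilon: relative extinction rate d/b in [0, 1).
    """
    if n < 1:
        raise ValueError("need at least one surviving lineage (n >= 1)")
    if t <= 0:
        raise ValueError("stem age t must be > 0")
    if not 0 <= epsilon < 1:
        raise ValueError("epsilon must be in [0, 1)")
    return math.log(n * (1.0 - epsilon) + epsilon) / t


@dataclass
class DiversificationEstimate:
    clade: str
    n: int
    t: float
    epsilon: float
    r: float


def diversification_table(inputs: pd.DataFrame,
                          epsilons=(0.0, 0.95),
                          decimals: int = 4) -> pd.DataFrame:
    """Per-clade rates at each epsilon, rounded half-up for reporting.

    ``inputs`` has columns clade, n_species, stem_age_myr (one row per
    clade, including any order-wide total row). Rows lacking a stem age are
    skipped with a warning column rather than an error.
    """
    rows = []
    for rec in inputs.to_dict("records"):
        clade, n = rec["clade"], int(rec["n_species"])
        t = rec.get("stem_age_myr")
        if t is None or pd.isna(t):
            continue
        row = {"clade": clade, "n_species": n, "stem_age_myr": float(t)}
        for eps in epsilons:
            r = stem_mom_rate(n, float(t), eps)
            row[f"r_eps{eps:g}"] = round_half_up(r, decimals)
        rows.append(row)
    return pd.DataFrame(rows)


def coverage_summary(diversity: pd.DataFrame) -> pd.DataFrame:
    """Percent of genera and species sampled, per clade and in total.

    ``diversity`` is indexed by clade with columns genera_sampled,
    genera_total, species_sampled, species_total. A zero total yields a
    missing percentage (NaN), not 0.
    """
    def pct(sampled, total):
        if total == 0:
            return float("nan")
        return round_half_up(100.0 * sampled / total, 1)

    out = diversity.copy()
    if "Total" not in out.index:
        out.loc["Total"] = diversity.sum()
    out["genera_pct"] = [pct(r.genera_sampled, r.genera_total) for r in out.itertuples()]
    out["species_pct"] = [pct(r.species_sampled, r.species_total) for r in out.itertuples()]
    return out


def packaged_path(name: str):
    """Filesystem path of a packaged CSV fixture."""
    return resources.files("mitophylo.data").joinpath(f"{name}.csv")


def packaged_table(name: str) -> pd.DataFrame:
    """Load a packaged CSV fixture (table1_diversity, table8_inputs,
    calibration_constraints)."""
    with resources.files("mitophylo.data").joinpath(f"{name}.csv").open() as fh:
        return pd.read_csv(fh)
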