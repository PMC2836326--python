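"""Dataset preparation for partitioned mitogenomic likelihood analysis.

Three transforms turn an annotated concatenated alignment into the analysis
datasets: (1) exclusion of positions that two protein-coding genes share
through overlapping reading frames (the shared nucleotides are kept once,
attributed to the upstream gene); (2) RY-recoding of third codon positions
(purines -> A, pyrimidines -> C) so that only transversions carry signal at
the fast, saturation-prone sites, or outright exclusion of those sites; and
(3) taxon subsampling proportional to the log of clade species diversity,
picking maximally phylogenetically diverse representatives, which guards
divergence-time estimation against the node-density effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .alignment import IUPAC_COMPAT, PartitionedAlignment

#: Dataset variants: how third codon positions are treated.
VARIANT_TREATMENTS = {
    "12n3rRTn": "RY_recode",   # third positions RY-recoded (A/G->A, C/T->C)
    "123nRTn": "include",      # all positions as observed
    "12nRTn": "exclude",       # third positions dropped
}


@dataclass(frozen=True)
class DatasetVariant:
    name: str

    def __post_init__(self) -> None:
        if self.name not in VARIANT_TREATMENTS:
            raise ValueError(f"unknown variant {self.name!r}; "
                             f"choose from {sorted(VARIANT_TREATMENTS)}")

    @property
    def third_position_treatment(self) -> str:
        return VARIANT_TREATMENTS[self.name]


def exclude_frame_overlaps(aln: PartitionedAlignment,
                           gene_coords: pd.DataFrame) -> PartitionedAlignment:
    """Drop the downstream copy of reading-frame overlaps between genes.

    ``gene_coords`` gives each gene's genomic interval (columns gene,
    genome_start, genome_end; 1-based inclusive). In a gene-by-gene
    concatenated alignment, nucleotides shared by two overlapping genes
    appear twice; this removes the leading sites of the downstream gene so
    every genomic position is represented once, attributed to the upstream
    gene. Overlaps spanning more than two genes are rejected.
    """
    coords = gene_coords.sort_values("genome_start").reset_index(drop=True)
    lo = int(coords["genome_start"].min())
    hi = int(coords["genome_end"].max())
    cover = np.zeros(hi - lo + 1, dtype=int)
    for rec in coords.to_dict("records"):
        cover[int(rec["genome_start"]) - lo:int(rec["genome_end"]) - lo + 1] += 1
    if cover.max() > 2:
        pos = int(np.argmax(cover > 2)) + lo
        raise ValueError(f"genomic position {pos} covered by more than two genes")
    drop = np.zeros(aln.n_sites, dtype=bool)
    for i in range(len(coords) - 1):
        up, down = coords.iloc[i], coords.iloc[i + 1]
        n_overlap = int(up["genome_end"]) - int(down["genome_start"]) + 1
        if n_overlap <= 0:
            continue
        down_sites = np.flatnonzero(aln.gene_of_site == down["gene"])
        if len(down_sites) < n_overlap:
            raise ValueError(f"gene {down['gene']} shorter than its overlap")
        drop[down_sites[:n_overlap]] = True
    return aln.subset_sites(np.flatnonzero(~drop))


def _ry_symbol(sym: str) -> str:
    """RY-recode one third-position symbol: purine-only codes -> A,
    pyrimidine-only codes -> C, anything mixed or missing -> '?'."""
    compat = IUPAC_COMPAT.get(sym.upper())
    if compat is None:
        raise ValueError(f"unknown symbol {sym!r} at a third codon position")
    if sym in "-?":
        return "?"
    purine = set(compat) <= {"A", "G"}
    pyrimidine = set(compat) <= {"C", "T"}
    if purine:
        return "A"
    if pyrimidine:
        return "C"
    return "?"


def ry_recode(aln: PartitionedAlignment, variant: DatasetVariant) -> PartitionedAlignment:
    """Apply a dataset variant's third-codon-position treatment.

    All taxa are recoded alike (the likelihood engine here has no
    restriction on all-binary partitions, so no taxon is exempted).
    """
    treatment = variant.third_position_treatment
    if treatment == "include":
        return aln.subset_sites(np.arange(aln.n_sites))
    third = aln.sites_where("codon3")
    if treatment == "exclude":
        keep = np.setdiff1d(np.arange(aln.n_sites), third)
        return aln.subset_sites(keep)
    matrix = aln.matrix.copy()
    recode = np.vectorize(_ry_symbol, otypes=["<U1"])
    if len(third):
        matrix[:, third] = recode(matrix[:, third])
    return PartitionedAlignment(list(aln.taxa), matrix,
                                aln.partition_of_site.copy(), aln.gene_of_site.copy())


# -- log-diversity taxon subsampling -------------------------------------

def allocate_slots_log_diversity(species_totals: dict[str, int], total_slots: int,
                                 floor: int = 2) -> dict[str, int]:
    """Slots per group proportional to log10 species diversity.

    Every group receives at least ``floor`` slots; the remainder is assigned
    by largest remainder against the log10-proportional quotas. With the
    anglerfish suborder diversities and 11 slots this yields 3 for the most
    species-rich suborder (Ceratioidei) and 2 for each of the other four.
    """
    groups = list(species_totals)
    if total_slots < floor * len(groups):
        raise ValueError(f"need at least {floor * len(groups)} slots for "
                         f"{len(groups)} groups (floor {floor})")
    w = np.log10(np.maximum([species_totals[g] for g in groups], 1.0))
    if w.sum() == 0:
        w = np.ones(len(groups))
    quota = total_slots * w / w.sum()
    alloc = {g: floor for g in groups}
    remaining = total_slots - floor * len(groups)
    deficit = quota - floor
    for idx in np.argsort(-deficit):
        if remaining == 0:
            break
        alloc[groups[idx]] += 1
        remaining -= 1
    return alloc


def _pd_length(tree_index: dict, chosen: set[str]) -> float:
    """Phylogenetic diversity: total length of edges on paths among chosen."""
    total = 0.0
    for below, length in tree_index["edges"]:
        inside = len(below & chosen)
        if inside >= 1 and len(chosen) > inside:
            total += length
    return total


def _index_tree(tree: dendropy.Tree) -> dict:
    edges = []
    for nd in tree.postorder_node_iter():
        if nd.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        edges.append((below, nd.edge.length or 0.0))
    return {"edges": edges}


def max_pd_subset(tree: dendropy.Tree, candidates: list[str], n: int) -> list[str]:
    """Greedy maximum-phylogenetic-diversity subset of size n.

    Greedy insertion is exact for the PD objective (each step adds the taxon
    whose pendant path to the current subtree is longest).
    """
    if n >= len(candidates):
        return sorted(candidates)
    idx = _index_tree(tree)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    # seed with the farthest candidate pair
    best_pair, best_d = None, -1.0
    for i, a in enumerate(candidates):
        for b in candidates[i + 1:]:
            d = pdm.patristic_distance(taxa[a], taxa[b])
            if d > best_d:
                best_pair, best_d = (a, b), d
    chosen = set(best_pair)
    while len(chosen) < n:
        gains = {}
        base = _pd_length(idx, chosen)
        for c in candidates:
            if c in chosen:
                continue
            gains[c] = _pd_length(idx, chosen | {c}) - base
        nxt = max(sorted(gains), key=lambda c: gains[c])
        chosen.add(nxt)
    return sorted(chosen)


def subsample_by_log_diversity(
    species_totals: dict[str, int],
    group_of_taxon: dict[str, str],
    total_slots: int,
    tree: dendropy.Tree,
    floor: int = 2,
) -> dict[str, list[str]]:
    """Pick taxa per group: slots by log diversity, members by maximum PD.

    ``species_totals`` maps each group (e.g. suborder) to its described
    species count; ``group_of_taxon`` assigns every sampled taxon in the
    tree to a group. Returns group -> chosen taxon labels.
    """
    groups: dict[str, list[str]] = {g: [] for g in species_totals}
    for taxon, g in group_of_taxon.items():
        if g not in groups:
            raise ValueError(f"taxon {taxon!r} assigned to unknown group {g!r}")
        groups[g].append(taxon)
    for g, members in groups.items():
        if not members:
            raise ValueError(f"group {g!r} has no sampled taxa")
    alloc = allocate_slots_log_diversity(species_totals, total_slots, floor=floor)
    return {g: max_pd_subset(tree, sorted(members), alloc[g])
            for g, members in groups.items()}


def load_diversity_table(path) -> pd.DataFrame:
    """Read a per-family diversity CSV and aggregate it per suborder.

    A row with suborder "Total" carries the table's own printed totals and
    is passed through as-is (printed totals can disagree with the column
    sums by a unit when a source table is internally inconsistent).
    """
    df = pd.read_csv(path)
    cols = ["genera_sampled", "genera_total", "species_sampled", "species_total"]
    totals = df[df["suborder"] == "Total"]
    agg = df[df["suborder"] != "Total"].groupby("suborder", sort=False)[cols].sum()
    if len(totals):
        agg.loc["Total"] = totals.iloc[0][cols]
    if (agg["genera_sampled"] > agg["genera_total"]).any() or \
       (agg["species_sampled"] > agg["species_total"]).any():
        raise ValueError("sampled counts exceed described totals")
    return agg
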