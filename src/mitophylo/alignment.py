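"""Partition-annotated nucleotide alignments and their file formats.

The central object is :class:`PartitionedAlignment`: a site x taxon character
matrix in which every site carries exactly one partition label (codon1,
codon2, codon3, rRNA or tRNA) and a gene name. Gaps introduced by alignment
are treated as missing data throughout, as are '?' and fully ambiguous codes.

File IO goes through Biopython's AlignIO (FASTA, relaxed PHYLIP, NEXUS); the
partition annotation travels in a sidecar TSV of 1-based inclusive gene
intervals (gene, start, end, class, codon_phase, strand).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PARTITION_LABELS = ("codon1", "codon2", "codon3", "rRNA", "tRNA")
MISSING_SYMBOLS = frozenset("-?")

#: IUPAC nucleotide codes -> set of compatible bases (used for tip partial
#: likelihoods and for RY-recoding decisions). '-' and '?' mean "no data".
IUPAC_COMPAT = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "?": "ACGT", "-": "ACGT", "X": "ACGT",
}

_FORMAT_BY_SUFFIX = {
    ".fasta": "fasta", ".fa": "fasta", ".fas": "fasta", ".fna": "fasta",
    ".phy": "phylip-relaxed", ".phylip": "phylip-relaxed",
    ".nex": "nexus", ".nexus": "nexus",
}


def _normalise_format(fmt: str) -> str:
    return {"phylip": "phylip-relaxed"}.get(fmt, fmt)


@dataclass
class PartitionedAlignment:
    """Aligned sequences with per-site partition and gene annotation.

    Coordinates are 0-based half-open internally; every user-facing table
    (partition TSVs, reports) uses 1-based inclusive intervals.
    """

    taxa: list[str]
    matrix: np.ndarray                # (n_taxa, n_sites), dtype '<U1', uppercase
    partition_of_site: np.ndarray     # (n_sites,) labels from PARTITION_LABELS
    gene_of_site: np.ndarray          # (n_sites,) gene names

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        self.partition_of_site = np.asarray(self.partition_of_site, dtype=object)
        self.gene_of_site = np.asarray(self.gene_of_site, dtype=object)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise ValueError("matrix must be (n_taxa, n_sites)")
        if self.partition_of_site.shape != (self.n_sites,):
            raise ValueError("one partition label per site required")
        if self.gene_of_site.shape != (self.n_sites,):
            raise ValueError("one gene name per site required")
        bad = set(self.partition_of_site) - set(PARTITION_LABELS)
        if bad:
            raise ValueError(f"unknown partition labels: {sorted(bad)}")

    # -- basic views ------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_taxa, n_sites): True where a cell carries no data."""
        return np.isin(self.matrix, ("-", "?"))

    def sites_where(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.partition_of_site == label)

    def partition_counts(self) -> dict[str, int]:
        return {lab: int((self.partition_of_site == lab).sum()) for lab in PARTITION_LABELS}

    def subset_sites(self, idx: np.ndarray) -> "PartitionedAlignment":
        idx = np.asarray(idx)
        return PartitionedAlignment(
            list(self.taxa), self.matrix[:, idx],
            self.partition_of_site[idx], self.gene_of_site[idx],
        )

    def subset_taxa(self, names: list[str]) -> "PartitionedAlignment":
        order = [self.taxa.index(n) for n in names]
        return PartitionedAlignment(
            list(names), self.matrix[order, :],
            self.partition_of_site.copy(), self.gene_of_site.copy(),
        )

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def empirical_base_frequencies(self, labels: list[str] | None = None) -> np.ndarray:
        """Observed A,C,G,T frequencies over unambiguous cells (optionally
        restricted to the given partition labels)."""
        m = self.matrix
        if labels is not None:
            m = m[:, np.isin(self.partition_of_site, labels)]
        counts = np.array([(m == b).sum() for b in "ACGT"], dtype=float)
        if counts.sum() == 0:
            return np.full(4, 0.25)
        return counts / counts.sum()

    # -- IO ---------------------------------------------------------------
    def to_msa(self) -> MultipleSeqAlignment:
        records = [
            SeqRecord(Seq("".join(row)), id=name, description="",
                      annotations={"molecule_type": "DNA"})
            for name, row in zip(self.taxa, self.matrix)
        ]
        return MultipleSeqAlignment(records)

    def write(self, path: str | Path, fmt: str | None = None) -> None:
        path = Path(path)
        fmt = _normalise_format(fmt or _FORMAT_BY_SUFFIX.get(path.suffix.lower(), "fasta"))
        AlignIO.write(self.to_msa(), str(path), fmt)

    def write_partition_table(self, path: str | Path) -> None:
        pd.DataFrame(self.partition_intervals()).to_csv(path, sep="\t", index=False)

    def write_partition_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"n_sites": self.n_sites,
                       "intervals": self.partition_intervals()}, fh, indent=1)

    def partition_intervals(self) -> list[dict]:
        """Compress per-site annotation to 1-based inclusive intervals."""
        out: list[dict] = []
        i = 0
        while i < self.n_sites:
            gene = self.gene_of_site[i]
            cls, phase = _site_class_phase(self.partition_of_site[i])
            j = i
            expect_pos = _codon_pos(self.partition_of_site[i])
            while j + 1 < self.n_sites and self.gene_of_site[j + 1] == gene:
                nxt = self.partition_of_site[j + 1]
                ncls, _ = _site_class_phase(nxt)
                if ncls != cls:
                    break
                if cls == "CDS":
                    if _codon_pos(nxt) != (expect_pos % 3) + 1:
                        break
                    expect_pos = _codon_pos(nxt)
                j += 1
            out.append({"gene": gene, "start": i + 1, "end": j + 1,
                        "class": cls, "codon_phase": phase, "strand": "+"})
            i = j + 1
        return out


def _site_class_phase(label: str) -> tuple[str, int]:
    if label.startswith("codon"):
        return "CDS", int(label[-1])
    return label, 0


def _codon_pos(label: str) -> int:
    return int(label[-1]) if label.startswith("codon") else 0


def read_alignment(path: str | Path, fmt: str | None = None) -> MultipleSeqAlignment:
    path = Path(path)
    fmt = _normalise_format(fmt or _FORMAT_BY_SUFFIX.get(path.suffix.lower(), "fasta"))
    return AlignIO.read(str(path), fmt)


def load_partitioned_alignment(
    aln_path: str | Path,
    partition_table: str | Path | pd.DataFrame,
    fmt: str | None = None,
) -> PartitionedAlignment:
    """Read an alignment plus its partition TSV into a PartitionedAlignment.

    The table holds 1-based inclusive intervals with columns
    (gene, start, end, class, codon_phase[, strand]); class is CDS, rRNA or
    tRNA. For CDS intervals codon_phase gives the codon position (1-3) of the
    interval's first site and positions cycle 1,2,3 from there.
    """
    msa = read_alignment(aln_path, fmt)
    taxa = [rec.id for rec in msa]
    matrix = np.array([list(str(rec.seq).upper()) for rec in msa], dtype="<U1")
    if isinstance(partition_table, (str, Path)):
        partition_table = pd.read_csv(partition_table, sep="\t")
    labels, genes = partition_labels_from_table(partition_table, matrix.shape[1])
    return PartitionedAlignment(taxa, matrix, labels, genes)


def partition_labels_from_table(table: pd.DataFrame, n_sites: int) -> tuple[np.ndarray, np.ndarray]:
    labels = np.empty(n_sites, dtype=object)
    genes = np.empty(n_sites, dtype=object)
    covered = np.zeros(n_sites, dtype=bool)
    for rec in table.to_dict("records"):
        start, end = int(rec["start"]) - 1, int(rec["end"])  # to 0-based half-open
        if not (0 <= start < end <= n_sites):
            raise ValueError(f"interval {rec} outside alignment of {n_sites} sites")
        if covered[start:end].any():
            raise ValueError(f"interval {rec} overlaps an earlier interval")
        covered[start:end] = True
        genes[start:end] = rec["gene"]
        cls = str(rec["class"])
        if cls in ("rRNA", "tRNA"):
            labels[start:end] = cls
        elif cls == "CDS":
            phase = int(rec.get("codon_phase", 1) or 1)
            pos = (phase - 1 + np.arange(end - start)) % 3 + 1
            labels[start:end] = np.array([f"codon{p}" for p in pos], dtype=object)
        elif cls in PARTITION_LABELS:
            labels[start:end] = cls
        else:
            raise ValueError(f"unknown partition class {cls!r}")
    if not covered.all():
        raise ValueError(f"{int((~covered).sum())} sites lack partition annotation")
    return labels, genes


def tip_partials(matrix: np.ndarray) -> np.ndarray:
    """Map a (n_taxa, n_sites) symbol matrix to 0/1 partial-likelihood
    vectors of shape (n_taxa, n_sites, 4). Unknown symbols are rejected."""
    known = sorted(IUPAC_COMPAT)
    lut = np.zeros((len(known), 4))
    for i, sym in enumerate(known):
        for b in IUPAC_COMPAT[sym]:
            lut[i, "ACGT".index(b)] = 1.0
    flat = np.char.upper(matrix.ravel())
    codes = np.searchsorted(known, flat)
    ok = (codes < len(known)) & (np.array(known, dtype="<U1")[np.minimum(codes, len(known) - 1)] == flat)
    if not ok.all():
        bad = sorted(set(flat[~ok]))
        raise ValueError(f"unknown sequence symbols: {bad}")
    return lut[codes].reshape(*matrix.shape, 4)


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=n, description="") for n, s in records.items()),
        str(path), "fasta",
    )
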