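"""Supermatrix assembly and coverage-based dataset-reduction rules.

Concatenates per-gene ortholog alignments into a single partitioned
matrix and implements the reduction rules used to derive the study
datasets: a minimum-taxon threshold per gene ("mintax4"/"mintax8"), a
group-coverage rule requiring every predefined taxon group to contribute
at least one sequence (the "most purposive subset"), exclusion of flagged
ribosomal-protein genes ("noRPs"), and reduction of focal groups to their
single best-covered representative taxon ("4Synd").

All filters read only the taxon-by-gene presence mask and the RP flags;
they never modify column content of retained genes, so they are
order-preserving, idempotent, and commute pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from synphy.io_formats import GAP, AlignedOrthologGroup


@dataclass
class TaxonGrouping:
    """Assignment of every matrix taxon to exactly one group label."""

    assignment: dict[str, str]

    def label(self, taxon: str) -> str:
        return self.assignment[taxon]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for taxon, lab in self.assignment.items():
            out.setdefault(lab, []).append(taxon)
        return out

    def validate_for(self, taxa) -> None:
        missing = [t for t in taxa if t not in self.assignment]
        if missing:
            raise ValueError(f"grouping missing taxa: {missing}")


class SuperMatrix:
    """Concatenated alignment with partition map and presence mask.

    Attributes
    ----------
    taxa : list of taxon ids (row order)
    genes : list of gene ids (partition order)
    columns : (n_taxa, total_length) array of single characters (dtype U1)
    partition_map : gene_id -> (start, end), 0-based half-open
    presence : (n_taxa, n_genes) bool; True iff the taxon contributed at
        least one non-gap residue to the gene
    flags : gene_id -> is_rp
    """

    def __init__(self, taxa, genes, columns, partition_map, presence, flags):
        self.taxa = list(taxa)
        self.genes = list(genes)
        self.columns = np.asarray(columns, dtype="U1")
        self.partition_map = dict(partition_map)
        self.presence = np.asarray(presence, dtype=bool)
        self.flags = dict(flags)
        self.models: dict[str, str] = {}
        self._check()

    def _check(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene_id in supermatrix")
        pos = 0
        for g in self.genes:
            start, end = self.partition_map[g]
            if start != pos or end <= start:
                raise ValueError("partition intervals must be contiguous, in order")
            pos = end
        if pos != self.columns.shape[1]:
            raise ValueError("partition intervals must cover the full matrix")
        if self.presence.shape != (len(self.taxa), len(self.genes)):
            raise ValueError("presence mask shape mismatch")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def total_length(self) -> int:
        return self.columns.shape[1]

    def row_string(self, i: int) -> str:
        return "".join(self.columns[i])

    def gene_columns(self, gene_id: str) -> np.ndarray:
        start, end = self.partition_map[gene_id]
        return self.columns[:, start:end]

    def gene_length(self, gene_id: str) -> int:
        start, end = self.partition_map[gene_id]
        return end - start

    def gene_group(self, gene_id: str) -> AlignedOrthologGroup:
        """Extract one gene back out as an :class:`AlignedOrthologGroup`."""
        gi = self.genes.index(gene_id)
        cols = self.gene_columns(gene_id)
        seqs = {
            t: "".join(cols[i])
            for i, t in enumerate(self.taxa)
            if self.presence[i, gi]
        }
        return AlignedOrthologGroup(gene_id, seqs, self.flags.get(gene_id, False))

    def coverage_positions(self) -> np.ndarray:
        """Per-taxon covered amino-acid positions: sum of gene lengths over
        present genes (mask-based, not gap-count-based)."""
        lengths = np.array([self.gene_length(g) for g in self.genes])
        return (self.presence * lengths[None, :]).sum(axis=1)

    def coverage_report(self) -> list[dict]:
        pos = self.coverage_positions()
        return [
            {
                "taxon": t,
                "genes_covered": int(self.presence[i].sum()),
                "positions_covered": int(pos[i]),
                "percent": round(100.0 * pos[i] / self.total_length, 2),
            }
            for i, t in enumerate(self.taxa)
        ]

    # -- construction -------------------------------------------------------

    @classmethod
    def from_rows(cls, taxa, rows, genes, partition_map, flags=None):
        columns = np.array([list(r) for r in rows], dtype="U1")
        n_genes = len(genes)
        presence = np.zeros((len(taxa), n_genes), dtype=bool)
        for gi, g in enumerate(genes):
            start, end = partition_map[g]
            presence[:, gi] = (columns[:, start:end] != GAP).any(axis=1)
        return cls(taxa, genes, columns, partition_map, presence, flags or {})

    def subset_genes(self, keep_ids) -> "SuperMatrix":
        """New matrix retaining the given genes (input order preserved)."""
        keep = [g for g in self.genes if g in set(keep_ids)]
        col_idx = np.concatenate(
            [np.arange(*self.partition_map[g]) for g in keep]
        ) if keep else np.zeros(0, dtype=int)
        new_map, pos = {}, 0
        for g in keep:
            length = self.gene_length(g)
            new_map[g] = (pos, pos + length)
            pos += length
        gene_idx = [self.genes.index(g) for g in keep]
        return SuperMatrix(
            self.taxa,
            keep,
            self.columns[:, col_idx],
            new_map,
            self.presence[:, gene_idx],
            {g: self.flags.get(g, False) for g in keep},
        )

    def subset_taxa(self, keep_taxa) -> "SuperMatrix":
        """New matrix over the given taxa; genes losing every taxon are
        dropped; remaining rows/columns are unchanged."""
        keep_set = set(keep_taxa)
        rows = [i for i, t in enumerate(self.taxa) if t in keep_set]
        sub_presence = self.presence[rows, :]
        keep_genes = [g for gi, g in enumerate(self.genes) if sub_presence[:, gi].any()]
        reduced = SuperMatrix(
            [self.taxa[i] for i in rows],
            self.genes,
            self.columns[rows, :],
            self.partition_map,
            sub_presence,
            self.flags,
        )
        return reduced.subset_genes(keep_genes)


def concatenate(groups: list[AlignedOrthologGroup], taxa: list[str]) -> SuperMatrix:
    """Concatenate ortholog groups into a supermatrix over a fixed taxon order.

    Taxa missing from a gene are filled with gaps over that gene's
    interval and marked absent in the presence mask.
    """
    ids = [g.gene_id for g in groups]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id among groups")
    taxa = list(taxa)
    taxon_set = set(taxa)
    for g in groups:
        extra = set(g.taxa) - taxon_set
        if extra:
            raise ValueError(f"gene {g.gene_id} contains unknown taxa: {sorted(extra)}")
    total = sum(g.length for g in groups)
    columns = np.full((len(taxa), total), GAP, dtype="U1")
    presence = np.zeros((len(taxa), len(groups)), dtype=bool)
    partition_map = {}
    pos = 0
    for gi, g in enumerate(groups):
        partition_map[g.gene_id] = (pos, pos + g.length)
        for ti, taxon in enumerate(taxa):
            seq = g.sequences.get(taxon)
            if seq is not None:
                columns[ti, pos : pos + g.length] = list(seq)
                presence[ti, gi] = True
        pos += g.length
    flags = {g.gene_id: g.is_rp for g in groups}
    return SuperMatrix(taxa, ids, columns, partition_map, presence, flags)


def filter_min_taxa(matrix: SuperMatrix, t: int) -> SuperMatrix:
    """Retain exactly the genes present in at least ``t`` taxa.

    The "mintax4"/"mintax8" rule. A taxon left with zero genes is an
    error (downstream likelihood needs data at every leaf), as is a
    threshold above the taxon count.
    """
    if t < 1:
        raise ValueError("min-taxa threshold must be >= 1")
    if t > matrix.n_taxa:
        raise ValueError(f"threshold {t} exceeds taxon count {matrix.n_taxa}")
    counts = matrix.presence.sum(axis=0)
    keep = [g for gi, g in enumerate(matrix.genes) if counts[gi] >= t]
    reduced = matrix.subset_genes(keep)
    orphaned = [
        taxon
        for i, taxon in enumerate(reduced.taxa)
        if not reduced.presence[i].any()
    ]
    if orphaned:
        raise ValueError(f"min-taxa filter would orphan taxa: {orphaned}")
    return reduced


def filter_group_coverage(matrix: SuperMatrix, grouping: TaxonGrouping) -> SuperMatrix:
    """Retain genes represented by >= 1 present taxon in every group (MPS)."""
    grouping.validate_for(matrix.taxa)
    labels = sorted({grouping.label(t) for t in matrix.taxa})
    label_rows = {
        lab: [i for i, t in enumerate(matrix.taxa) if grouping.label(t) == lab]
        for lab in labels
    }
    keep = []
    for gi, g in enumerate(matrix.genes):
        if all(matrix.presence[rows, gi].any() for rows in label_rows.values()):
            keep.append(g)
    return matrix.subset_genes(keep)


def exclude_flagged(matrix: SuperMatrix) -> SuperMatrix:
    """Remove every gene whose RP flag is set (the "noRPs" rule)."""
    keep = [g for g in matrix.genes if not matrix.flags.get(g, False)]
    if not keep:
        raise ValueError("all genes are flagged; refusing to build an empty matrix")
    return matrix.subset_genes(keep)


def select_representatives(
    matrix: SuperMatrix, grouping: TaxonGrouping, focal_groups
) -> SuperMatrix:
    """Keep one best-covered taxon per focal group (the "4Synd" rule).

    Coverage is measured in covered amino-acid positions (sum of gene
    lengths over present genes); exact ties break to the
    lexicographically smaller taxon id. Non-focal taxa are untouched;
    genes that lose all their taxa are dropped.
    """
    grouping.validate_for(matrix.taxa)
    focal_groups = set(focal_groups)
    groups = grouping.groups()
    for lab in focal_groups:
        if not groups.get(lab):
            raise ValueError(f"focal group {lab!r} has no taxa in the matrix")
    coverage = matrix.coverage_positions()
    cov_by_taxon = dict(zip(matrix.taxa, coverage))
    keep_taxa = []
    for taxon in matrix.taxa:
        lab = grouping.label(taxon)
        if lab not in focal_groups:
            keep_taxa.append(taxon)
            continue
        members = [t for t in groups[lab] if t in set(matrix.taxa)]
        best = min(members, key=lambda t: (-cov_by_taxon[t], t))
        if taxon == best:
            keep_taxa.append(taxon)
    return matrix.subset_taxa(keep_taxa)
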