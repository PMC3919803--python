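"""Readers and writers for the formats the pipeline touches.

Per-gene FASTA alignments (one file per ortholog group), the TSV gene
manifest carrying the ribosomal-protein flag, supermatrix FASTA plus a
RAxML-style partition definition file, and Newick trees (re-exported from
:mod:`synphy.trees`).

Internally all column coordinates are 0-based half-open; the partition
file dialect is 1-based inclusive. Conversion between the two lives in
:func:`interval_to_partition_line` / :func:`parse_partition_line` only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from synphy.trees import PhyloTree, read_newick, write_newick  # noqa: F401

GAP = "-"
_STANDARD = set("ARNDCQEGHILKMFPSTWYV")


class FormatError(ValueError):
    """A file violates the expected format; the message names the file."""


def _normalize_residue(c: str) -> str:
    c = c.upper()
    if c in _STANDARD:
        return c
    if c in {"-", ".", "*"}:
        return GAP
    return "X"  # any other code is treated as fully ambiguous


@dataclass
class AlignedOrthologGroup:
    """One gene's aligned amino-acid sequences keyed by taxon.

    All sequences share a common length; a taxon whose row is entirely
    gaps is treated as absent and must not appear in ``sequences``.
    """

    gene_id: str
    sequences: dict[str, str]
    is_rp: bool = False

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise FormatError(
                f"gene {self.gene_id}: unequal sequence lengths {sorted(lengths)}"
            )
        for taxon, seq in self.sequences.items():
            if seq and set(seq) <= {GAP}:
                raise FormatError(
                    f"gene {self.gene_id}: taxon {taxon} is all gaps; drop it first"
                )

    @property
    def length(self) -> int:
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @classmethod
    def from_records(
        cls, gene_id: str, records: list[tuple[str, str]], is_rp: bool = False
    ) -> "AlignedOrthologGroup":
        """Build from (taxon, sequence) pairs, normalizing residues and
        dropping all-gap taxa; duplicate taxa raise :class:`FormatError`."""
        seqs: dict[str, str] = {}
        for taxon, seq in records:
            if taxon in seqs:
                raise FormatError(f"gene {gene_id}: duplicate taxon {taxon}")
            seqs[taxon] = "".join(_normalize_residue(c) for c in seq)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise FormatError(
                f"gene {gene_id}: unequal sequence lengths {sorted(lengths)}"
            )
        seqs = {t: s for t, s in seqs.items() if set(s) - {GAP}}
        return cls(gene_id=gene_id, sequences=seqs, is_rp=is_rp)

    def restrict(self, taxa) -> "AlignedOrthologGroup":
        """Sub-alignment over the given taxa (those present in this group)."""
        keep = {t: s for t, s in self.sequences.items() if t in set(taxa)}
        return AlignedOrthologGroup(self.gene_id, keep, self.is_rp)


@dataclass
class ManifestRow:
    gene_id: str
    is_rp: bool
    path: str


@dataclass
class GeneManifest:
    """Ordered gene ledger: (gene_id, is_rp flag, alignment file path)."""

    rows: list[ManifestRow] = field(default_factory=list)
    base_dir: Path | None = None  # paths resolve relative to this directory

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.rows]
        if len(ids) != len(set(ids)):
            raise FormatError("duplicate gene_id in manifest")

    def resolve(self, row: ManifestRow) -> Path:
        p = Path(row.path)
        if not p.is_absolute() and self.base_dir is not None:
            p = self.base_dir / p
        return p

    @classmethod
    def read(cls, path: str | os.PathLike) -> "GeneManifest":
        path = Path(path)
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["gene_id", "is_rp", "path"]:
                raise FormatError(f"{path}: expected header gene_id/is_rp/path")
            for ln in fh:
                if not ln.strip():
                    continue
                gene_id, is_rp, p = ln.rstrip("\n").split("\t")[:3]
                rows.append(ManifestRow(gene_id, is_rp.lower() in {"1", "true"}, p))
        return cls(rows=rows, base_dir=path.parent)

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tis_rp\tpath\n")
            for r in self.rows:
                fh.write(f"{r.gene_id}\t{int(r.is_rp)}\t{r.path}\n")


def read_alignment_fasta(
    path: str | os.PathLike, gene_id: str | None = None, is_rp: bool = False
) -> AlignedOrthologGroup:
    """Read one per-gene FASTA alignment; gene_id defaults to the file stem."""
    path = Path(path)
    if gene_id is None:
        gene_id = path.stem
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append((rec.id, str(rec.seq)))
    except Exception as exc:
        raise FormatError(f"{path}: not parseable as FASTA: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    try:
        return AlignedOrthologGroup.from_records(gene_id, records, is_rp=is_rp)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_alignment_fasta(group: AlignedOrthologGroup, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in group.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def read_ortholog_groups(manifest: GeneManifest) -> list[AlignedOrthologGroup]:
    """Load every alignment referenced by the manifest, in manifest order."""
    groups = []
    for row in manifest.rows:
        path = manifest.resolve(row)
        if not path.exists():
            raise FormatError(f"{path}: referenced by manifest but missing")
        groups.append(read_alignment_fasta(path, gene_id=row.gene_id, is_rp=row.is_rp))
    return groups


# -- partition file dialect -------------------------------------------------


def interval_to_partition_line(model: str, name: str, start: int, end: int) -> str:
    """0-based half-open [start, end) -> "MODEL, name = first-last" (1-based
    inclusive, RAxML dialect)."""
    if end <= start:
        raise ValueError(f"empty interval for partition {name}")
    return f"{model}, {name} = {start + 1}-{end}"


def parse_partition_line(line: str) -> tuple[str, str, int, int]:
    """Inverse of :func:`interval_to_partition_line`; returns 0-based
    half-open coordinates."""
    try:
        model_part, rest = line.split(",", 1)
        name, coords = rest.split("=")
        first, last = coords.strip().split("-")
        start, end = int(first) - 1, int(last)
    except ValueError as exc:
        raise FormatError(f"bad partition line: {line!r}") from exc
    if start < 0 or end <= start:
        raise FormatError(f"bad coordinates in partition line: {line!r}")
    return model_part.strip(), name.strip(), start, end


def write_supermatrix(
    matrix,
    alignment_path: str | os.PathLike,
    partition_path: str | os.PathLike,
    models: dict[str, str] | None = None,
) -> None:
    """Write a supermatrix as FASTA plus a RAxML-style partition file.

    Missing genes are encoded as runs of "-" in each taxon's row (the
    presence mask is the authority on coverage, not gap counts).
    ``models`` maps gene_id to the model name printed on its partition
    line; unlisted genes print as "LG".
    """
    if matrix.n_genes == 0 or matrix.n_taxa == 0:
        raise ValueError("refusing to write an empty supermatrix")
    models = models or {}
    with open(alignment_path, "w") as fh:
        for i, taxon in enumerate(matrix.taxa):
            fh.write(f">{taxon}\n{matrix.row_string(i)}\n")
    with open(partition_path, "w") as fh:
        for gene_id in matrix.genes:
            start, end = matrix.partition_map[gene_id]
            fh.write(
                interval_to_partition_line(
                    models.get(gene_id, "LG"), gene_id, start, end
                )
                + "\n"
            )


def read_supermatrix(
    alignment_path: str | os.PathLike, partition_path: str | os.PathLike
):
    """Read back a supermatrix written by :func:`write_supermatrix`.

    The presence mask is reconstructed from the gap pattern (a taxon is
    present in a gene iff it has >= 1 non-gap residue in its interval),
    which matches how the writer encodes missingness. RP flags are not
    stored in these files and come back False.
    """
    from synphy.supermatrix import SuperMatrix  # deferred: avoid import cycle

    taxa, rows = [], []
    for rec in SeqIO.parse(str(alignment_path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq))
    if not taxa:
        raise FormatError(f"{alignment_path}: no FASTA records")
    if len({len(r) for r in rows}) != 1:
        raise FormatError(f"{alignment_path}: unequal row lengths")
    genes, partition_map, model_map = [], {}, {}
    with open(partition_path) as fh:
        for ln in fh:
            if not ln.strip():
                continue
            model, name, start, end = parse_partition_line(ln)
            genes.append(name)
            partition_map[name] = (start, end)
            model_map[name] = model
    matrix = SuperMatrix.from_rows(taxa, rows, genes, partition_map)
    matrix.models = model_map
    return matrix


def read_newick_file(path: str | os.PathLike) -> PhyloTree:
    return read_newick(Path(path).read_text())


def write_newick_file(tree: PhyloTree, path: str | os.PathLike) -> None:
    Path(path).write_text(write_newick(tree) + "\n")
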