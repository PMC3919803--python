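"""Singleton/dingleton column classification and "-DS" pruning.

Rare apomorphic column states concentrate on long terminal branches and
fuel long-branch attraction. The "-DS" reduction deletes every alignment
column containing a singleton (a residue carried by exactly one sequence)
or a dingleton (a residue shared by exactly two sequences and seen in no
other sequence). Gaps and the ambiguity code "X" are disregarded when
tallying — an ambiguous state is not evidence of a private character.

Two readings of the dingleton definition are supported:

* tally mode (default): a residue with tally exactly 2, regardless of
  what the remaining sequences carry;
* strict mode: additionally requires the remaining non-gap residues to be
  monomorphic.

The tally reading is the default because the strict one is nearly inert
at realistic taxon counts and could not produce the strong alignment
shortening this reduction is known for.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from synphy.io_formats import GAP
from synphy.supermatrix import SuperMatrix

logger = logging.getLogger(__name__)

_IGNORED = {GAP, "X", "."}


@dataclass(frozen=True)
class ColumnClassification:
    index: int
    labels: frozenset[str]  # subset of {constant, singleton, dingleton, other}
    tally: dict[str, int]


def classify_column(
    column, index: int = -1, strict: bool = False
) -> ColumnClassification:
    """Classify one alignment column by its residue tally.

    Gaps and "X" are excluded before tallying. A column with at most one
    distinct residue is ``constant`` (and never singleton/dingleton —
    private characters require variation). Otherwise the column is
    ``singleton`` if some residue occurs exactly once, ``dingleton`` if
    some residue occurs exactly twice (strict mode: and the remaining
    residues are all identical), and ``other`` if neither applies.
    """
    tally = Counter(c for c in column if c not in _IGNORED)
    labels: set[str] = set()
    if len(tally) <= 1:
        labels.add("constant")
    else:
        counts = tally.values()
        if 1 in counts:
            labels.add("singleton")
        if strict:
            for residue, n in tally.items():
                if n == 2 and len(tally) == 2:
                    labels.add("dingleton")
                    break
        elif 2 in counts:
            labels.add("dingleton")
        if not labels:
            labels.add("other")
    return ColumnClassification(index, frozenset(labels), dict(tally))


def classify_columns(matrix: SuperMatrix, strict: bool = False):
    """Classification for every column of a supermatrix, in column order."""
    return [
        classify_column(matrix.columns[:, j], index=j, strict=strict)
        for j in range(matrix.total_length)
    ]


def prune_singletons_dingletons(
    matrix: SuperMatrix, strict: bool = False
) -> SuperMatrix:
    """Remove every column labeled singleton or dingleton (the "-DS" rule).

    Partition intervals are recomputed per gene; the gene set is
    preserved unless a gene loses all of its columns, in which case it is
    dropped with a logged warning. Idempotent, and never removes a column
    whose non-gap residues are all identical.
    """
    classes = classify_columns(matrix, strict=strict)
    keep_mask = np.array(
        [not ({"singleton", "dingleton"} & c.labels) for c in classes], dtype=bool
    )
    new_genes, new_map, pos = [], {}, 0
    col_idx = []
    for g in matrix.genes:
        start, end = matrix.partition_map[g]
        kept = np.nonzero(keep_mask[start:end])[0] + start
        if kept.size == 0:
            logger.warning(
                "gene %s reduced to zero columns by -DS pruning; dropping it", g
            )
            continue
        new_genes.append(g)
        new_map[g] = (pos, pos + kept.size)
        pos += kept.size
        col_idx.append(kept)
    if not new_genes:
        raise ValueError("-DS pruning removed every column of every gene")
    columns = matrix.columns[:, np.concatenate(col_idx)]
    # presence is recomputed: a taxon may lose its last residues of a gene
    presence = np.zeros((matrix.n_taxa, len(new_genes)), dtype=bool)
    for gi, g in enumerate(new_genes):
        start, end = new_map[g]
        presence[:, gi] = (columns[:, start:end] != GAP).any(axis=1)
    return SuperMatrix(
        matrix.taxa,
        new_genes,
        columns,
        new_map,
        presence,
        {g: matrix.flags.get(g, False) for g in new_genes},
    )
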