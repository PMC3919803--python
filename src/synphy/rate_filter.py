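"""Tree-length gene-rate proxy and fast-gene exclusion.

A gene's evolutionary rate is proxied by the total branch length of a
small maximum-likelihood tree inferred from the primer-taxon sequences
only (the core reference species whose sequences seed the ortholog
groups). Genes whose tree length strictly exceeds the 75% empirical
quantile of the rateable genes are excluded ("slow" datasets).

Quantile convention: with ``n`` rateable genes the threshold is the
``floor(q * n)``-th smallest tree length and exceedance is strict, so
410 distinct rates at q = 0.75 retain exactly 307 genes. Genes with
fewer than two primer taxa cannot be rated; they are retained (the
filter acts only on measured rates) and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from synphy.distances import nj_start_tree
from synphy.io_formats import GAP, AlignedOrthologGroup
from synphy.likelihood import optimize_branch_lengths
from synphy.models import RateModel

logger = logging.getLogger(__name__)

#: Default primer taxa: the seven core-set reference species.
PRIMER_TAXA = (
    "Schistosoma_mansoni",
    "Lottia_gigantea",
    "Helobdella_robusta",
    "Capitella_capitata",
    "Caenorhabditis_elegans",
    "Daphnia_pulex",
    "Apis_mellifera",
)


@dataclass
class GeneRateRecord:
    gene_id: str
    tree_length: float | None  # None: unrateable (< 2 primer taxa)
    n_taxa: int

    @property
    def rateable(self) -> bool:
        return self.tree_length is not None

    def __post_init__(self) -> None:
        if self.tree_length is not None and self.tree_length < 0:
            raise ValueError("tree_length must be >= 0")


def estimate_gene_rate(
    group: AlignedOrthologGroup,
    model: RateModel,
    primer_taxa=PRIMER_TAXA,
    bl_tol: float = 1e-3,
) -> GeneRateRecord:
    """Total ML tree length of the gene restricted to its primer taxa.

    Builds an NJ topology on ML pairwise distances, optimizes branch
    lengths under ``model``, and returns the summed lengths. The result
    is invariant to non-primer content (those rows are discarded first).
    """
    sub = group.restrict(primer_taxa)
    present = [t for t in sub.taxa]
    if len(present) < 2:
        logger.warning(
            "gene %s: only %d primer taxa present; unrateable",
            group.gene_id,
            len(present),
        )
        return GeneRateRecord(group.gene_id, None, len(present))
    # all-gap columns in the restricted alignment carry no signal
    cols = np.array([list(sub.sequences[t]) for t in present], dtype="U1")
    keep = (cols != GAP).any(axis=0)
    aln = {t: "".join(cols[i, keep]) for i, t in enumerate(present)}
    start = nj_start_tree(aln, model)
    tree, _ = optimize_branch_lengths(aln, start, model, tol=bl_tol)
    return GeneRateRecord(group.gene_id, tree.total_length(), len(present))


def rate_threshold(records: list[GeneRateRecord], q: float = 0.75) -> float:
    """The floor(q*n)-th smallest tree length over the rateable records."""
    if not (0.0 < q < 1.0):
        raise ValueError("quantile q must be in (0, 1)")
    lengths = sorted(r.tree_length for r in records if r.rateable)
    if not lengths:
        raise ValueError("no rateable gene-rate records")
    k = max(1, math.floor(q * len(lengths)))
    return lengths[k - 1]


def exclude_fast_genes(records: list[GeneRateRecord], q: float = 0.75) -> list[str]:
    """Gene ids retained after excluding rates strictly above the quantile.

    Unrateable genes are always retained. Order follows the input.
    """
    threshold = rate_threshold(records, q)
    retained = [
        r.gene_id for r in records if not r.rateable or r.tree_length <= threshold
    ]
    return retained
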