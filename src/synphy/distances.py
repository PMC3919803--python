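"""Maximum-likelihood pairwise distances and neighbor-joining start trees.

Pairwise ML distances maximize the two-sequence likelihood under the
same +I+G+F model used downstream; neighbor joining (via scikit-bio) on
that distance matrix provides the fixed starting topology whose branch
lengths the likelihood module then optimizes. Full ML topology search is
deliberately out of scope: the downstream consumers (the gene-rate proxy
and per-gene model selection) are robust to the exact topology.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from skbio import DistanceMatrix
from skbio.tree import nj

from synphy.likelihood import MAX_BRANCH_LENGTH, _codes_dict
from synphy.models import AMBIG, RateModel
from synphy.trees import Node, PhyloTree, read_newick

_TINY = 1e-300


def ml_pairwise_distance(
    codes_a: np.ndarray, codes_b: np.ndarray, model: RateModel
) -> float:
    """ML distance (expected substitutions per site) between two rows.

    Sites where either sequence is ambiguous are ignored. Pairs with no
    comparable site fall back to the branch-length ceiling.
    """
    ok = (codes_a != AMBIG) & (codes_b != AMBIG)
    if not ok.any():
        return MAX_BRANCH_LENGTH
    counts = np.zeros((20, 20))
    np.add.at(counts, (codes_a[ok].astype(int), codes_b[ok].astype(int)), 1.0)
    rates = model.category_rates()
    weights = np.full(len(rates), 1.0 / len(rates))
    pi = model.pi
    p_inv = model.p_inv
    ident = np.eye(20, dtype=bool)

    def neg_loglik(t: float) -> float:
        mix = np.zeros((20, 20))
        for r, w in zip(rates, weights):
            mix += w * model.transition_matrix(t, rate=r)
        joint = (1.0 - p_inv) * pi[:, None] * mix
        if p_inv > 0:
            joint[ident] += p_inv * pi
        return -float((counts * np.log(np.maximum(joint, _TINY))).sum())

    res = minimize_scalar(
        neg_loglik,
        bounds=(1e-8, MAX_BRANCH_LENGTH),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def ml_distance_matrix(alignment, model: RateModel) -> tuple[np.ndarray, list[str]]:
    codes = _codes_dict(alignment)
    taxa = list(codes)
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = ml_pairwise_distance(
                codes[taxa[i]], codes[taxa[j]], model
            )
    return D, taxa


def nj_start_tree(alignment, model: RateModel) -> PhyloTree:
    """Neighbor-joining tree on ML distances; negative NJ branch lengths
    are clamped to zero. Two-taxon alignments return a simple cherry."""
    D, taxa = ml_distance_matrix(alignment, model)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa for a tree")
    if len(taxa) == 2:
        half = D[0, 1] / 2.0
        return PhyloTree(Node(children=[Node(taxa[0], half), Node(taxa[1], half)]))
    dm = DistanceMatrix(D, ids=taxa)
    newick = str(nj(dm))
    tree = read_newick(newick)
    for br in tree.branches():
        if br.length < 0:
            br.length = 0.0
    return tree
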