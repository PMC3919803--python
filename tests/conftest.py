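"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings
from scipy.linalg import expm

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from synphy.io_formats import AlignedOrthologGroup
from synphy.models import AMBIG, AA_ORDER, encode_sequence
from synphy.supermatrix import concatenate
from synphy.trees import read_newick


def normalized_q(model) -> np.ndarray:
    """Rate matrix rebuilt from first principles (independent of the
    model's cached eigendecomposition)."""
    Q = model.S * model.pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q / -(model.pi * np.diag(Q)).sum()


def enumeration_loglik(alignment: dict[str, str], tree, model) -> float:
    """Brute-force likelihood by explicit summation over every joint
    assignment of states to the internal nodes, with transition matrices
    via scipy expm (independent of the package's eigendecomposition path).

    Exponential in the number of internal nodes; intended for trees with
    at most 3 internal nodes.
    """
    Q = normalized_q(model)
    codes = {t: encode_sequence(s) for t, s in alignment.items()}
    n_sites = len(next(iter(codes.values())))
    rates = model.category_rates()
    internals = [n for n in tree.preorder() if not n.is_leaf]
    index = {id(n): i for i, n in enumerate(internals)}
    m = len(internals)
    # all 20^m joint assignments, one column of states per internal node
    grids = np.meshgrid(*([np.arange(20)] * m), indexing="ij")
    assign = np.stack([g.ravel() for g in grids])  # (m, 20^m)

    def tip_vec(node):
        out = np.zeros((20, n_sites))
        for s in range(n_sites):
            c = codes[node.name][s]
            if c == AMBIG:
                out[:, s] = 1.0
            else:
                out[int(c), s] = 1.0
        return out

    lik_var = np.zeros(n_sites)
    for r in rates:
        P = {id(n): expm(Q * n.length * r) for n in tree.preorder()
             if n is not tree.root}
        term = np.repeat(
            model.pi[assign[index[id(tree.root)]]][:, None], n_sites, axis=1
        )
        for node in internals:
            for child in node.children:
                if child.is_leaf:
                    contrib = P[id(child)] @ tip_vec(child)  # (20, S)
                    term = term * contrib[assign[index[id(node)]], :]
                else:
                    term = (
                        term
                        * P[id(child)][
                            assign[index[id(node)]], assign[index[id(child)]]
                        ][:, None]
                    )
        lik_var += term.sum(axis=0) / len(rates)
    inv = np.zeros(n_sites)
    for s in range(n_sites):
        sets = []
        for t in codes:
            c = codes[t][s]
            sets.append(set(range(20)) if c == AMBIG else {int(c)})
        inv[s] = sum(model.pi[i] for i in set.intersection(*sets))
    return float(
        np.log(model.p_inv * inv + (1.0 - model.p_inv) * lik_var).sum()
    )


def random_alignment(rng, taxa, n_sites, gap_rate=0.1, x_rate=0.05):
    """Random amino-acid alignment with gaps and ambiguity codes."""
    alphabet = list(AA_ORDER)
    out = {}
    for t in taxa:
        chars = []
        for _ in range(n_sites):
            u = rng.random()
            if u < gap_rate:
                chars.append("-")
            elif u < gap_rate + x_rate:
                chars.append("X")
            else:
                chars.append(alphabet[rng.integers(0, 20)])
        out[t] = "".join(chars)
    # avoid all-gap rows
    for t in taxa:
        if set(out[t]) <= {"-", "X"}:
            out[t] = "A" + out[t][1:]
    return out


def toy_matrix(presence, flags=None, gene_length=3):
    """SuperMatrix built from a taxon-by-gene presence mask (bool array)."""
    presence = np.asarray(presence, dtype=bool)
    n_taxa, n_genes = presence.shape
    taxa = [f"t{i:02d}" for i in range(n_taxa)]
    flags = flags or {}
    groups = []
    for g in range(n_genes):
        rows = np.nonzero(presence[:, g])[0]
        seqs = {taxa[i]: "A" * gene_length for i in rows}
        groups.append(
            AlignedOrthologGroup(f"g{g:03d}", seqs, is_rp=flags.get(g, False))
        )
    return concatenate(groups, taxa)


@pytest.fixture
def quartet_tree():
    return read_newick("((A:0.1,B:0.2):0.07,(C:0.3,D:0.15):0.0);")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
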