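"""Per-gene best-fit empirical model by AIC and partition assignment.

Each gene is scored under the eight candidate exchangeability matrices
with +I +G +F on one shared tree: the topology comes from neighbor
joining on ML distances, branch lengths, the gamma shape and the
invariant-sites proportion are optimized once (under LG), and every
candidate is then evaluated on that fixed tree. Because the +F
frequencies are the gene's own observed frequencies — identical for all
candidates — and the shared p_inv/alpha/frequency parameters give every
candidate the same parameter count, AIC ranking reduces to lnL ranking
with a deterministic model-name tie-break.

Genes are then assigned to partitions named by their AIC-best model, or
by their second-best model when the best one is excluded from the
available set (the 7-partition scheme used when LG is unavailable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from synphy.distances import nj_start_tree
from synphy.io_formats import AlignedOrthologGroup
from synphy.likelihood import build_partition, PartitionedEngine, optimize_branch_lengths
from synphy.models import (
    MODEL_NAMES,
    RateModel,
    empirical_frequencies,
    encode_sequence,
    load_empirical_model,
)
from synphy.trees import PhyloTree

#: Free parameters shared by every +I+G+F candidate: p_inv (1), gamma
#: shape (1), and 19 free equilibrium frequencies.
K_SHARED = 21

_MODEL_RANK = {name: i for i, name in enumerate(MODEL_NAMES)}


@dataclass
class ModelFitResult:
    gene_id: str
    model: str
    lnl: float
    k: int = K_SHARED
    rank: int | None = None
    alpha: float | None = None
    p_inv: float | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.lnl


@dataclass
class PartitionScheme:
    """Partitions named by model, each holding its member gene ids.

    ``params`` carries per-partition (alpha, p_inv) used when the
    partitioned likelihood is evaluated; +F frequencies are always
    recomputed from the partition's own columns.
    """

    partitions: dict[str, list[str]]
    params: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for genes in self.partitions.values():
            for g in genes:
                if g in seen:
                    raise ValueError(f"gene {g} assigned to more than one partition")
                seen.add(g)

    @classmethod
    def single(
        cls, model: str, genes, alpha: float | None = None, p_inv: float = 0.0
    ) -> "PartitionScheme":
        return cls({model: list(genes)}, {model: {"alpha": alpha, "p_inv": p_inv}})


def _rank_fits(fits: list[ModelFitResult]) -> list[ModelFitResult]:
    fits = sorted(fits, key=lambda f: (f.aic, _MODEL_RANK[f.model]))
    for i, f in enumerate(fits, start=1):
        f.rank = i
    return fits


def _optimize_rate_params(
    alignment, tree: PhyloTree, base: RateModel
) -> tuple[float, float]:
    """Profile alpha and p_inv on a fixed tree (two alternating passes)."""
    leaf_order = tree.leaf_names()

    def lnl(alpha: float, p_inv: float) -> float:
        model = base.with_options(alpha=alpha, p_inv=p_inv)
        part = build_partition(model, alignment, leaf_order)
        return PartitionedEngine(tree, [part], leaf_order).loglik()

    alpha, p_inv = base.alpha or 1.0, base.p_inv
    for _ in range(2):
        res = minimize_scalar(
            lambda la: -lnl(float(np.exp(la)), p_inv),
            bounds=(np.log(0.05), np.log(50.0)),
            method="bounded",
            options={"xatol": 0.02},
        )
        alpha = float(np.exp(res.x))
        res = minimize_scalar(
            lambda p: -lnl(alpha, p),
            bounds=(0.0, 0.7),
            method="bounded",
            options={"xatol": 0.005},
        )
        p_inv = float(res.x)
    return alpha, p_inv


def fit_gene_models(
    group: AlignedOrthologGroup,
    candidate_models=MODEL_NAMES,
    base_model: str = "LG",
    n_cat: int = 4,
) -> list[ModelFitResult]:
    """Fit all candidate models to one gene; returns ranked results.

    The shared tree is NJ-started and branch-length-optimized under the
    base model (+I+G+F); alpha and p_inv are profiled once on that tree
    and reused for every candidate.
    """
    if len(group.taxa) < 2:
        raise ValueError(f"gene {group.gene_id}: need >= 2 taxa to fit a model")
    pi = empirical_frequencies(
        np.concatenate([encode_sequence(s) for s in group.sequences.values()])
    )
    if base_model not in candidate_models:
        base_model = candidate_models[0]
    base = load_empirical_model(base_model, pi=pi, p_inv=0.05, alpha=1.0, n_cat=n_cat)
    start = nj_start_tree(group, base)
    tree, _ = optimize_branch_lengths(group, start, base, tol=1e-3)
    alpha, p_inv = _optimize_rate_params(group, tree, base)
    tree, _ = optimize_branch_lengths(
        group, tree, base.with_options(alpha=alpha, p_inv=p_inv), tol=1e-3
    )
    fits = [
        fit_gene_model(group, name, tree=tree, pi=pi, alpha=alpha, p_inv=p_inv,
                       n_cat=n_cat)
        for name in candidate_models
    ]
    return _rank_fits(fits)


def fit_gene_model(
    group: AlignedOrthologGroup,
    model_name: str,
    tree: PhyloTree | None = None,
    pi: np.ndarray | None = None,
    alpha: float = 1.0,
    p_inv: float = 0.05,
    n_cat: int = 4,
) -> ModelFitResult:
    """lnL/AIC of one candidate model on a fixed (or freshly built) tree."""
    if len(group.taxa) < 2:
        raise ValueError(f"gene {group.gene_id}: need >= 2 taxa to fit a model")
    if pi is None:
        pi = empirical_frequencies(
            np.concatenate([encode_sequence(s) for s in group.sequences.values()])
        )
    model = load_empirical_model(model_name, pi=pi, p_inv=p_inv, alpha=alpha, n_cat=n_cat)
    if tree is None:
        start = nj_start_tree(group, model)
        tree, lnl = optimize_branch_lengths(group, start, model, tol=1e-3)
    else:
        leaf_order = tree.leaf_names()
        part = build_partition(model, group, leaf_order)
        lnl = PartitionedEngine(tree, [part], leaf_order).loglik()
    return ModelFitResult(
        gene_id=group.gene_id, model=model_name, lnl=lnl,
        alpha=alpha, p_inv=p_inv,
    )


def assign_partitions(
    fits_by_gene: dict[str, list[ModelFitResult]],
    available_models=MODEL_NAMES,
) -> PartitionScheme:
    """Assign each gene to its best available model's partition.

    A gene falls back to its second-best model when the best one is not
    in ``available_models`` (e.g. the 7-partition no-LG scheme); if
    neither ranked model is available that is an error. Partitions are
    emitted in the fixed model-name order; empty ones are omitted.
    Per-partition alpha/p_inv are the means over member genes' fits.
    """
    available = set(available_models)
    chosen: dict[str, list[str]] = {}
    alphas: dict[str, list[float]] = {}
    pinvs: dict[str, list[float]] = {}
    for gene_id, fits in fits_by_gene.items():
        ranked = sorted(fits, key=lambda f: f.rank if f.rank else 99)
        if len(ranked) < 2 or ranked[0].rank != 1:
            raise ValueError(f"gene {gene_id}: needs ranked fits (ranks 1 and 2)")
        if ranked[0].model in available:
            pick = ranked[0]
        elif ranked[1].model in available:
            pick = ranked[1]
        else:
            raise ValueError(
                f"gene {gene_id}: neither {ranked[0].model} nor {ranked[1].model} "
                "is in the available model set"
            )
        chosen.setdefault(pick.model, []).append(gene_id)
        if pick.alpha is not None:
            alphas.setdefault(pick.model, []).append(pick.alpha)
        if pick.p_inv is not None:
            pinvs.setdefault(pick.model, []).append(pick.p_inv)
    ordered = {m: chosen[m] for m in MODEL_NAMES if m in chosen}
    params = {
        m: {
            "alpha": float(np.mean(alphas[m])) if m in alphas else None,
            "p_inv": float(np.mean(pinvs[m])) if m in pinvs else 0.0,
        }
        for m in ordered
    }
    return PartitionScheme(ordered, params)


def build_partition_models(matrix, scheme: PartitionScheme) -> dict[str, RateModel]:
    """Per-partition +I+G+F models for the partitioned likelihood.

    Frequencies are observed counts (add-one smoothed) over the
    partition's own columns; alpha/p_inv come from the scheme's params
    (defaults: alpha 1.0, p_inv 0).
    """
    models = {}
    for name, gene_ids in scheme.partitions.items():
        codes = np.concatenate(
            [
                encode_sequence("".join(matrix.gene_columns(g)[i]))
                for g in gene_ids
                for i in range(matrix.n_taxa)
            ]
        )
        pi = empirical_frequencies(codes)
        p = scheme.params.get(name, {})
        models[name] = load_empirical_model(
            name,
            pi=pi,
            p_inv=p.get("p_inv") or 0.0,
            alpha=p.get("alpha") or 1.0,
        )
    return models
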