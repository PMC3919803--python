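"""Concatenation and the coverage-based dataset-reduction rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synphy.io_formats import AlignedOrthologGroup
from synphy.supermatrix import (
    TaxonGrouping,
    concatenate,
    exclude_flagged,
    filter_group_coverage,
    filter_min_taxa,
    select_representatives,
)

from conftest import toy_matrix


def presence_masks(n_taxa=6, max_genes=8):
    """Presence masks where every gene and every taxon is covered."""
    return (
        st.integers(2, max_genes)
        .flatmap(
            lambda g: st.lists(
                st.lists(st.booleans(), min_size=n_taxa, max_size=n_taxa),
                min_size=g,
                max_size=g,
            )
        )
        .map(lambda rows: np.array(rows, dtype=bool).T)
        .map(_ensure_covered)
    )


def _ensure_covered(mask):
    mask = mask.copy()
    for g in range(mask.shape[1]):
        if not mask[:, g].any():
            mask[g % mask.shape[0], g] = True
    for t in range(mask.shape[0]):
        if not mask[t].any():
            mask[t, t % mask.shape[1]] = True
    return mask


class TestConcatenate:
    def test_intervals_and_gap_fill(self):
        g1 = AlignedOrthologGroup("g1", {"A": "R" * 100, "B": "K" * 100})
        g2 = AlignedOrthologGroup("g2", {"A": "D" * 50})
        matrix = concatenate([g1, g2], ["A", "B"])
        assert matrix.total_length == 150
        assert matrix.partition_map == {"g1": (0, 100), "g2": (100, 150)}
        assert matrix.row_string(1)[100:] == "-" * 50
        assert not matrix.presence[1, 1] and matrix.presence[1, 0]

    def test_duplicate_gene_rejected(self):
        g = AlignedOrthologGroup("g1", {"A": "R"})
        with pytest.raises(ValueError, match="duplicate"):
            concatenate([g, g], ["A"])

    def test_unknown_taxon_rejected(self):
        g = AlignedOrthologGroup("g1", {"A": "R", "Z": "K"})
        with pytest.raises(ValueError, match="unknown"):
            concatenate([g], ["A"])

    def test_presence_row_sums_match_file_scan(self, rng):
        # oracle: per-group scan of which taxa carry a non-gap residue
        taxa = [f"t{i}" for i in range(19)]
        groups = []
        expected = {t: 0 for t in taxa}
        for gi in range(40):
            members = rng.choice(19, size=rng.integers(2, 19), replace=False)
            seqs = {taxa[i]: "ACD" for i in members}
            for i in members:
                expected[taxa[i]] += 1
            groups.append(AlignedOrthologGroup(f"g{gi}", seqs))
        matrix = concatenate(groups, taxa)
        for i, t in enumerate(taxa):
            assert matrix.presence[i].sum() == expected[t]


class TestMinTaxa:
    def test_paper_threshold_removes_sparse_gene(self):
        mask = np.zeros((4, 2), dtype=bool)
        mask[:3, 0] = True  # gene 0: 3 taxa
        mask[:4, 1] = True  # gene 1: 4 taxa
        matrix = toy_matrix(mask)
        reduced = filter_min_taxa(matrix, 4)
        assert reduced.genes == ["g001"]

    def test_t1_is_identity(self):
        mask = _ensure_covered(np.eye(4, 5, dtype=bool))
        matrix = toy_matrix(mask)
        reduced = filter_min_taxa(matrix, 1)
        assert reduced.genes == matrix.genes
        assert np.array_equal(reduced.columns, matrix.columns)

    def test_against_mask_count_oracle(self, rng):
        mask = _ensure_covered(rng.random((10, 30)) < 0.6)
        matrix = toy_matrix(mask)
        for t in (2, 4, 8):
            expected = [
                matrix.genes[g] for g in range(30) if mask[:, g].sum() >= t
            ]
            try:
                reduced = filter_min_taxa(matrix, t)
            except ValueError:
                # legal only when some taxon would lose every gene
                kept = np.array([g in expected for g in matrix.genes])
                assert not mask[:, kept].any(axis=1).all()
                continue
            assert reduced.genes == expected

    def test_threshold_above_taxon_count_rejected(self):
        matrix = toy_matrix(np.ones((3, 2), dtype=bool))
        with pytest.raises(ValueError):
            filter_min_taxa(matrix, 4)

    def test_orphaned_taxon_is_error(self):
        # t04 appears only in the sparse gene that the filter removes
        mask = np.array(
            [[1, 1], [1, 1], [1, 0], [1, 0], [0, 1]], dtype=bool
        )
        matrix = toy_matrix(mask)
        with pytest.raises(ValueError, match="t04"):
            filter_min_taxa(matrix, 4)


class TestGroupCoverage:
    def _grouping(self, matrix, labels):
        return TaxonGrouping(dict(zip(matrix.taxa, labels)))

    def test_gene_missing_one_group_removed(self):
        # five groups; gene 0 misses the singleton group, gene 1 covers all
        mask = np.ones((5, 2), dtype=bool)
        mask[1, 0] = False
        matrix = toy_matrix(mask)
        grouping = self._grouping(matrix, ["A", "S", "B", "M", "N"])
        reduced = filter_group_coverage(matrix, grouping)
        assert reduced.genes == ["g001"]

    def test_random_masks_match_predicate_oracle(self, rng):
        labels = ["A", "A", "S", "B", "B", "M", "N", "N", "N", "N"]
        mask = _ensure_covered(rng.random((10, 40)) < 0.5)
        matrix = toy_matrix(mask)
        grouping = self._grouping(matrix, labels)
        reduced = filter_group_coverage(matrix, grouping)
        expected = []
        for g in range(40):
            covered = {labels[t] for t in range(10) if mask[t, g]}
            if covered == set(labels):
                expected.append(matrix.genes[g])
        assert reduced.genes == expected

    def test_incomplete_grouping_rejected(self):
        matrix = toy_matrix(np.ones((3, 2), dtype=bool))
        with pytest.raises(ValueError, match="missing"):
            filter_group_coverage(matrix, TaxonGrouping({"t00": "A", "t01": "B"}))


class TestExcludeFlagged:
    def test_no_flags_is_identity(self):
        matrix = toy_matrix(np.ones((3, 4), dtype=bool))
        reduced = exclude_flagged(matrix)
        assert reduced.genes == matrix.genes

    def test_flagged_genes_removed(self):
        matrix = toy_matrix(np.ones((3, 5), dtype=bool), flags={1: True, 3: True})
        reduced = exclude_flagged(matrix)
        assert reduced.genes == ["g000", "g002", "g004"]

    def test_all_flagged_is_error(self):
        matrix = toy_matrix(np.ones((3, 2), dtype=bool), flags={0: True, 1: True})
        with pytest.raises(ValueError):
            exclude_flagged(matrix)


class TestSelectRepresentatives:
    def test_highest_position_coverage_wins(self):
        # taxon t00 covers 2 genes (6 positions), t01 covers 1 (3 positions)
        mask = np.array([[1, 1], [1, 0], [1, 1]], dtype=bool)
        matrix = toy_matrix(mask)
        grouping = TaxonGrouping({"t00": "F", "t01": "F", "t02": "out"})
        reduced = select_representatives(matrix, grouping, {"F"})
        assert reduced.taxa == ["t00", "t02"]

    def test_tie_breaks_lexicographically(self):
        mask = np.ones((2, 2), dtype=bool)
        matrix = toy_matrix(mask)
        grouping = TaxonGrouping({"t00": "F", "t01": "F"})
        reduced = select_representatives(matrix, grouping, {"F"})
        assert reduced.taxa == ["t00"]

    def test_singleton_group_kept(self):
        matrix = toy_matrix(np.ones((2, 2), dtype=bool))
        grouping = TaxonGrouping({"t00": "F", "t01": "out"})
        reduced = select_representatives(matrix, grouping, {"F"})
        assert set(reduced.taxa) == {"t00", "t01"}

    def test_genes_losing_all_taxa_dropped(self):
        mask = np.array([[1, 0], [0, 1]], dtype=bool)
        matrix = toy_matrix(mask)
        grouping = TaxonGrouping({"t00": "F", "t01": "F"})
        reduced = select_representatives(matrix, grouping, {"F"})
        assert reduced.genes == ["g000"] and reduced.taxa == ["t00"]


class TestFilterAlgebra:
    @settings(max_examples=40, deadline=None)
    @given(presence_masks())
    def test_min_taxa_idempotent_and_composition(self, mask):
        matrix = toy_matrix(mask)
        try:
            once = filter_min_taxa(matrix, 2)
            twice = filter_min_taxa(once, 2)
        except ValueError:
            return  # orphaned taxon: filter legitimately refuses
        assert twice.genes == once.genes
        # composition rule: t=3 after t=2 equals t=3 directly
        try:
            composed = filter_min_taxa(once, 3)
            direct = filter_min_taxa(matrix, 3)
        except ValueError:
            return
        assert composed.genes == direct.genes
        assert np.array_equal(composed.columns, direct.columns)

    @settings(max_examples=40, deadline=None)
    @given(presence_masks(), st.booleans())
    def test_mask_filters_commute(self, mask, rp_first):
        flags = {g: g % 3 == 0 for g in range(mask.shape[1])}
        matrix = toy_matrix(mask, flags=flags)
        try:
            if rp_first:
                a = filter_min_taxa(exclude_flagged(matrix), 2)
            else:
                a = exclude_flagged(filter_min_taxa(matrix, 2))
        except ValueError:
            return
        try:
            b = (
                exclude_flagged(filter_min_taxa(matrix, 2))
                if rp_first
                else filter_min_taxa(exclude_flagged(matrix), 2)
            )
        except ValueError:
            return
        assert a.genes == b.genes
        assert np.array_equal(a.columns, b.columns)
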