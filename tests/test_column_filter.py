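"""Singleton/dingleton classification and the -DS pruning rule."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synphy.column_filter import (
    classify_column,
    classify_columns,
    prune_singletons_dingletons,
)
from synphy.io_formats import AlignedOrthologGroup
from synphy.supermatrix import concatenate


def brute_labels(column, strict=False):
    """Independent re-statement of the definitions via a plain tally."""
    tally = Counter(c for c in column if c not in "-X.")
    if len(tally) <= 1:
        return frozenset({"constant"})
    labels = set()
    if any(n == 1 for n in tally.values()):
        labels.add("singleton")
    if strict:
        if len(tally) == 2 and 2 in tally.values():
            labels.add("dingleton")
    elif any(n == 2 for n in tally.values()):
        labels.add("dingleton")
    return frozenset(labels or {"other"})


class TestClassifyColumn:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ("AAAA", {"constant"}),
            ("AAAV", {"singleton"}),
            ("AA-VV", {"dingleton"}),  # gaps are not considered
            ("AAVVL", {"singleton", "dingleton"}),
            ("AAAVVV", {"other"}),
            ("----", {"constant"}),  # all-gap: empty tally
            ("A---", {"constant"}),  # one residue: no variation
            ("AXXV", {"singleton"}),  # X ignored like gaps
            ("AV---", {"singleton"}),  # two differing residues: two singletons
        ],
    )
    def test_examples(self, column, expected):
        got = classify_column(list(column))
        assert got.labels == frozenset(expected)

    def test_strict_dingleton_requires_monomorphic_remainder(self):
        assert "dingleton" in classify_column("AAVVL").labels
        assert "dingleton" not in classify_column("AAVVL", strict=True).labels
        assert "dingleton" in classify_column("AAVVV", strict=True).labels

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.sampled_from("AVLKR-X"), min_size=2, max_size=12),
        st.booleans(),
    )
    def test_matches_tally_oracle(self, column, strict):
        got = classify_column(column, strict=strict)
        assert got.labels == brute_labels(column, strict=strict)
        # constant excludes singleton/dingleton by definition
        if "constant" in got.labels:
            assert got.labels == frozenset({"constant"})


def _matrix_from_rows(rows, gene_lengths=None):
    taxa = [f"t{i}" for i in range(len(rows))]
    n = len(rows[0])
    gene_lengths = gene_lengths or [n]
    groups, pos = [], 0
    for gi, length in enumerate(gene_lengths):
        seqs = {}
        for t, row in zip(taxa, rows):
            piece = row[pos : pos + length]
            if set(piece) - {"-"}:
                seqs[t] = piece
        groups.append(AlignedOrthologGroup(f"g{gi}", seqs))
        pos += length
    return concatenate(groups, taxa)


class TestPruneSingletonsDingletons:
    def test_identical_sequences_untouched(self):
        matrix = _matrix_from_rows(["ARNDC", "ARNDC", "ARNDC"])
        pruned = prune_singletons_dingletons(matrix)
        assert np.array_equal(pruned.columns, matrix.columns)

    def test_idempotent(self, rng):
        # skewed residue pool so a good share of columns survive pruning
        pool = list("AAAAAARRV-")
        rows = ["".join(rng.choice(pool, size=60)) for _ in range(6)]
        rows = [r if set(r) - {"-"} else "A" + r[1:] for r in rows]
        matrix = _matrix_from_rows(rows, gene_lengths=[25, 35])
        once = prune_singletons_dingletons(matrix)
        twice = prune_singletons_dingletons(once)
        assert np.array_equal(once.columns, twice.columns)
        assert once.partition_map == twice.partition_map

    def test_retained_columns_match_per_column_oracle(self, rng):
        rows = ["".join(rng.choice(list("AVLK-X"), size=40)) for _ in range(5)]
        rows = [r if set(r) - {"-", "X"} else "A" + r[1:] for r in rows]
        matrix = _matrix_from_rows(rows)
        pruned = prune_singletons_dingletons(matrix)
        keep = [
            j
            for j in range(matrix.total_length)
            if not (
                {"singleton", "dingleton"} & brute_labels(matrix.columns[:, j])
            )
        ]
        assert np.array_equal(pruned.columns, matrix.columns[:, keep])

    def test_never_removes_monomorphic_columns(self, rng):
        rows = ["".join(rng.choice(list("ARND-"), size=80)) for _ in range(7)]
        rows = [r if set(r) - {"-"} else "A" + r[1:] for r in rows]
        matrix = _matrix_from_rows(rows, gene_lengths=[40, 40])
        pruned = prune_singletons_dingletons(matrix)
        mono = 0
        for j in range(matrix.total_length):
            residues = {c for c in matrix.columns[:, j] if c != "-"}
            if len(residues) <= 1:
                mono += 1
        # all monomorphic columns survive
        kept_mono = 0
        for j in range(pruned.total_length):
            residues = {c for c in pruned.columns[:, j] if c != "-"}
            if len(residues) <= 1:
                kept_mono += 1
        assert kept_mono == mono

    def test_partition_intervals_stay_contiguous(self, rng):
        pool = list("AAAAAVVR")
        rows = ["".join(rng.choice(pool, size=50)) for _ in range(5)]
        matrix = _matrix_from_rows(rows, gene_lengths=[20, 10, 20])
        pruned = prune_singletons_dingletons(matrix)
        pos = 0
        for g in pruned.genes:
            start, end = pruned.partition_map[g]
            assert start == pos and end > start
            pos = end
        assert pos == pruned.total_length

    def test_gene_reduced_to_zero_columns_dropped(self, caplog):
        # gene g0: every column has a singleton; gene g1: constant
        matrix = _matrix_from_rows(
            ["AK" + "RR", "VK" + "RR", "AA" + "RR"], gene_lengths=[2, 2]
        )
        with caplog.at_level("WARNING"):
            pruned = prune_singletons_dingletons(matrix)
        assert pruned.genes == ["g1"]
        assert "g0" in caplog.text

    def test_classification_dump_covers_every_column(self):
        matrix = _matrix_from_rows(["ARND", "ARNE", "ARKD"])
        classes = classify_columns(matrix)
        assert [c.index for c in classes] == list(range(4))
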