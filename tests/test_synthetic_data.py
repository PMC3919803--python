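"""Simulator correctness: determinism, frequencies, missingness, fixtures."""

import json

import numpy as np
import pytest
from scipy.stats import binom

from synphy.io_formats import read_alignment_fasta
from synphy.models import AA_INDEX, load_empirical_model
from synphy.supermatrix import concatenate
from synphy.synthetic_data import (
    DEFAULT_PRESENCE,
    STUDY_TAXA,
    SimulationConfig,
    apply_missingness,
    candidate_topologies,
    generate_study_fixture,
    simulate_gene_alignment,
    study_grouping,
    study_tree,
)
from synphy.trees import read_newick


class TestStudyStructure:
    def test_five_groups_of_stated_sizes(self):
        sizes = sorted(
            len(v) for v in study_grouping().groups().values()
        )
        assert sizes == [1, 2, 2, 3, 11]
        assert len(STUDY_TAXA) == 19

    def test_tree_spans_the_taxon_set(self):
        tree = study_tree()
        assert set(tree.leaf_names()) == set(STUDY_TAXA)

    def test_candidate_topologies_differ_only_in_syndermata(self):
        cands = candidate_topologies()
        assert set(cands) == {"Pararotatoria", "Lemniscea", "Eurotatoria"}
        splits = {n: t.splits() for n, t in cands.items()}
        assert splits["Pararotatoria"] != splits["Lemniscea"]
        acan_seis = frozenset(
            {"Seison_nebaliae", "Pomphorhynchus_laevis",
             "Paratenuisentis_ambiguus", "Echinorhynchus_truttae"}
        )
        assert acan_seis in splits["Pararotatoria"]
        assert acan_seis not in splits["Lemniscea"]


class TestSimulateGene:
    def test_deterministic_given_seed_and_index(self):
        cfg = SimulationConfig(n_genes=2, seed=42)
        a = simulate_gene_alignment(cfg, 1)
        b = simulate_gene_alignment(cfg, 1)
        assert a.sequences == b.sequences
        c = simulate_gene_alignment(cfg, 0)
        assert c.sequences != a.sequences

    def test_zero_branch_lengths_copy_root(self):
        tree = study_tree()
        for br in tree.branches():
            br.length = 0.0
        cfg = SimulationConfig(tree=tree, n_genes=1, seed=3)
        gene = simulate_gene_alignment(cfg, 0)
        assert len(set(gene.sequences.values())) == 1

    def test_residue_frequencies_converge_to_pi(self):
        cfg = SimulationConfig(
            n_genes=1, mean_length=100_000, length_sigma=0.0,
            min_length=100_000, model_probs={"LG": 1.0}, seed=8,
        )
        gene = simulate_gene_alignment(cfg, 0)
        model = load_empirical_model("LG")
        counts = np.zeros(20)
        for seq in gene.sequences.values():
            for c in seq:
                counts[AA_INDEX[c]] += 1
        freqs = counts / counts.sum()
        assert 0.5 * np.abs(freqs - model.pi).sum() < 0.02


class TestMissingness:
    def test_probability_one_is_identity(self):
        cfg = SimulationConfig(n_genes=1, seed=5)
        gene = simulate_gene_alignment(cfg, 0)
        rng = np.random.default_rng(0)
        out = apply_missingness(gene, {t: 1.0 for t in gene.taxa}, rng)
        assert out.sequences == gene.sequences

    def test_low_coverage_taxon_within_binomial_band(self):
        cfg = SimulationConfig(n_genes=1, mean_length=60, seed=5)
        gene = simulate_gene_alignment(cfg, 0)
        rng = np.random.default_rng(77)
        hits = 0
        n = 400
        for _ in range(n):
            out = apply_missingness(gene, DEFAULT_PRESENCE, rng)
            hits += "Turbanella_ambronensis" in out.sequences
        lo, hi = binom.ppf([0.005, 0.995], n, 0.087)
        assert lo <= hits <= hi

    def test_zero_probability_taxon_absent(self):
        cfg = SimulationConfig(n_genes=1, mean_length=60, seed=5)
        gene = simulate_gene_alignment(cfg, 0)
        probs = {t: 1.0 for t in gene.taxa}
        probs["Adineta_vaga"] = 0.0
        rng = np.random.default_rng(7)
        for _ in range(20):
            assert "Adineta_vaga" not in apply_missingness(gene, probs, rng).sequences

    def test_at_least_two_taxa_forced(self):
        cfg = SimulationConfig(n_genes=1, mean_length=60, seed=5)
        gene = simulate_gene_alignment(cfg, 0)
        probs = {t: 0.01 for t in gene.taxa}
        rng = np.random.default_rng(3)
        for _ in range(50):
            assert len(apply_missingness(gene, probs, rng).taxa) >= 2


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    cfg = SimulationConfig(n_genes=24, mean_length=80, seed=13)
    manifest, truth = generate_study_fixture(cfg, out)
    return out, manifest, truth


class TestStudyFixture:
    def test_file_and_manifest_counts(self, fixture_dir):
        out, manifest, truth = fixture_dir
        assert len(manifest.rows) == 24
        assert len(list(out.glob("gene_*.fasta"))) == 24
        assert len(truth["genes"]) == 24

    def test_truth_presence_matches_concatenate(self, fixture_dir):
        out, manifest, truth = fixture_dir
        groups = [
            read_alignment_fasta(out / f"{r.gene_id}.fasta", gene_id=r.gene_id)
            for r in manifest.rows
        ]
        matrix = concatenate(groups, STUDY_TAXA)
        for gi, gene_id in enumerate(matrix.genes):
            present = {
                matrix.taxa[i] for i in range(19) if matrix.presence[i, gi]
            }
            assert present == set(truth["genes"][gene_id]["taxa"])

    def test_rp_flags_deterministic_count(self, tmp_path):
        cfg = SimulationConfig(
            n_genes=410, mean_length=61, min_length=60, seed=2,
            rp_fraction=51.0 / 410.0,
        )
        from synphy.synthetic_data import _rp_flags

        flags = _rp_flags(cfg)
        assert flags.sum() == 51

    def test_reproducible_from_seed(self, fixture_dir, tmp_path):
        out, manifest, truth = fixture_dir
        cfg = SimulationConfig(n_genes=24, mean_length=80, seed=13)
        _, truth2 = generate_study_fixture(cfg, tmp_path / "again")
        assert json.dumps(truth, sort_keys=True) == json.dumps(truth2, sort_keys=True)
        a = (out / "gene_0003.fasta").read_bytes()
        b = (tmp_path / "again" / "gene_0003.fasta").read_bytes()
        assert a == b

    def test_truth_tree_round_trips(self, fixture_dir):
        _, _, truth = fixture_dir
        tree = read_newick(truth["tree"])
        assert set(tree.leaf_names()) == set(STUDY_TAXA)
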