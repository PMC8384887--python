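"""Codon state space, Q matrices, likelihood engine and containers."""

import numpy as np
import pytest

from mitosel.selection import (
    CodonAlignment,
    LabeledTree,
    PruningEngine,
    build_q_matrix,
    clean_codon_columns,
    enumeration_log_likelihood,
    f3x4_frequencies,
    uniform_frequencies,
)
from mitosel.selection.code import (
    NUC_INDEX,
    codon_index,
    neighbor_arrays,
    sense_codons,
)
from mitosel.selection.qmatrix import SpectralQ, f3x4_from_position_frequencies
from mitosel.simulate import CodonSimSpec, simulate_codon_alignment


class TestCodeAndFrequencies:
    def test_vertebrate_mito_code_has_60_sense_codons(self):
        codons = sense_codons()
        assert len(codons) == 60
        assert {"TAA", "TAG", "AGA", "AGG"}.isdisjoint(codons)
        assert "ATA" in codons and "TGA" in codons

    def test_uniform_usage_gives_one_sixtieth_each(self):
        pi = f3x4_from_position_frequencies(np.full((3, 4), 0.25))
        assert np.allclose(pi, 1 / 60)

    def test_f3x4_sums_to_one_on_random_alignments(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACGT"), size=90)) for _ in range(4)]
        assert f3x4_frequencies(rows).sum() == pytest.approx(1.0)

    def test_f3x4_product_spot_checks(self):
        pos = np.array([
            [0.4, 0.3, 0.2, 0.1],
            [0.1, 0.2, 0.3, 0.4],
            [0.25, 0.25, 0.25, 0.25],
        ])
        pi = f3x4_from_position_frequencies(pos)
        idx = codon_index()
        raw = {}
        for codon in ("ATA", "CCC", "GTT"):
            raw[codon] = (pos[0, NUC_INDEX[codon[0]]]
                          * pos[1, NUC_INDEX[codon[1]]]
                          * pos[2, NUC_INDEX[codon[2]]])
        total = sum(
            pos[0, NUC_INDEX[c[0]]] * pos[1, NUC_INDEX[c[1]]] * pos[2, NUC_INDEX[c[2]]]
            for c in sense_codons()
        )
        for codon, value in raw.items():
            assert pi[idx[codon]] == pytest.approx(value / total, rel=1e-6)

    def test_impossible_position_class_rejected(self):
        pos = np.array([[1.0, 0, 0, 0], [0, 0, 0, 1.0], [0, 0, 1.0, 0]])
        # only codon ATG possible at each position -> fine; zero out all:
        bad = np.zeros((3, 4))
        with pytest.raises(ValueError):
            f3x4_from_position_frequencies(bad)


class TestQMatrix:
    def test_neutral_equal_rates_collapse_to_frequencies(self):
        pi = uniform_frequencies()
        q = build_q_matrix(1.0, 1.0, pi, scale=False)
        ii, jj, _, _ = neighbor_arrays()
        assert np.allclose(q[ii, jj], pi[jj])

    def test_synonymous_transition_rate(self):
        pi = uniform_frequencies()
        kappa = 3.5
        q = build_q_matrix(kappa, 0.2, pi, scale=False)
        idx = codon_index()
        # AAA (Lys) -> AAG (Lys): synonymous transition
        assert q[idx["AAA"], idx["AAG"]] == pytest.approx(kappa * pi[idx["AAG"]])
        # AAA (Lys) -> AAC (Asn): nonsynonymous transversion
        assert q[idx["AAA"], idx["AAC"]] == pytest.approx(0.2 * pi[idx["AAC"]])

    def test_rows_sum_to_zero_and_mean_rate_one(self):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(60))
        q = build_q_matrix(2.0, 0.4, pi)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert -(pi @ np.diag(q)) == pytest.approx(1.0)

    def test_detailed_balance(self):
        rng = np.random.default_rng(2)
        pi = rng.dirichlet(np.ones(60))
        q = build_q_matrix(2.0, 0.4, pi)
        flux = pi[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_spectral_exponential_matches_scipy_expm(self):
        from scipy.linalg import expm

        rng = np.random.default_rng(3)
        pi = rng.dirichlet(np.ones(60))
        q = build_q_matrix(2.0, 0.4, pi)
        p_spec = SpectralQ(q, pi).transition_matrices(np.array([0.07, 0.9]))
        for t, p in zip((0.07, 0.9), p_spec):
            assert np.allclose(p, expm(q * t), atol=1e-10)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)


def small_tree():
    return LabeledTree.from_newick("((A:0.1,B:0.25):0.07,(C:0.3,D:0.15):0.1);")


class TestPruning:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = LabeledTree.from_newick(
            "(A:{:.2f},B:{:.2f},(C:{:.2f},D:{:.2f}):{:.2f});".format(
                *rng.uniform(0.05, 0.5, size=5))
        )
        aln, _ = simulate_codon_alignment(
            CodonSimSpec(tree, int(rng.integers(1, 4)), kappa=2.0,
                         regime={"model": "M0", "omega": 0.5}, seed=seed)
        )
        pi = f3x4_frequencies(aln.rows)
        n_classes = int(rng.integers(1, 4))
        omega_values = rng.uniform(0.05, 3.0, size=n_classes)
        weights = rng.dirichlet(np.ones(n_classes))
        omega_idx = rng.integers(0, n_classes, size=(tree.n_nodes, n_classes))
        engine = PruningEngine(aln, tree, pi)
        lnl = engine.log_likelihood(2.0, omega_values, omega_idx, weights)
        ref = enumeration_log_likelihood(aln, tree, pi, 2.0, omega_values,
                                         omega_idx, weights)
        assert lnl == pytest.approx(ref, abs=1e-8)

    def test_saturated_branches_factorize_into_frequencies(self):
        # two taxa at t -> infinity: P(i,j) -> pi_j, lnL -> log(pi_a pi_b)
        tree = LabeledTree.from_newick("(A:400.0,B:400.0);")
        aln = CodonAlignment(["A", "B"], ["ATG", "CCT"])
        pi = uniform_frequencies()
        engine = PruningEngine(aln, tree, pi)
        lnl = engine.log_likelihood(
            2.0, np.array([0.5]), np.zeros((tree.n_nodes, 1), dtype=int),
            np.array([1.0]),
        )
        assert lnl == pytest.approx(2 * np.log(1 / 60), abs=1e-6)

    def test_rerooting_invariance(self):
        # the same unrooted tree written with two different rootings
        aln, _ = simulate_codon_alignment(
            CodonSimSpec(small_tree(), 40, regime={"model": "M0", "omega": 0.3},
                         seed=5)
        )
        pi = f3x4_frequencies(aln.rows)
        t1 = LabeledTree.from_newick("((A:0.1,B:0.25):0.07,(C:0.3,D:0.15):0.1);")
        t2 = LabeledTree.from_newick("(A:0.1,B:0.25,(C:0.3,D:0.15):0.17);")
        args = (np.array([0.3]), None, np.array([1.0]))
        lnls = []
        for tree in (t1, t2):
            engine = PruningEngine(aln, tree, pi)
            idx = np.zeros((tree.n_nodes, 1), dtype=int)
            lnls.append(engine.log_likelihood(2.0, args[0], idx, args[2]))
        assert lnls[0] == pytest.approx(lnls[1], abs=1e-9)

    def test_taxon_mismatch_rejected(self):
        aln = CodonAlignment(["A", "B", "X", "Y"], ["ATG"] * 4)
        with pytest.raises(ValueError, match="mismatch"):
            PruningEngine(aln, small_tree(), uniform_frequencies())


class TestAlignmentContainer:
    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment(["A"], ["ATGTAAATG"])

    def test_fasta_and_phylip_roundtrip(self, tmp_path):
        aln = CodonAlignment(["tax1", "tax2"], ["ATGGCT---", "ATGGCAGTT"])
        f = tmp_path / "a.fasta"
        p = tmp_path / "a.phy"
        aln.to_fasta(f)
        aln.to_phylip(p)
        assert CodonAlignment.from_fasta(f).rows == aln.rows
        assert CodonAlignment.from_phylip(p).rows == aln.rows

    def test_clean_codon_columns(self):
        aln = CodonAlignment(["A", "B"], ["ATG---GCT", "ATGCCTGCT"])
        cleaned, removed = clean_codon_columns(aln)
        assert removed == 1
        assert cleaned.rows == ["ATGGCT", "ATGGCT"] or cleaned.n_codons == 2

    def test_planted_gap_columns_all_removed(self):
        aln, _ = simulate_codon_alignment(
            CodonSimSpec(small_tree(), 100, regime={"model": "M0", "omega": 0.3},
                         seed=6)
        )
        rng = np.random.default_rng(0)
        gap_cols = sorted(rng.choice(100, size=7, replace=False))
        rows = []
        for k, row in enumerate(aln.rows):
            chars = list(row)
            target = gap_cols[k % 7]  # one gap somewhere in each chosen column
            for col in gap_cols:
                chars[3 * col : 3 * col + 3] = "---"
            rows.append("".join(chars))
        gapped = CodonAlignment(aln.taxa, rows)
        cleaned, removed = clean_codon_columns(gapped)
        assert removed == 7
        assert cleaned.n_codons == 93

    def test_empty_result_rejected(self):
        aln = CodonAlignment(["A", "B"], ["---", "ATG"])
        with pytest.raises(ValueError):
            clean_codon_columns(aln)


class TestLabeledTree:
    def test_hash_marks_label_single_branches(self):
        tree = LabeledTree.from_newick("((A#fg:0.1,B:0.2):0.1,C:0.3);")
        fg = tree.group_names.index("fg")
        assert tree.group[tree.taxa.index("A")] == fg
        assert (tree.group == fg).sum() == 1

    def test_dollar_marks_label_whole_clades(self):
        tree = LabeledTree.from_newick("((A:0.1,B:0.2)$v:0.1,(C:0.1,D:0.2):0.3);")
        v = tree.group_names.index("v")
        labeled = {tree.branch_name(n) for n in range(tree.n_nodes)
                   if tree.group[n] == v}
        assert {"A", "B"} <= labeled and len(labeled) == 3

    def test_label_clade_matches_dollar_syntax(self):
        t1 = LabeledTree.from_newick("((A:0.1,B:0.2)$v:0.1,(C:0.1,D:0.2):0.3);")
        t2 = LabeledTree.from_newick(
            "((A:0.1,B:0.2):0.1,(C:0.1,D:0.2):0.3);"
        ).label_clade(["A", "B"], "v")
        assert list(t1.group) == list(t2.group)

    def test_taxon_map_labels_terminals(self):
        tree = LabeledTree.from_newick("((A:0.1,B:0.2):0.1,C:0.3);")
        labeled = tree.label_taxa({"C": "big"})
        assert labeled.group[labeled.taxa.index("C")] == labeled.group_id("big")

    def test_newick_roundtrip_preserves_groups(self):
        tree = LabeledTree.from_newick("((A#x:0.1,B:0.2):0.1,C:0.3);")
        again = LabeledTree.from_newick(tree.to_newick())
        assert [again.group_names[g] for g in again.group] == [
            tree.group_names[g] for g in tree.group
        ]
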