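"""Model fitting, LRTs, NG86 counting and the mass~omega regression."""

import numpy as np
import pytest
from scipy import stats

from mitosel.selection import (
    CodonAlignment,
    LabeledTree,
    fit_model,
    lrt,
    mass_omega_correlation,
    nested_lrt,
    ng86_dnds,
)
from mitosel.selection.models import CodonModelFit
from mitosel.simulate import CodonSimSpec, simulate_codon_alignment
from mitosel.studies import two_clade_tree, unlabeled_tree


def _fake_fit(model, lnl, n_params):
    return CodonModelFit(
        model=model, lnl=lnl, kappa=2.0, params={}, n_free_params=n_params,
        converged=True, n_evaluations=0, n_starts=1, theta=np.zeros(n_params),
    )


class TestFitModel:
    def test_m0_parameter_recovery(self):
        tree = unlabeled_tree(8)
        aln, _ = simulate_codon_alignment(
            CodonSimSpec(tree, 500, kappa=2.0,
                         regime={"model": "M0", "omega": 0.2}, seed=11)
        )
        fit = fit_model(aln, tree, "M0", n_starts=1)
        assert fit.params["omega"] == pytest.approx(0.2, abs=0.05)
        assert fit.kappa == pytest.approx(2.0, abs=0.4)
        assert fit.converged

    def test_nested_lnl_ordering(self, two_clade_tree):
        tree = two_clade_tree
        aln, _ = simulate_codon_alignment(
            CodonSimSpec(tree, 200, kappa=2.0,
                         regime={"model": "M0", "omega": 0.3}, seed=12)
        )
        m0 = fit_model(aln, tree, "M0", n_starts=1)
        branch = fit_model(aln, tree, "branch", n_starts=1, start=None)
        free = fit_model(aln, tree, "free_ratios", n_starts=1)
        assert m0.lnl <= branch.lnl + 1e-4
        assert branch.lnl <= free.lnl + 1e-4
        m2a = fit_model(aln, tree, "M2a_rel", n_starts=1)
        cmc = fit_model(aln, tree, "CmC", n_starts=1, start=m2a)
        assert m2a.lnl <= cmc.lnl + 1e-4

    def test_branch_model_requires_labels(self):
        tree = unlabeled_tree(4)
        aln, _ = simulate_codon_alignment(
            CodonSimSpec(tree, 30, regime={"model": "M0", "omega": 0.3}, seed=1)
        )
        with pytest.raises(ValueError, match="label"):
            fit_model(aln, tree, "branch")

    def test_unknown_model_rejected(self, two_clade_tree):
        aln, _ = simulate_codon_alignment(
            CodonSimSpec(two_clade_tree, 30,
                         regime={"model": "M0", "omega": 0.3}, seed=1)
        )
        with pytest.raises(ValueError, match="unknown model"):
            fit_model(aln, two_clade_tree, "M8")

    @pytest.mark.parametrize("seed", [21, 22])
    def test_branch_site_detects_planted_foreground_selection(self, seed):
        # foreground clade labeled with codeml-style '$'
        base = LabeledTree.from_newick(
            "((a0:0.25,a1:0.25):0.12,(b0:0.25,b1:0.25)$1:0.12);"
        )
        aln, _ = simulate_codon_alignment(
            CodonSimSpec(base, 900, kappa=2.0,
                         regime={"model": "BSM_A", "p0": 0.3, "p1": 0.3,
                                 "omega0": 0.05, "omega2": 8.0},
                         seed=seed)
        )
        null, alt, res = nested_lrt(aln, base, "BSM_A_null", "BSM_A", seed=3)
        assert res.df == 1
        assert res.p_value < 0.05
        assert alt.params["omega2"] > 1.5


class TestLRT:
    def test_identical_fits_give_zero_statistic(self):
        res = lrt(_fake_fit("M2a_rel", -100.0, 5), _fake_fit("CmC", -100.0, 6))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi2_quantile(self):
        res = lrt(_fake_fit("M2a_rel", -101.92, 5), _fake_fit("CmC", -100.0, 6))
        assert res.statistic == pytest.approx(3.84)
        assert res.p_value == pytest.approx(0.05, abs=0.001)

    def test_negative_statistic_beyond_tolerance_raises(self):
        with pytest.raises(RuntimeError, match="optimizer"):
            lrt(_fake_fit("M2a_rel", -99.0, 5), _fake_fit("CmC", -100.0, 6))

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            lrt(_fake_fit("CmC", -100.0, 6), _fake_fit("M2a_rel", -99.0, 6))


class TestNG86:
    def test_identical_sequences_undefined_omega(self):
        res = ng86_dnds("ATGGCTCTA", "ATGGCTCTA")
        assert res.dn == 0 and res.ds == 0 and res.omega is None

    def test_single_synonymous_difference(self):
        res = ng86_dnds("CTACTA", "CTACTG")  # Leu -> Leu, third position
        assert res.dn == 0.0
        assert res.ds > 0.0

    def test_single_nonsynonymous_difference(self):
        res = ng86_dnds("ATGGCT", "ATGTCT")  # Ala -> Ser
        assert res.ds == 0.0 and res.dn > 0.0

    def test_hand_worked_site_counts(self):
        # TTT (Phe, mito code): third position T->C synonymous only
        res = ng86_dnds("TTT", "TTT")
        assert res.syn_sites == pytest.approx(1 / 3)
        assert res.nonsyn_sites == pytest.approx(3 - 1 / 3)

    def test_two_position_pathway_averaging(self):
        # CTA (Leu) vs CCG (Pro): paths through CCA (Pro) and CTG (Leu)
        # path1: CTA->CCA (nonsyn) ->CCG (syn); path2: CTA->CTG (syn) ->CCG (nonsyn)
        # padded with identical codons to keep proportions in the JC domain
        pad = "ATGGGT" * 4
        res = ng86_dnds(pad + "CTA", pad + "CCG")
        assert res.syn_diffs == pytest.approx(1.0)
        assert res.nonsyn_diffs == pytest.approx(1.0)

    def test_counting_tracks_ml_estimates(self):
        # pairwise simulations under M0: NG86 omega near truth and
        # rank-correlated with the ML estimates
        tree = LabeledTree.from_newick("(A:0.3,B:0.3);")
        ml, ng = [], []
        for seed in range(15):
            omega = 0.1 + 0.05 * seed
            aln, _ = simulate_codon_alignment(
                CodonSimSpec(tree, 400, kappa=2.0,
                             regime={"model": "M0", "omega": omega}, seed=seed)
            )
            fit = fit_model(aln, tree, "M0", n_starts=1)
            res = ng86_dnds(aln.rows[0], aln.rows[1])
            ml.append(fit.params["omega"])
            ng.append(res.omega)
        rho = stats.spearmanr(ml, ng).statistic
        assert rho > 0.8

    def test_mean_ng86_omega_near_truth(self):
        tree = LabeledTree.from_newick("(A:0.4,B:0.4);")
        omegas = []
        for seed in range(20):
            aln, _ = simulate_codon_alignment(
                CodonSimSpec(tree, 300, kappa=2.0,
                             regime={"model": "M0", "omega": 0.3}, seed=100 + seed)
            )
            omegas.append(ng86_dnds(aln.rows[0], aln.rows[1]).omega)
        assert 0.2 <= float(np.mean(omegas)) <= 0.4


class TestMassOmegaRegression:
    def test_perfect_linear_relation(self):
        mass = [5, 7, 9, 11, 14]
        omega = [0.01 * m for m in mass]
        r, p = mass_omega_correlation(mass, omega)
        assert r == pytest.approx(1.0)
        assert p < 0.01

    def test_constant_omega_rejected(self):
        with pytest.raises(ValueError):
            mass_omega_correlation([5, 7, 9], [0.1, 0.1, 0.1])

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            mass_omega_correlation([5, 7], [0.1, 0.2])

    def test_p_values_calibrated_under_independence(self):
        rng = np.random.default_rng(0)
        pvals = np.array([
            mass_omega_correlation(rng.normal(size=7), rng.normal(size=7))[1]
            for _ in range(600)
        ])
        # calibrated two-sided p-values: nominal rejection rates at several
        # alphas (binomial tolerance), a sharper check than an omnibus KS
        assert 0.02 <= np.mean(pvals < 0.05) <= 0.08
        assert 0.05 <= np.mean(pvals < 0.10) <= 0.15
        assert 0.42 <= np.mean(pvals < 0.50) <= 0.58

    def test_spearman_option(self):
        r, p = mass_omega_correlation([1, 2, 3, 4], [2, 4, 8, 16], method="spearman")
        assert r == pytest.approx(1.0)


class TestCmCRecovery:
    def test_clade_omegas_recovered_on_long_genes(self):
        """CmC point estimates track the planted clade-specific omegas.

        The divergent-class omega trades off against its proportion, and a
        clade omega2 approaching 1 is partially confounded with the neutral
        class on that clade, so the clade whose omega2 lies nearer 1 carries
        visibly more estimation variance — tolerances reflect that.
        """
        tree = two_clade_tree(tips_per_clade=6)
        errors = {"background": [], "target": []}
        for seed in range(5):
            aln, _ = simulate_codon_alignment(
                CodonSimSpec(tree, 800, kappa=2.0,
                             regime={"model": "CmC", "p0": 0.5, "p1": 0.2,
                                     "omega0": 0.05,
                                     "omega2_by_group": {"background": 0.2,
                                                         "target": 0.7}},
                             seed=300 + seed)
            )
            fit = fit_model(aln, tree, "CmC", n_starts=2, seed=seed)
            est = fit.params["omega2_by_group"]
            errors["background"].append(abs(est["background"] - 0.2))
            errors["target"].append(abs(est["target"] - 0.7))
        assert np.median(errors["background"]) <= 0.15
        assert np.median(errors["target"]) <= 0.30
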