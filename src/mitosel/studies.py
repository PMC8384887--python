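"""Reproducible simulation studies of the codon-model machinery.

These functions define the package's standard benchmark conditions — an
eight-taxon two-clade tree with moderate mitochondrial-scale divergence,
and mixture parameters dominated by strong purifying selection — and run
the corresponding simulation studies end to end: likelihood-oracle
agreement, M0 parameter recovery, type-I-error calibration of the clade
model C test, and its power to detect the relaxation regime (background
omega2 = 0.3 versus target omega2 = 1.0).  Both the test suite and the
acceptance script call these entry points.
"""

from __future__ import annotations

import numpy as np

from .selection import (
    LabeledTree,
    PruningEngine,
    enumeration_log_likelihood,
    f3x4_frequencies,
    fit_model,
    nested_lrt,
)
from .simulate import CodonSimSpec, simulate_codon_alignment

#: site-class mixture shared by the calibration and power studies:
#: half the sites under strong purifying selection, a fifth neutral,
#: and a divergent class carrying the clade signal
MIXTURE = {"p0": 0.5, "p1": 0.2, "omega0": 0.05}

DEFAULT_KAPPA = 2.0


def two_clade_tree(
    tips_per_clade: int = 4,
    tip_length: float = 0.2,
    inner_length: float = 0.1,
    target: str = "target",
) -> LabeledTree:
    """Balanced two-clade tree; the second clade is the labeled target."""

    def clade(names):
        s = f"({names[0]}:{tip_length},{names[1]}:{tip_length})"
        for nm in names[2:]:
            s = f"({s}:{inner_length},{nm}:{tip_length})"
        return s

    a = clade([f"a{i}" for i in range(tips_per_clade)])
    b = clade([f"b{i}" for i in range(tips_per_clade)])
    newick = f"({a}:{inner_length},{b}${target}:{inner_length});"
    return LabeledTree.from_newick(newick)


def unlabeled_tree(n_taxa: int = 8, tip_length: float = 0.15,
                   inner_length: float = 0.08) -> LabeledTree:
    names = [f"t{i}" for i in range(n_taxa)]
    half = n_taxa // 2

    def clade(block):
        s = f"({block[0]}:{tip_length},{block[1]}:{tip_length})"
        for nm in block[2:]:
            s = f"({s}:{inner_length},{nm}:{tip_length})"
        return s

    return LabeledTree.from_newick(
        f"({clade(names[:half])}:{inner_length},{clade(names[half:])}:{inner_length});"
    )


def _seed_stream(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# studies
# ---------------------------------------------------------------------------
def pruning_oracle_study(n_instances: int = 200, seed: int = 0) -> dict:
    """Pruning vs brute-force enumeration on tiny random instances.

    Random trees of 3-4 taxa, 1-3 codons, random mixture parameters;
    reports the largest absolute log-likelihood discrepancy.
    """
    rng = np.random.default_rng(seed)
    diffs = []
    for _ in range(n_instances):
        n_taxa = int(rng.integers(3, 5))
        names = [f"x{i}" for i in range(n_taxa)]
        bl = rng.uniform(0.02, 0.6, size=2 * n_taxa)
        # trifurcating roots keep the enumeration oracle at <= 2 internal nodes
        if n_taxa == 3:
            nwk = (f"({names[0]}:{bl[0]:.3f},{names[1]}:{bl[1]:.3f},"
                   f"{names[2]}:{bl[2]:.3f});")
        else:
            nwk = (f"({names[0]}:{bl[0]:.3f},{names[1]}:{bl[1]:.3f},"
                   f"({names[2]}:{bl[2]:.3f},{names[3]}:{bl[3]:.3f}):{bl[4]:.3f});")
        tree = LabeledTree.from_newick(nwk)
        n_codons = int(rng.integers(1, 4))
        omega_true = float(rng.uniform(0.05, 2.0))
        kappa = float(rng.uniform(0.5, 8.0))
        aln, _ = simulate_codon_alignment(
            CodonSimSpec(tree, n_codons, kappa=kappa,
                         regime={"model": "M0", "omega": omega_true},
                         seed=int(rng.integers(2**31 - 1)))
        )
        pi = f3x4_frequencies(aln.rows)
        n_classes = int(rng.integers(1, 4))
        omega_values = rng.uniform(0.05, 3.0, size=n_classes)
        weights = rng.dirichlet(np.ones(n_classes))
        omega_idx = rng.integers(0, n_classes, size=(tree.n_nodes, n_classes))
        engine = PruningEngine(aln, tree, pi)
        lnl = engine.log_likelihood(kappa, omega_values, omega_idx, weights)
        ref = enumeration_log_likelihood(
            aln, tree, pi, kappa, omega_values, omega_idx, weights
        )
        diffs.append(abs(lnl - ref))
    return {"n": n_instances, "max_abs_diff": float(max(diffs))}


def m0_recovery_study(
    n_replicates: int = 20,
    n_codons: int = 500,
    omega: float = 0.2,
    kappa: float = DEFAULT_KAPPA,
    seed: int = 0,
) -> dict:
    """Simulate under M0 and refit; reports per-replicate estimates."""
    tree = unlabeled_tree(8)
    omega_hat, kappa_hat = [], []
    for s in _seed_stream(seed, n_replicates):
        aln, _ = simulate_codon_alignment(
            CodonSimSpec(tree, n_codons, kappa=kappa,
                         regime={"model": "M0", "omega": omega}, seed=s)
        )
        fit = fit_model(aln, tree, "M0", n_starts=1, seed=s)
        omega_hat.append(fit.params["omega"])
        kappa_hat.append(fit.kappa)
    omega_err = np.abs(np.array(omega_hat) - omega)
    return {
        "n": n_replicates,
        "omega_true": omega,
        "kappa_true": kappa,
        "omega_hat": omega_hat,
        "kappa_hat": kappa_hat,
        "median_omega_error": float(np.median(omega_err)),
        "median_kappa_error": float(np.median(np.abs(np.array(kappa_hat) - kappa))),
    }


def cmc_calibration_study(
    n_genes: int = 200,
    n_codons: int = 300,
    omega2: float = 0.3,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the CmC vs M2a_rel LRT on null-simulated genes.

    Uses the 12-taxon study tree; replicate genes warm-start from the
    previous replicate's null solution (with the local-optimum guard of
    :func:`nested_lrt`), which roughly halves runtime without touching
    the statistics.
    """
    tree = two_clade_tree(tips_per_clade=6)
    regime = {"model": "M2a_rel", **MIXTURE, "omega2": omega2}
    p_values = []
    prev_null = prev_alt = None
    for s in _seed_stream(seed, n_genes):
        aln, _ = simulate_codon_alignment(
            CodonSimSpec(tree, n_codons, kappa=DEFAULT_KAPPA, regime=regime, seed=s)
        )
        null, alt, res = nested_lrt(
            aln, tree, "M2a_rel", "CmC", seed=s,
            null_start=prev_null, alt_start=prev_alt,
        )
        prev_null, prev_alt = null.theta, alt.theta
        p_values.append(res.p_value)
    p = np.array(p_values)
    return {
        "n": n_genes,
        "alpha": alpha,
        "p_values": p_values,
        "type_one_error": float(np.mean(p < alpha)),
    }


def cmc_power_study(
    n_replicates: int = 50,
    n_codons: int = 800,
    omega2_background: float = 0.3,
    omega2_target: float = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Power of the CmC test under the relaxation regime (target omega2 -> 1)."""
    tree = two_clade_tree()
    regime = {
        "model": "CmC",
        **MIXTURE,
        "omega2_by_group": {
            "background": omega2_background,
            "target": omega2_target,
        },
    }
    p_values = []
    prev_null = prev_alt = None
    for s in _seed_stream(seed, n_replicates):
        aln, _ = simulate_codon_alignment(
            CodonSimSpec(tree, n_codons, kappa=DEFAULT_KAPPA, regime=regime, seed=s)
        )
        null, alt, res = nested_lrt(
            aln, tree, "M2a_rel", "CmC", seed=s,
            null_start=prev_null, alt_start=prev_alt,
        )
        prev_null, prev_alt = null.theta, alt.theta
        p_values.append(res.p_value)
    p = np.array(p_values)
    return {
        "n": n_replicates,
        "alpha": alpha,
        "p_values": p_values,
        "rejection_rate": float(np.mean(p < alpha)),
    }
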