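"""Simulation of codon alignments under GY94-style omega regimes.

Sequences evolve on a labeled tree by drawing the root state from the
equilibrium frequencies and sampling each child state from exp(Q t) along
its branch; stop codons are never emitted because the generator matrix
has zero rate into them.  Site classes (for mixture regimes) are drawn
per site and recorded in the truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..selection.code import sense_codons
from ..selection.alignment import CodonAlignment
from ..selection.models import _ModelSpec, _logit
from ..selection.qmatrix import (
    SpectralQ,
    build_q_matrix,
    f3x4_from_position_frequencies,
    uniform_frequencies,
)
from ..selection.trees import LabeledTree

#: base usage resembling an avian mitogenome H strand (A, C, G, T)
MITO_BASE_FREQS = (0.31, 0.32, 0.13, 0.24)


@dataclass
class CodonSimSpec:
    """Parameters of one simulated codon alignment.

    ``regime`` names one of the implemented models and its true
    parameters, e.g. ``{"model": "M0", "omega": 0.2}`` or
    ``{"model": "CmC", "p0": .5, "p1": .3, "omega0": .1,
    "omega2_by_group": {"background": .3, "target": 1.0}}``.
    """

    tree: LabeledTree
    n_codons: int
    kappa: float = 2.0
    regime: dict = field(default_factory=lambda: {"model": "M0", "omega": 0.2})
    pi: str | np.ndarray = "mito"  # "mito", "uniform", a 3x4 table or a pi vector
    seed: int = 0
    table_id: int = 2


def _resolve_pi(spec: CodonSimSpec) -> np.ndarray:
    if isinstance(spec.pi, str):
        if spec.pi == "uniform":
            return uniform_frequencies(spec.table_id)
        if spec.pi == "mito":
            pos = np.tile(MITO_BASE_FREQS, (3, 1))
            return f3x4_from_position_frequencies(pos, spec.table_id)
        raise ValueError(f"unknown pi preset {spec.pi!r}")
    arr = np.asarray(spec.pi, dtype=float)
    if arr.shape == (3, 4):
        return f3x4_from_position_frequencies(arr, spec.table_id)
    return arr / arr.sum()


def _theta_from_regime(spec_model: _ModelSpec, regime: dict, kappa: float):
    """Transformed parameter vector reproducing the regime exactly."""
    m = regime["model"]
    theta = [np.log(kappa)]
    log = lambda x: np.log(x) if x > 0 else -np.inf  # omega = 0 is simulable
    if m == "M0":
        theta.append(log(regime["omega"]))
    elif m in ("branch", "free_ratios"):
        by_group = regime["omega_by_group"]
        for g in spec_model.tree.group_names:
            theta.append(np.log(by_group[g]))
    else:
        p0, p1 = regime["p0"], regime["p1"]
        theta += [_logit(p0), _logit(p1 / (1 - p0))]
        theta.append(np.log(regime["omega0"]))
        if m == "M2a_rel":
            theta.append(np.log(regime["omega2"]))
        elif m == "CmC":
            for g in spec_model.tree.group_names:
                theta.append(np.log(regime["omega2_by_group"][g]))
        elif m == "BSM_A":
            theta.append(np.log(regime["omega2"]))
        elif m != "BSM_A_null":
            raise ValueError(f"unknown regime model {m!r}")
    return np.array(theta)


def simulate_codon_alignment(spec: CodonSimSpec) -> tuple[CodonAlignment, dict]:
    """Evolve an alignment under the regime; returns (alignment, truth)."""
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    pi = _resolve_pi(spec)
    model = spec.regime["model"]
    layout_spec = _ModelSpec(model, tree)
    theta = _theta_from_regime(layout_spec, spec.regime, spec.kappa)
    kappa, omega_values, omega_idx, weights = layout_spec.layout(theta)
    tree = layout_spec.tree  # free_ratios relabels branches

    n = spec.n_codons
    n_classes = len(weights)
    classes = rng.choice(n_classes, size=n, p=weights)

    # transition matrices per (distinct omega, branch)
    p_stack = []
    for omega in omega_values:
        q = build_q_matrix(kappa, omega, pi, spec.table_id)
        p_stack.append(SpectralQ(q, pi).transition_matrices(tree.blen))
    p_stack = np.stack(p_stack)

    states = np.empty((tree.n_nodes, n), dtype=np.int64)
    root = tree.root
    states[root] = rng.choice(len(pi), size=n, p=pi)
    order = []
    stack = [root]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(tree.children[node])
    for node in order:
        if node == root:
            continue
        pmat = p_stack[omega_idx[node], node]  # (n_classes, ns, ns)
        probs = pmat[classes, states[tree.parent[node]]]
        probs = probs / probs.sum(axis=1, keepdims=True)
        u = rng.random(n)
        states[node] = (u[:, None] < probs.cumsum(axis=1)).argmax(axis=1)

    codons = sense_codons(spec.table_id)
    rows = [
        "".join(codons[s] for s in states[i]) for i in range(tree.n_tips)
    ]
    aln = CodonAlignment(list(tree.taxa), rows, spec.table_id)
    truth = {
        "model": model,
        "regime": spec.regime,
        "kappa": spec.kappa,
        "n_codons": n,
        "seed": spec.seed,
        "site_classes": classes.tolist(),
        "class_weights": weights.tolist(),
        "omega_values": np.asarray(omega_values).tolist(),
        "group_names": list(tree.group_names),
    }
    return aln, truth
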