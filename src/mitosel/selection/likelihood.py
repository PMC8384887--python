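"""Felsenstein pruning over codon states with site-class mixtures.

The engine caches the pattern-compressed alignment and tree arrays; each
call evaluates the log-likelihood for one parameter point.  Site-class
mixture models are expressed as a matrix ``omega_idx[node, class]``
indexing into a vector of distinct omega values, so clade, branch and
branch-site structures all share the same code path.
"""

from __future__ import annotations

import numpy as np

from .alignment import CodonAlignment, encode_alignment
from .qmatrix import PI_FLOOR, SpectralQ, build_q_matrix
from .trees import LabeledTree


class PruningEngine:
    def __init__(self, aln: CodonAlignment, tree: LabeledTree, pi: np.ndarray):
        missing = [t for t in tree.taxa if t not in aln.taxa]
        extra = [t for t in aln.taxa if t not in tree.taxa]
        if missing or extra:
            raise ValueError(
                f"taxon mismatch between alignment and tree: "
                f"missing from alignment {missing}; not in tree {extra}"
            )
        self.tree = tree
        pi = np.asarray(pi, dtype=float)
        if np.any(pi < PI_FLOOR):
            pi = np.maximum(pi, PI_FLOOR)
            pi = pi / pi.sum()
        self.pi = pi
        self.table_id = aln.table_id
        self.n_states = len(self.pi)

        states = encode_alignment(aln)
        # reorder rows to the tree's tip order
        order = [aln.taxa.index(t) for t in tree.taxa]
        states = states[order]
        cols, inverse, counts = np.unique(
            states.T, axis=0, return_inverse=True, return_counts=True
        )
        self.tip_patterns = cols.T  # (n_tips, n_patterns)
        self.pattern_counts = counts.astype(float)
        self.pattern_of_site = inverse
        self.n_patterns = self.tip_patterns.shape[1]
        self.n_sites = states.shape[1]
        self._tip_clean = [bool((self.tip_patterns[i] >= 0).all())
                           for i in range(tree.n_tips)]
        # branch lengths are fixed, so P(t) depends only on (kappa, omega);
        # finite-difference gradients then reuse most matrices
        self._p_cache: dict[tuple[float, float], np.ndarray] = {}

    def _transition_matrices(self, kappa: float, omega: float) -> np.ndarray:
        key = (float(kappa), float(omega))
        p = self._p_cache.get(key)
        if p is None:
            if len(self._p_cache) > 128:
                self._p_cache.clear()
            q = build_q_matrix(kappa, omega, self.pi, self.table_id)
            p = SpectralQ(q, self.pi).transition_matrices(self.tree.blen)
            self._p_cache[key] = p
        return p

    # ------------------------------------------------------------------
    def log_likelihood(
        self,
        kappa: float,
        omega_values: np.ndarray,
        omega_idx: np.ndarray,
        class_weights: np.ndarray,
        site_loglik: bool = False,
    ):
        """Mixture log-likelihood.

        omega_values: (n_omega,) distinct dN/dS values
        omega_idx:    (n_nodes, n_classes) index into omega_values for the
                      branch above each node (root row ignored)
        class_weights:(n_classes,) mixture proportions, summing to 1
        """
        tree = self.tree
        n_nodes = tree.n_nodes
        n_classes = omega_idx.shape[1]
        npat = self.n_patterns
        ns = self.n_states

        # transition matrices per distinct omega (cached across calls)
        p_by_omega = [
            self._transition_matrices(kappa, omega) for omega in omega_values
        ]

        logscale = np.zeros(npat)
        partials: dict[int, np.ndarray] = {}
        contrib = np.empty((n_classes, ns, npat))
        for node in tree.postorder_internal:
            part = np.ones((n_classes, ns, npat))
            for child in tree.children[node]:
                if child < tree.n_tips:
                    s = self.tip_patterns[child]
                    if self._tip_clean[child]:
                        for c in range(n_classes):
                            contrib[c] = p_by_omega[omega_idx[child, c]][child][:, s]
                    else:
                        safe = np.where(s >= 0, s, 0)
                        for c in range(n_classes):
                            np.copyto(
                                contrib[c],
                                np.where(
                                    s[None, :] >= 0,
                                    p_by_omega[omega_idx[child, c]][child][:, safe],
                                    1.0,
                                ),
                            )
                else:
                    cpart = partials.pop(child)
                    for c in range(n_classes):
                        np.matmul(
                            p_by_omega[omega_idx[child, c]][child],
                            cpart[c],
                            out=contrib[c],
                        )
                part *= contrib
            m = part.max(axis=(0, 1))
            if not np.all(m > 0):
                return -np.inf
            part /= m
            logscale += np.log(m)
            partials[node] = part

        root_part = partials[tree.root]  # (n_classes, ns, npat)
        class_lik = np.einsum("j,cjp->cp", self.pi, root_part)
        site_lik = np.asarray(class_weights) @ class_lik
        if np.any(site_lik <= 0):
            return -np.inf
        per_pattern = np.log(site_lik) + logscale
        lnl = float(self.pattern_counts @ per_pattern)
        if site_loglik:
            return lnl, per_pattern[self.pattern_of_site]
        return lnl


def enumeration_log_likelihood(
    aln: CodonAlignment,
    tree: LabeledTree,
    pi: np.ndarray,
    kappa: float,
    omega_values,
    omega_idx,
    class_weights,
) -> float:
    """Brute-force likelihood by summing over all internal-state assignments.

    Independent oracle for the pruning engine; usable only for tiny trees
    and alignments (cost grows as n_states**n_internal per site).
    """
    from itertools import product

    from scipy.linalg import expm

    states = encode_alignment(aln)
    order = [aln.taxa.index(t) for t in tree.taxa]
    states = states[order]
    n_sites = states.shape[1]
    n_nodes = tree.n_nodes
    internals = [n for n in range(n_nodes) if tree.children[n]]
    root = tree.root
    ns = len(pi)

    pmats = {}
    for node in range(n_nodes):
        if node == root:
            continue
        row = {}
        for c in range(len(class_weights)):
            omega = omega_values[omega_idx[node, c]]
            q = build_q_matrix(kappa, omega, pi, aln.table_id)
            row[c] = expm(q * tree.blen[node])
        pmats[node] = row

    total = 0.0
    for site in range(n_sites):
        site_like = 0.0
        for c, weight in enumerate(class_weights):
            like_c = 0.0
            for assignment in product(range(ns), repeat=len(internals)):
                st = {n: a for n, a in zip(internals, assignment)}
                for tip in range(tree.n_tips):
                    st[tip] = states[tip, site]
                prob = pi[st[root]]
                for node in range(n_nodes):
                    if node == root:
                        continue
                    child_state = st[node]
                    parent_state = st[tree.parent[node]]
                    if child_state < 0:  # ambiguous tip: marginalize
                        prob *= 1.0
                    else:
                        prob *= pmats[node][c][parent_state, child_state]
                like_c += prob
            site_like += weight * like_c
        total += np.log(site_like)
    return float(total)
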