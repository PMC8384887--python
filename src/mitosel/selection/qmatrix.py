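"""GY94-style codon rate matrices with F3x4 equilibrium frequencies.

The instantaneous rate from codon i to codon j (single-nucleotide
exchanges only) is

    q_ij = pi_j                synonymous transversion
         = kappa * pi_j        synonymous transition
         = omega * pi_j        nonsynonymous transversion
         = omega*kappa*pi_j    nonsynonymous transition

and zero for multi-nucleotide exchanges or exchanges into stop codons.
Each matrix is scaled so the expected number of substitutions per codon
site per unit branch length equals one.
"""

from __future__ import annotations

import numpy as np

from .code import (
    NUC_INDEX,
    VERTEBRATE_MITO_TABLE_ID,
    neighbor_arrays,
    sense_codons,
)

#: smallest admissible equilibrium frequency for a sense codon
PI_FLOOR = 1e-8


def f3x4_frequencies(
    codon_rows, table_id: int = VERTEBRATE_MITO_TABLE_ID
) -> np.ndarray:
    """Codon equilibrium frequencies from position-specific base usage.

    ``codon_rows`` is an iterable of in-frame nucleotide strings (gaps and
    Ns are ignored in the counts).  The frequency of codon n1n2n3 is the
    product of the position-specific frequencies of n1, n2 and n3, with
    stop codons assigned zero and the sense set renormalized.
    """
    counts = np.zeros((3, 4))
    for row in codon_rows:
        s = row.upper()
        for k, ch in enumerate(s):
            j = NUC_INDEX.get(ch)
            if j is not None:
                counts[k % 3, j] += 1
    if counts.sum() == 0:
        raise ValueError("no countable nucleotides in alignment")
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    return f3x4_from_position_frequencies(pos_freq, table_id)


def f3x4_from_position_frequencies(
    pos_freq: np.ndarray, table_id: int = VERTEBRATE_MITO_TABLE_ID
) -> np.ndarray:
    """Assemble sense-codon frequencies from a 3x4 base-frequency table."""
    pos_freq = np.asarray(pos_freq, dtype=float)
    if pos_freq.shape != (3, 4):
        raise ValueError("position frequencies must be a 3x4 array")
    codons = sense_codons(table_id)
    pi = np.array(
        [
            pos_freq[0, NUC_INDEX[c[0]]]
            * pos_freq[1, NUC_INDEX[c[1]]]
            * pos_freq[2, NUC_INDEX[c[2]]]
            for c in codons
        ]
    )
    total = pi.sum()
    if total <= 0:
        raise ValueError(
            "position-specific frequencies leave no sense codon possible"
        )
    # floor unobserved codons so the reversible decomposition stays defined
    pi = np.maximum(pi / total, PI_FLOOR)
    return pi / pi.sum()


def uniform_frequencies(table_id: int = VERTEBRATE_MITO_TABLE_ID) -> np.ndarray:
    n = len(sense_codons(table_id))
    return np.full(n, 1.0 / n)


def build_q_matrix(
    kappa: float,
    omega: float,
    pi: np.ndarray,
    table_id: int = VERTEBRATE_MITO_TABLE_ID,
    scale: bool = True,
) -> np.ndarray:
    """Scaled GY94 rate matrix for one (kappa, omega) pair."""
    ii, jj, ts, syn = neighbor_arrays(table_id)
    n = len(pi)
    rates = pi[jj].copy()
    rates[ts] *= kappa
    rates[~syn] *= omega
    q = np.zeros((n, n))
    q[ii, jj] = rates
    q[np.diag_indices(n)] = -q.sum(axis=1)
    if scale:
        mean_rate = -float(pi @ np.diag(q))
        if mean_rate <= 0:
            raise ValueError("degenerate rate matrix (zero mean rate)")
        q /= mean_rate
    return q


class SpectralQ:
    """Eigendecomposition of a reversible Q for fast exp(Q t).

    Uses the symmetrized form B = D Q D^-1 with D = diag(sqrt(pi)); B is
    symmetric, so P(t) = D^-1 U exp(L t) U' D with an orthogonal U.  Falls
    back to scipy's scaling-and-squaring expm if the decomposition fails.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        self.q = q
        self.pi = pi
        sqrt_pi = np.sqrt(pi)
        self._fallback = False
        b = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        b = 0.5 * (b + b.T)
        try:
            lam, u = np.linalg.eigh(b)
            self.lam = lam
            self.left = u / sqrt_pi[:, None]
            self.right = u.T * sqrt_pi[None, :]
        except np.linalg.LinAlgError:  # pragma: no cover - numerical safety
            self._fallback = True

    def transition_matrices(self, t: np.ndarray) -> np.ndarray:
        """P(t) for a vector of branch lengths; shape (len(t), n, n)."""
        t = np.asarray(t, dtype=float)
        if self._fallback:  # pragma: no cover - numerical safety
            from scipy.linalg import expm

            return np.stack([expm(self.q * ti) for ti in t])
        e = np.exp(t[:, None] * self.lam[None, :])
        p = (self.left[None, :, :] * e[:, None, :]) @ self.right
        np.clip(p, 0.0, None, out=p)
        return p
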