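"""Nei–Gojobori (1986) counting estimator of dN/dS.

Independent of the ML machinery: synonymous and nonsynonymous sites are
counted per codon, differences are averaged over all mutational pathways
with equal weights (pathways through stop codons are skipped), and
proportions are corrected with the Jukes–Cantor formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np

from .code import NUCS, VERTEBRATE_MITO_TABLE_ID, sense_codons, stop_codons
from Bio.Data import CodonTable


@dataclass
class NG86Result:
    dn: float
    ds: float
    omega: float | None  # None when dS == 0 (undefined, not infinite)
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float


@lru_cache(maxsize=None)
def _aa_of(table_id):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table)


@lru_cache(maxsize=None)
def _site_counts(codon: str, table_id: int) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes into stop codons count as nonsynonymous
    (the original convention).
    """
    aa = _aa_of(table_id)
    syn = 0.0
    for pos in range(3):
        for nb in NUCS:
            if nb == codon[pos]:
                continue
            alt = codon[:pos] + nb + codon[pos + 1 :]
            if alt in aa and aa[alt] == aa[codon]:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _pair_diffs(c1: str, c2: str, table_id: int) -> tuple[float, float]:
    """Average (syn, nonsyn) differences over equal-weight pathways."""
    if c1 == c2:
        return 0.0, 0.0
    aa = _aa_of(table_id)
    stops = stop_codons(table_id)
    positions = [k for k in range(3) if c1[k] != c2[k]]
    path_counts = []
    for order in permutations(positions):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in stops:
                blocked = True
                break
            if aa[cur] == aa[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            path_counts.append((sd, nd))
    if not path_counts:
        # every pathway crosses a stop codon; fall back to counting the
        # direct differences as nonsynonymous
        return 0.0, float(len(positions))
    arr = np.array(path_counts)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValueError(
            f"proportion of differences {p:.3f} too large for the "
            "Jukes-Cantor correction"
        )
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(
    seq1: str, seq2: str, table_id: int = VERTEBRATE_MITO_TABLE_ID
) -> NG86Result:
    """NG86 dN, dS and omega for an equal-length, gap-free in-frame pair."""
    s1, s2 = seq1.upper(), seq2.upper()
    if len(s1) != len(s2):
        raise ValueError("sequences differ in length")
    if len(s1) % 3:
        raise ValueError("length not a multiple of 3")
    sense = set(sense_codons(table_id))
    S = N = Sd = Nd = 0.0
    for k in range(0, len(s1), 3):
        c1, c2 = s1[k : k + 3], s2[k : k + 3]
        if c1 not in sense or c2 not in sense:
            raise ValueError(f"non-sense codon pair ({c1},{c2}) at nt {k}")
        s_a, n_a = _site_counts(c1, table_id)
        s_b, n_b = _site_counts(c2, table_id)
        S += 0.5 * (s_a + s_b)
        N += 0.5 * (n_a + n_b)
        sd, nd = _pair_diffs(c1, c2, table_id)
        Sd += sd
        Nd += nd
    ds = _jukes_cantor(Sd / S) if S > 0 else 0.0
    dn = _jukes_cantor(Nd / N) if N > 0 else 0.0
    omega = (dn / ds) if ds > 0 else None
    return NG86Result(dn, ds, omega, S, N, Sd, Nd)
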