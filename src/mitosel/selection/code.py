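"""Vertebrate mitochondrial genetic code and codon state space.

The codon models operate on the 60 sense codons of NCBI translation
table 2 (vertebrate mitochondrial): TAA, TAG, AGA and AGG are stops,
ATA codes Met and TGA codes Trp.  Codons are indexed in lexicographic
ACGT order restricted to the sense set.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCS = "ACGT"
NUC_INDEX = {b: i for i, b in enumerate(NUCS)}
PURINES = frozenset("AG")

VERTEBRATE_MITO_TABLE_ID = 2


def _mito_table():
    return CodonTable.unambiguous_dna_by_id[VERTEBRATE_MITO_TABLE_ID]


@lru_cache(maxsize=None)
def sense_codons(table_id: int = VERTEBRATE_MITO_TABLE_ID) -> tuple[str, ...]:
    """All non-stop codons of the code, in lexicographic ACGT order."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    stops = set(table.stop_codons)
    return tuple(
        a + b + c
        for a in NUCS
        for b in NUCS
        for c in NUCS
        if a + b + c not in stops
    )


@lru_cache(maxsize=None)
def stop_codons(table_id: int = VERTEBRATE_MITO_TABLE_ID) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)


@lru_cache(maxsize=None)
def codon_index(table_id: int = VERTEBRATE_MITO_TABLE_ID) -> dict[str, int]:
    return {c: i for i, c in enumerate(sense_codons(table_id))}


@lru_cache(maxsize=None)
def amino_acids(table_id: int = VERTEBRATE_MITO_TABLE_ID) -> tuple[str, ...]:
    """Amino acid (one-letter) encoded by each sense codon, index-aligned."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return tuple(table.forward_table[c] for c in sense_codons(table_id))


def is_transition(a: str, b: str) -> bool:
    return a != b and ((a in PURINES) == (b in PURINES))


@lru_cache(maxsize=None)
def neighbor_arrays(table_id: int = VERTEBRATE_MITO_TABLE_ID):
    """Sparse structure of single-nucleotide codon exchanges.

    Returns (ii, jj, ts, syn): parallel int/bool arrays over all ordered
    sense-codon pairs differing at exactly one position.  ``ts`` marks
    transitions, ``syn`` synonymous exchanges.
    """
    codons = sense_codons(table_id)
    aas = amino_acids(table_id)
    idx = codon_index(table_id)
    ii, jj, ts, syn = [], [], [], []
    for i, ci in enumerate(codons):
        for pos in range(3):
            for nb in NUCS:
                if nb == ci[pos]:
                    continue
                cj = ci[:pos] + nb + ci[pos + 1 :]
                j = idx.get(cj)
                if j is None:  # change into a stop codon: rate 0
                    continue
                ii.append(i)
                jj.append(j)
                ts.append(is_transition(ci[pos], nb))
                syn.append(aas[i] == aas[j])
    return (
        np.asarray(ii, dtype=np.intp),
        np.asarray(jj, dtype=np.intp),
        np.asarray(ts, dtype=bool),
        np.asarray(syn, dtype=bool),
    )


def encode_codon_sequence(seq: str, table_id: int = VERTEBRATE_MITO_TABLE_ID) -> np.ndarray:
    """Encode an in-frame nucleotide string as sense-codon indices.

    Codons containing gaps or ambiguity characters map to -1 (treated as
    fully ambiguous by the likelihood engine).

    Raises ``ValueError`` on internal stop codons or a length not
    divisible by three.
    """
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    idx = codon_index(table_id)
    stops = stop_codons(table_id)
    out = np.empty(len(seq) // 3, dtype=np.int64)
    s = seq.upper()
    for k in range(0, len(s), 3):
        codon = s[k : k + 3]
        if codon in idx:
            out[k // 3] = idx[codon]
        elif codon in stops:
            raise ValueError(f"internal stop codon {codon} at nucleotide {k}")
        else:
            out[k // 3] = -1
    return out
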