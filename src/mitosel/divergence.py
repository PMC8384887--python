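"""Pairwise identity matrices and sliding-window entropy profiles.

Identity uses pair-deletion: columns with a gap in either row are
excluded from the denominator, which stabilizes percentages across
indel-rich control regions.  Entropy is Shannon entropy in bits per
column over non-gap residues, averaged in sliding windows (default
50 nt, step 1) and reported at window centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from .genome_io import extract_gene

DEFAULT_ALIGN_PARAMS = {
    "match": 1.0,
    "mismatch": -1.0,
    "gap_open": -5.0,
    "gap_extend": -1.0,
}

_GAPLIKE = set("-.")


@dataclass
class PairwiseAlignment:
    a: str  # gapped
    b: str  # gapped
    score: float
    params: dict

    def __post_init__(self):
        if len(self.a) != len(self.b):
            raise ValueError("gapped rows differ in length")


@dataclass
class EntropyProfile:
    alignment_id: str
    window: int
    step: int
    centers: np.ndarray   # 1-based alignment coordinates of window centers
    entropy: np.ndarray   # mean bits per window

    def to_tsv(self, path) -> None:
        pd.DataFrame({"position": self.centers, "entropy_bits": self.entropy}).to_csv(
            path, sep="\t", index=False
        )


def _aligner(params: dict) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params["match"]
    aligner.mismatch_score = params["mismatch"]
    # first gap position costs gap_open, each further one gap_extend
    aligner.open_gap_score = params["gap_open"]
    aligner.extend_gap_score = params["gap_extend"]
    return aligner


def global_align(a: str, b: str, **overrides) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch, affine-gap) alignment of two sequences."""
    if not a or not b:
        raise ValueError("empty input sequence")
    params = {**DEFAULT_ALIGN_PARAMS, **overrides}
    aligner = _aligner(params)
    alignment = next(iter(aligner.align(a.upper(), b.upper())))
    return PairwiseAlignment(
        a=str(alignment[0]), b=str(alignment[1]),
        score=float(alignment.score), params=params,
    )


def pairwise_identity(aln_or_a, b: str | None = None) -> float:
    """Percent identity over columns where both rows are non-gap."""
    if isinstance(aln_or_a, PairwiseAlignment):
        row_a, row_b = aln_or_a.a, aln_or_a.b
    else:
        row_a, row_b = aln_or_a, b
        if row_b is None or len(row_a) != len(row_b):
            raise ValueError("pre-aligned rows of equal length required")
    same = comparable = 0
    for x, y in zip(row_a.upper(), row_b.upper()):
        if x in _GAPLIKE or y in _GAPLIKE:
            continue
        comparable += 1
        if x == y:
            same += 1
    if comparable == 0:
        raise ValueError("no comparable (gap-free) columns")
    return 100.0 * same / comparable


def identity_matrix(gene: str, genomes, **align_params) -> pd.DataFrame:
    """Symmetric percent-identity matrix for one gene across genomes."""
    missing = [g.id for g in genomes if gene not in g.gene_names()]
    if missing:
        raise KeyError(f"gene {gene!r} missing from genomes: {missing}")
    ids = [g.id for g in genomes]
    seqs = [extract_gene(g, gene) for g in genomes]
    n = len(genomes)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(global_align(seqs[i], seqs[j], **align_params))
            mat[i, j] = mat[j, i] = ident
    return pd.DataFrame(mat, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# alignment-column statistics
# ---------------------------------------------------------------------------
def column_entropy(rows: list[str]) -> np.ndarray:
    """Shannon entropy (bits) per column over non-gap A/C/G/T residues.

    Columns with fewer than two non-gap residues carry no information and
    get entropy 0.
    """
    if len(rows) < 2:
        raise ValueError("need at least two rows")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("rows differ in length")
    mat = np.frombuffer("".join(r.upper() for r in rows).encode(), dtype="S1")
    mat = mat.reshape(len(rows), length)
    ent = np.zeros(length)
    for j in range(length):
        col = mat[:, j]
        counts = np.array([(col == base.encode()).sum() for base in "ACGT"])
        total = counts.sum()
        if total < 2:
            continue
        p = counts[counts > 0] / total
        ent[j] = float(-(p * np.log2(p)).sum())
    return ent


def window_entropy(
    rows: list[str],
    window: int = 50,
    step: int = 1,
    alignment_id: str = "",
) -> EntropyProfile:
    """Mean per-column entropy in sliding windows over an alignment."""
    ent = column_entropy(rows)
    length = len(ent)
    if window > length:
        raise ValueError(f"window {window} exceeds alignment length {length}")
    kernel = np.ones(window) / window
    means = np.convolve(ent, kernel, mode="valid")[::step]
    starts = np.arange(0, length - window + 1, step)
    centers = starts + 1 + (window - 1) / 2.0  # 1-based window centers
    return EntropyProfile(alignment_id, window, step, centers, means)


def polymorphic_sites(
    rows: list[str], regions: list[tuple[int, int]] | None = None
) -> list[int]:
    """Count columns with >=2 distinct non-gap residues per [start, end) region."""
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("rows differ in length")
    if regions is None:
        regions = [(0, length)]
    poly = np.zeros(length, dtype=bool)
    upper = [r.upper() for r in rows]
    for j in range(length):
        residues = {r[j] for r in upper} - _GAPLIKE - {"N"}
        poly[j] = len(residues) >= 2
    out = []
    for start, end in regions:
        if start < 0 or end > length or end <= start:
            raise ValueError(f"region [{start},{end}) outside alignment")
        out.append(int(poly[start:end].sum()))
    return out
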