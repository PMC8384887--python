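"""Base composition, strand skews, amino-acid usage and RSCU statistics.

Skews are (A-T)/(A+T) and (G-C)/(G+C), computed on the deposited (H)
strand at genome scope and on the sense strand at gene scope, so a gene
like ND6 (L strand) shows its characteristic skew reversal.  RSCU is the
observed codon count divided by its expectation under uniform usage
within the synonymous family of the vertebrate mitochondrial code.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import MT_STOP_CODONS, InternalStopError, translate_mt
from .selection.code import VERTEBRATE_MITO_TABLE_ID, amino_acids, sense_codons


class CompositionError(ValueError):
    pass


@dataclass
class CompositionProfile:
    scope: str
    counts: dict[str, int]
    frequencies: dict[str, float]
    at_skew: float
    gc_skew: float

    @property
    def gc_fraction(self) -> float:
        return self.frequencies["G"] + self.frequencies["C"]

    def as_vector(self) -> np.ndarray:
        """(fA, fC, fG, fT) — convenient for cross-genome correlations."""
        return np.array([self.frequencies[b] for b in "ACGT"])


def base_composition(seq: str, scope: str = "genome") -> CompositionProfile:
    """Counts, frequencies and both skews; N's excluded from denominators."""
    s = seq.upper()
    if not s:
        raise CompositionError("empty sequence")
    bad = set(s) - set("ACGTN")
    if bad:
        raise CompositionError(
            f"ambiguity codes other than N are not supported: {sorted(bad)}"
        )
    counts = {b: s.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise CompositionError("all-N sequence has no defined composition")
    freqs = {b: c / total for b, c in counts.items()}
    at = counts["A"] + counts["T"]
    gc = counts["G"] + counts["C"]
    at_skew = (counts["A"] - counts["T"]) / at if at else 0.0
    gc_skew = (counts["G"] - counts["C"]) / gc if gc else 0.0
    return CompositionProfile(scope, counts, freqs, at_skew, gc_skew)


def genome_composition_table(genome) -> pd.DataFrame:
    """Genome-scope profile (H strand) plus per-gene sense-strand profiles."""
    from .genome_io import extract_gene

    rows = []

    def row_of(profile: CompositionProfile):
        return {
            "scope": profile.scope,
            **{f"freq_{b}": profile.frequencies[b] for b in "ACGT"},
            **{f"count_{b}": profile.counts[b] for b in "ACGT"},
            "at_skew": profile.at_skew,
            "gc_skew": profile.gc_skew,
        }

    rows.append(row_of(base_composition(genome.sequence, scope="genome")))
    for f in genome.features:
        rows.append(
            row_of(base_composition(extract_gene(genome, f.name), scope=f.name))
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# codon and amino-acid usage
# ---------------------------------------------------------------------------
@dataclass
class RSCUTable:
    table_id: int
    counts: dict[str, int]
    rscu: dict[str, float]
    families: dict[str, list[str]] = field(repr=False, default_factory=dict)

    def as_dataframe(self) -> pd.DataFrame:
        aa_of = dict(zip(sense_codons(self.table_id), amino_acids(self.table_id)))
        rows = [
            {
                "codon": c,
                "amino_acid": aa_of[c],
                "count": self.counts[c],
                "rscu": self.rscu[c],
            }
            for c in sense_codons(self.table_id)
        ]
        return pd.DataFrame(rows)

    def top_codons(self, n: int = 7) -> list[str]:
        """The n most-used codons by RSCU (count as tie-break)."""
        return sorted(
            self.rscu, key=lambda c: (self.rscu[c], self.counts[c]), reverse=True
        )[:n]


def _codon_counts(cds_list, table_id: int) -> Counter:
    counts: Counter = Counter()
    for cds in cds_list:
        s = cds.upper()
        if len(s) % 3:
            raise ValueError(
                f"CDS length {len(s)} not a multiple of 3; complete or trim it first"
            )
        for k in range(0, len(s), 3):
            codon = s[k : k + 3]
            if codon in MT_STOP_CODONS:
                if k + 3 < len(s):
                    raise InternalStopError(k, codon)
                continue  # terminal stop excluded from usage counts
            counts[codon] += 1
    return counts


def rscu(cds_list, table_id: int = VERTEBRATE_MITO_TABLE_ID) -> RSCUTable:
    """Relative synonymous codon usage over a set of in-frame CDSs."""
    counts = _codon_counts(cds_list, table_id)
    codons = sense_codons(table_id)
    aas = amino_acids(table_id)
    families: dict[str, list[str]] = {}
    for codon, aa in zip(codons, aas):
        families.setdefault(aa, []).append(codon)
    values = {}
    for aa, fam in families.items():
        fam_total = sum(counts.get(c, 0) for c in fam)
        if fam_total == 0:
            for c in fam:
                values[c] = 0.0
        else:
            expected = fam_total / len(fam)
            for c in fam:
                values[c] = counts.get(c, 0) / expected
    return RSCUTable(
        table_id=table_id,
        counts={c: counts.get(c, 0) for c in codons},
        rscu=values,
        families=families,
    )


def amino_acid_usage(cds_list, completion: str = "none") -> dict[str, float]:
    """Amino-acid frequencies over translated CDSs (frequencies sum to 1)."""
    tally: Counter = Counter()
    for cds in cds_list:
        protein = translate_mt(cds, completion=completion)
        tally.update(protein)
    total = sum(tally.values())
    if total == 0:
        raise ValueError("no residues translated")
    return {aa: n / total for aa, n in sorted(tally.items())}


# ---------------------------------------------------------------------------
# cross-genome correlation
# ---------------------------------------------------------------------------
def composition_correlation(
    v1,
    v2,
    method: str = "pearson",
    permutation: bool = False,
    n_permutations: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Correlate paired composition/skew vectors across two genomes.

    p-values come from the usual t (pearson) or large-sample (spearman)
    approximations; ``permutation=True`` switches to an exact-style
    permutation p-value, recommended for n < 10.
    """
    x = np.asarray(v1, dtype=float)
    y = np.asarray(v2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D vectors required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CompositionError("zero variance: correlation undefined")
    if method == "pearson":
        stat = stats.pearsonr
    elif method == "spearman":
        stat = stats.spearmanr
    else:
        raise ValueError(f"unknown method {method!r}")
    r, p = stat(x, y)
    if permutation:
        rng = np.random.default_rng(seed)
        observed = abs(r)
        hits = 0
        for _ in range(n_permutations):
            rp, _ = stat(x, rng.permutation(y))
            if abs(rp) >= observed - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    return float(r), float(p)
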