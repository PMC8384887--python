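"""In-frame codon alignments: container, FASTA/PHYLIP I/O, column cleaning."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .code import VERTEBRATE_MITO_TABLE_ID, codon_index, stop_codons

_GAPLIKE = set("-.")


@dataclass
class CodonAlignment:
    """Gap-aware aligned coding sequences indexed by taxon.

    Rows are nucleotide strings of equal length, a multiple of three;
    internal stop codons (after gap removal) are rejected.
    """

    taxa: list[str]
    rows: list[str]
    table_id: int = VERTEBRATE_MITO_TABLE_ID
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in length")
        if not self.rows:
            raise ValueError("empty alignment")
        length = len(self.rows[0])
        if any(len(r) != length for r in self.rows):
            raise ValueError("rows have unequal lengths")
        if length % 3:
            raise ValueError(f"alignment length {length} not a multiple of 3")
        self.rows = [r.upper() for r in self.rows]
        self._index = {t: i for i, t in enumerate(self.taxa)}
        if len(self._index) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        stops = stop_codons(self.table_id)
        for taxon, row in zip(self.taxa, self.rows):
            ungapped = "".join(ch for ch in row if ch not in _GAPLIKE)
            # terminal stop codons are expected to have been trimmed upstream
            for k in range(0, len(ungapped) - len(ungapped) % 3, 3):
                if ungapped[k : k + 3] in stops:
                    raise ValueError(
                        f"internal stop codon in {taxon} at ungapped nt {k}"
                    )

    def __len__(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3

    def __getitem__(self, taxon: str) -> str:
        return self.rows[self._index[taxon]]

    @classmethod
    def from_fasta(cls, path, table_id: int = VERTEBRATE_MITO_TABLE_ID):
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records], table_id)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(row), id=taxon, description="")
            for taxon, row in zip(self.taxa, self.rows)
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_phylip(self, path) -> None:
        """PHYLIP sequential with relaxed (whitespace-delimited) names."""
        with open(path, "w") as fh:
            fh.write(f" {len(self.taxa)} {len(self.rows[0])}\n")
            for taxon, row in zip(self.taxa, self.rows):
                fh.write(f"{taxon}  {row}\n")

    @classmethod
    def from_phylip(cls, path, table_id: int = VERTEBRATE_MITO_TABLE_ID):
        text = Path(path).read_text().split()
        n, length = int(text[0]), int(text[1])
        taxa, rows = [], []
        k = 2
        for _ in range(n):
            taxa.append(text[k])
            k += 1
            chunks = []
            got = 0
            while got < length:
                chunks.append(text[k])
                got += len(text[k])
                k += 1
            rows.append("".join(chunks))
        return cls(taxa, rows, table_id)


def clean_codon_columns(aln: CodonAlignment) -> tuple[CodonAlignment, int]:
    """Drop codon columns containing any gap or ambiguity character.

    Returns the filtered alignment and the number of removed codon
    columns.  Raises if nothing survives.
    """
    idx = codon_index(aln.table_id)
    n = aln.n_codons
    keep = []
    for k in range(n):
        ok = all(row[3 * k : 3 * k + 3] in idx for row in aln.rows)
        if ok:
            keep.append(k)
    if not keep:
        raise ValueError("no clean codon columns remain")
    rows = [
        "".join(row[3 * k : 3 * k + 3] for k in keep) for row in aln.rows
    ]
    return CodonAlignment(list(aln.taxa), rows, aln.table_id), n - len(keep)


def encode_alignment(aln: CodonAlignment) -> np.ndarray:
    """Sense-codon index matrix (n_taxa, n_codons); -1 marks ambiguity."""
    idx = codon_index(aln.table_id)
    out = np.full((len(aln.taxa), aln.n_codons), -1, dtype=np.int64)
    for i, row in enumerate(aln.rows):
        for k in range(aln.n_codons):
            out[i, k] = idx.get(row[3 * k : 3 * k + 3], -1)
    return out
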