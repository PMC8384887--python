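"""Annotated mitogenomes: parsing, validation, gene extraction, translation.

Coordinates are 0-based half-open internally and 1-based inclusive in
GenBank output.  ``H`` is the reference (heavy) strand as deposited, ``L``
the opposite; per-gene sequences are always returned on the sense strand.
Translation uses the vertebrate mitochondrial code (NCBI table 2), with
support for the transcriptional exceptions seen in bird mitogenomes:
incomplete (polyadenylation-completed) stop codons and single-nucleotide
frameshifts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

GENE_KINDS = ("PCG", "tRNA", "rRNA", "control_region", "other")

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]
MT_STOP_CODONS = frozenset(_MITO_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeValidationError(ValueError):
    pass


class InternalStopError(ValueError):
    """Premature stop codon during translation; carries the nt offset."""

    def __init__(self, offset: int, codon: str):
        super().__init__(f"internal stop codon {codon} at nucleotide offset {offset}")
        self.offset = offset
        self.codon = codon


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------
@dataclass
class GeneFeature:
    name: str
    kind: str
    start: int  # 0-based
    end: int    # half-open; may exceed sequence length on circular wrap
    strand: str  # H or L
    notes: str = ""

    def __post_init__(self):
        if self.kind not in GENE_KINDS:
            raise GenomeValidationError(f"unknown feature kind {self.kind!r}")
        if self.end <= self.start:
            raise GenomeValidationError(
                f"{self.name}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("H", "L"):
            raise GenomeValidationError(f"{self.name}: strand must be H or L")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Mitogenome:
    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    source_taxon: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise GenomeValidationError("empty sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise GenomeValidationError(f"non-ACGTN characters: {sorted(bad)}")
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        for f in self.features:
            limit = 2 * n if self.circular else n
            if f.end > limit:
                raise GenomeValidationError(
                    f"feature {f.name} [{f.start},{f.end}) outside sequence "
                    f"of length {n} ({'circular' if self.circular else 'linear'})"
                )
        self.features = sorted(self.features, key=lambda f: f.start)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r} in {self.id}")

    def gene_names(self) -> list[str]:
        return [f.name for f in self.features]


@dataclass
class StopCodonStatus:
    gene: str
    status: str  # complete | truncated_T | truncated_TA | unclassified
    terminal_codon: str


@dataclass
class FrameshiftReport:
    gene: str
    detected: bool
    skip_position: int | None = None
    corrected_protein_length: int | None = None
    note: str = ""


# ---------------------------------------------------------------------------
# name canonicalization
# ---------------------------------------------------------------------------
_PCG_ALIASES = {
    "ND1": "ND1", "NAD1": "ND1", "NADH1": "ND1",
    "ND2": "ND2", "NAD2": "ND2", "NADH2": "ND2",
    "ND3": "ND3", "NAD3": "ND3", "NADH3": "ND3",
    "ND4": "ND4", "NAD4": "ND4", "NADH4": "ND4",
    "ND4L": "ND4L", "NAD4L": "ND4L",
    "ND5": "ND5", "NAD5": "ND5", "NADH5": "ND5",
    "ND6": "ND6", "NAD6": "ND6", "NADH6": "ND6",
    "COX1": "COX1", "COI": "COX1", "CO1": "COX1", "COXI": "COX1",
    "COX2": "COX2", "COII": "COX2", "CO2": "COX2", "COXII": "COX2",
    "COX3": "COX3", "COIII": "COX3", "CO3": "COX3", "COXIII": "COX3",
    "ATP6": "ATP6", "ATPASE6": "ATP6", "ATP SYNTHASE F0 SUBUNIT 6": "ATP6",
    "ATP8": "ATP8", "ATPASE8": "ATP8", "ATP SYNTHASE F0 SUBUNIT 8": "ATP8",
    "CYTB": "CYTB", "COB": "CYTB", "CYT B": "CYTB", "CYTOCHROME B": "CYTB",
}

_PCG_PRODUCTS = {
    "NADH DEHYDROGENASE SUBUNIT 1": "ND1",
    "NADH DEHYDROGENASE SUBUNIT 2": "ND2",
    "NADH DEHYDROGENASE SUBUNIT 3": "ND3",
    "NADH DEHYDROGENASE SUBUNIT 4": "ND4",
    "NADH DEHYDROGENASE SUBUNIT 4L": "ND4L",
    "NADH DEHYDROGENASE SUBUNIT 5": "ND5",
    "NADH DEHYDROGENASE SUBUNIT 6": "ND6",
    "CYTOCHROME C OXIDASE SUBUNIT I": "COX1",
    "CYTOCHROME C OXIDASE SUBUNIT II": "COX2",
    "CYTOCHROME C OXIDASE SUBUNIT III": "COX3",
    "CYTOCHROME B": "CYTB",
}

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# paralog tRNAs: anticodon family -> canonical suffix
_TRNA_PARALOGS = {
    ("L", "UUR"): "trnL2", ("L", "UUA"): "trnL2", ("L", "UAA"): "trnL2",
    ("L", "CUN"): "trnL1", ("L", "CUA"): "trnL1", ("L", "UAG"): "trnL1",
    ("S", "UCN"): "trnS2", ("S", "UCA"): "trnS2", ("S", "UGA"): "trnS2",
    ("S", "AGY"): "trnS1", ("S", "AGC"): "trnS1", ("S", "GCU"): "trnS1",
}


def canonical_gene_name(raw: str, kind: str, note: str = "") -> str:
    """Map GenBank gene/product spellings to the package's symbols."""
    token = raw.strip()
    if kind == "PCG":
        upper = token.upper().replace("-", "")
        if upper in _PCG_ALIASES:
            return _PCG_ALIASES[upper]
        if token.upper() in _PCG_PRODUCTS:
            return _PCG_PRODUCTS[token.upper()]
        return token
    if kind == "tRNA":
        # accept 'trnF', 'trnL2', 'tRNA-Phe', 'tRNA-Leu (UUR)'
        import re

        if re.fullmatch(r"trn[A-Z][12]?", token):
            return token
        t = token.replace("tRNA-", "").replace("trn", "").strip()
        aa3 = t[:3].upper()
        one = _AA3_TO_1.get(aa3, t[:1].upper())
        if one in ("L", "S"):
            blob = (token + " " + note).upper()
            for (aa, codon), name in _TRNA_PARALOGS.items():
                if aa == one and codon in blob:
                    return name
            return f"trn{one}1"  # undeterminable paralog: default suffix 1
        return f"trn{one}"
    if kind == "rRNA":
        up = token.upper()
        if "12" in up or "SMALL" in up or up in ("RRNS", "S-RRNA"):
            return "rrnS"
        if "16" in up or "LARGE" in up or up in ("RRNL", "L-RRNA"):
            return "rrnL"
        return token
    if kind == "control_region":
        return "CR"
    return token


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------
def read_genbank(path) -> Mitogenome:
    """Parse a GenBank flatfile into a validated :class:`Mitogenome`."""
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq)
    if not seq or set(seq.upper()) == {"N"}:
        raise GenomeValidationError(f"{path}: record has no usable sequence")
    circular = record.annotations.get("topology", "linear") == "circular"
    features = []
    for feat in record.features:
        kind = {
            "CDS": "PCG",
            "tRNA": "tRNA",
            "rRNA": "rRNA",
            "D-loop": "control_region",
        }.get(feat.type)
        if feat.type == "misc_feature":
            notes = " ".join(feat.qualifiers.get("note", [])).lower()
            if "control region" in notes or "d-loop" in notes:
                kind = "control_region"
        if kind is None:
            if feat.type in ("source", "gene"):
                continue
            kind = "other"
        quals = feat.qualifiers
        raw = (
            quals.get("gene", [None])[0]
            or quals.get("product", [None])[0]
            or ("CR" if kind == "control_region" else feat.type)
        )
        note = " ".join(
            quals.get("note", []) + quals.get("codon_recognized", [])
        )
        name = canonical_gene_name(raw, kind, note)
        start = int(feat.location.start)
        end = int(feat.location.end)
        strand = "L" if feat.location.strand == -1 else "H"
        features.append(
            GeneFeature(name=name, kind=kind, start=start, end=end,
                        strand=strand, notes=note)
        )
    return Mitogenome(
        id=record.id or record.name,
        sequence=seq,
        circular=circular,
        features=features,
        source_taxon=record.annotations.get("organism", ""),
    )


def write_genbank(genome: Mitogenome, path) -> None:
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id.split(".")[0][:16],
        description=f"{genome.source_taxon} mitochondrion".strip(),
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "organism": genome.source_taxon,
        },
    )
    type_of = {
        "PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
        "control_region": "D-loop", "other": "misc_feature",
    }
    for f in genome.features:
        quals = {"gene": [f.name]}
        if f.notes:
            quals["note"] = [f.notes]
        record.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=-1 if f.strand == "L" else 1),
                type=type_of[f.kind],
                qualifiers=quals,
            )
        )
    SeqIO.write(record, str(path), "genbank")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene extraction and translation
# ---------------------------------------------------------------------------
def extract_gene(genome: Mitogenome, name: str) -> str:
    """Sense-strand sequence of a named feature (L features reverse-complemented)."""
    f = genome.feature(name)
    n = len(genome.sequence)
    if f.end <= n:
        sub = genome.sequence[f.start : f.end]
    elif genome.circular:
        sub = genome.sequence[f.start :] + genome.sequence[: f.end - n]
    else:
        raise GenomeValidationError(f"{name} wraps origin of a linear record")
    return reverse_complement(sub) if f.strand == "L" else sub


def translate_mt(cds: str, completion: str = "none") -> str:
    """Translate a CDS under the vertebrate mitochondrial code.

    ``completion='polyA'`` appends A residues to complete a terminal T/TA
    codon (mRNA polyadenylation).  The terminal stop is not included in
    the protein.  Raises :class:`InternalStopError` on a premature stop.
    """
    s = cds.upper()
    if completion == "polyA":
        if len(s) % 3:
            s += "A" * (3 - len(s) % 3)
    elif completion != "none":
        raise ValueError(f"unknown completion mode {completion!r}")
    if len(s) < 3:
        raise ValueError("CDS shorter than one codon")
    usable = len(s) - len(s) % 3
    protein = []
    fwd = _MITO_TABLE.forward_table
    for k in range(0, usable, 3):
        codon = s[k : k + 3]
        if codon in MT_STOP_CODONS:
            if k + 3 < usable:
                raise InternalStopError(k, codon)
            break
        protein.append(fwd.get(codon, "X"))
    return "".join(protein)


def detect_incomplete_stop(genome: Mitogenome, gene: str) -> StopCodonStatus:
    """Classify a PCG terminus as complete, truncated (T/TA) or unclassified.

    A truncated terminus must abut the downstream feature (no spacer) so
    that polyadenylation of the transcript can complete the TAA stop.
    """
    f = genome.feature(gene)
    if f.kind != "PCG":
        raise ValueError(f"{gene} is not a protein-coding gene")
    cds = extract_gene(genome, gene)
    rem = len(cds) % 3
    terminal = cds[-3:] if rem == 0 else cds[-rem:]
    if rem == 0 and terminal in MT_STOP_CODONS:
        return StopCodonStatus(gene, "complete", terminal)
    if rem == 2 and cds.endswith("TA") and _abuts_downstream(genome, f):
        return StopCodonStatus(gene, "truncated_TA", terminal)
    if rem == 1 and cds.endswith("T") and _abuts_downstream(genome, f):
        return StopCodonStatus(gene, "truncated_T", terminal)
    return StopCodonStatus(gene, "unclassified", terminal)


def _abuts_downstream(genome: Mitogenome, f: GeneFeature) -> bool:
    """True when the next feature in transcription direction starts flush."""
    n = len(genome.sequence)
    if f.strand == "H":
        boundary = f.end % n if genome.circular else f.end
        return any(g.start == boundary for g in genome.features if g is not f)
    return any(g.end == f.start for g in genome.features if g is not f)


def detect_frameshift(cds: str) -> FrameshiftReport:
    """Detect a single-nucleotide insertion rescued by translational skipping.

    If naive translation of frame 0 hits a premature stop, every single-
    nucleotide skip position is tried (earliest first); the first skip
    giving a stop-free frame that ends in a valid stop codon is reported.
    """
    s = cds.upper()

    def first_internal_stop(seq: str) -> int | None:
        usable = len(seq) - len(seq) % 3
        for k in range(0, usable, 3):
            if seq[k : k + 3] in MT_STOP_CODONS:
                return k if k + 3 < usable else None
        return None

    def ends_with_stop(seq: str) -> bool:
        usable = len(seq) - len(seq) % 3
        return usable >= 3 and seq[usable - 3 : usable] in MT_STOP_CODONS

    if first_internal_stop(s) is None:
        return FrameshiftReport(gene="", detected=False, note="clean reading frame")
    for skip in range(len(s)):
        fixed = s[:skip] + s[skip + 1 :]
        if first_internal_stop(fixed) is None and ends_with_stop(fixed):
            usable = len(fixed) - len(fixed) % 3
            return FrameshiftReport(
                gene="",
                detected=True,
                skip_position=skip,
                corrected_protein_length=usable // 3 - 1,
            )
    return FrameshiftReport(
        gene="",
        detected=False,
        note="premature stop present but no single-nucleotide skip rescues the frame",
    )


# ---------------------------------------------------------------------------
# gene order
# ---------------------------------------------------------------------------
def gene_order_signature(genome: Mitogenome) -> list[tuple[str, str]]:
    """Rotation-normalized (name, strand) signature, starting at trnF."""
    if len(genome.features) < 2:
        raise ValueError("need at least two features for a gene-order signature")
    sig = [(f.name, f.strand) for f in genome.features]
    return _rotate_to_start(sig)


def _rotate_to_start(sig: list[tuple[str, str]]) -> list[tuple[str, str]]:
    names = [s[0] for s in sig]
    if "trnF" in names:
        k = names.index("trnF")
    else:  # deterministic fallback: lexicographically minimal rotation
        k = min(range(len(sig)), key=lambda i: sig[i:] + sig[:i])
    return sig[k:] + sig[:k]


def ancestral_gene_order() -> list[tuple[str, str]]:
    """The shipped chicken-like ancestral avian order (37 genes + CR)."""
    table = load_gene_table()
    return [(row["name"], row["strand"]) for row in table]


def matches_ancestral(
    signature: list[tuple[str, str]],
    reference: list[tuple[str, str]] | None = None,
) -> bool:
    ref = _rotate_to_start(reference or ancestral_gene_order())
    return _rotate_to_start(list(signature)) == ref


def write_signature_tsv(signature, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tname\tstrand\n")
        for i, (name, strand) in enumerate(signature, start=1):
            fh.write(f"{i}\t{name}\t{strand}\n")


def load_gene_table() -> list[dict]:
    """Shipped gene table: name, kind, strand and default length, in order."""
    ref = resources.files("mitosel.data") / "gene_table.tsv"
    rows = []
    with ref.open() as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for row in reader:
            row["length"] = int(row["length"])
            rows.append(row)
    return rows
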