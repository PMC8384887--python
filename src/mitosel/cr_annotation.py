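"""Control-region annotation: conserved blocks, domains, tracts, STRs, hairpins.

The avian control region is organized in three domains: a variable 5'
domain (I) ending at the F box, a conserved central domain (II) with the
short conserved blocks F/E/D/C, CSBa/CSBb and the avian-specific Bird
Box, and a 3' domain (III) opening with CSB1 and often carrying tandem
repeats and stem-loop-forming sequence.  Element consensi live in an
editable library file (IUPAC strings with per-motif mismatch allowances).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

from .genome_io import reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

PAIR_SCORE = {("G", "C"): 3, ("C", "G"): 3, ("A", "T"): 2, ("T", "A"): 2}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------
@dataclass
class MotifHit:
    name: str
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass
class STRArray:
    unit: str            # lexicographically minimal rotation
    unit_as_found: str   # phase as it occurs in the sequence
    copies: int
    partial: int
    start: int
    end: int

    def __post_init__(self):
        if self.end - self.start != self.copies * len(self.unit) + self.partial:
            raise ValueError("inconsistent STR span")

    def copy_count(self, count_partial_as_copy: bool = False) -> int:
        """Copy number; optionally counting a >=50% partial repeat as a copy."""
        bonus = 1 if count_partial_as_copy and 2 * self.partial >= len(self.unit) else 0
        return self.copies + bonus


@dataclass
class PolyTract:
    base: str
    start: int
    end: int


@dataclass
class TAIsland:
    start: int
    end: int


@dataclass
class HairpinCandidate:
    stem_start_5p: int
    stem_len: int
    loop_len: int
    stem_start_3p: int
    score: int

    @property
    def span(self) -> tuple[int, int]:
        return self.stem_start_5p, self.stem_start_3p + self.stem_len


@dataclass
class CRAnnotation:
    length: int
    domains: dict[str, tuple[int, int]]
    unresolved: list[str] = field(default_factory=list)
    motif_hits: list[MotifHit] = field(default_factory=list)
    poly_tracts: list[PolyTract] = field(default_factory=list)
    ta_islands: list[TAIsland] = field(default_factory=list)
    str_arrays: list[STRArray] = field(default_factory=list)
    hairpins: list[HairpinCandidate] = field(default_factory=list)

    def missing_motifs(self, library) -> list[str]:
        """Library elements with no hit — absence is a reportable result."""
        found = {h.name for h in self.motif_hits}
        return [m.name for m in library if m.name not in found]

    def to_bed(self, path, chrom: str = "CR") -> None:
        with open(path, "w") as fh:
            for name, (s, e) in self.domains.items():
                fh.write(f"{chrom}\t{s}\t{e}\tdomain_{name}\n")
            for h in self.motif_hits:
                fh.write(f"{chrom}\t{h.start}\t{h.end}\t{h.name}\n")
            for t in self.poly_tracts:
                fh.write(f"{chrom}\t{t.start}\t{t.end}\tpoly{t.base}\n")
            for i in self.ta_islands:
                fh.write(f"{chrom}\t{i.start}\t{i.end}\tTA_island\n")
            for s in self.str_arrays:
                fh.write(f"{chrom}\t{s.start}\t{s.end}\tSTR_{s.unit}x{s.copies}\n")
            for hp in self.hairpins:
                a, b = hp.span
                fh.write(f"{chrom}\t{a}\t{b}\thairpin_stem{hp.stem_len}\n")


@dataclass
class MotifDef:
    name: str
    iupac: str
    max_mismatch: int
    domain: str = ""


def load_motif_library(path=None) -> list[MotifDef]:
    """Element library: shipped defaults or a user TSV (name, iupac, mm, domain)."""
    if path is None:
        src = resources.files("mitosel.data") / "cr_motifs.tsv"
        fh = src.open()
    else:
        fh = open(path)
    with fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        return [
            MotifDef(
                row["name"], row["iupac"].upper(),
                int(row["max_mismatch"]), row.get("domain", ""),
            )
            for row in reader
        ]


# ---------------------------------------------------------------------------
# element scanners
# ---------------------------------------------------------------------------
def find_motif(
    seq: str,
    pattern: str,
    max_mismatch: int = 0,
    name: str = "",
    both_strands: bool = False,
) -> list[MotifHit]:
    """All Hamming-distance matches of an IUPAC pattern, sorted by (mm, start)."""
    if not pattern:
        raise ValueError("empty pattern")
    pattern = pattern.upper()
    bad = [ch for ch in pattern if ch not in IUPAC]
    if bad:
        raise ValueError(f"invalid IUPAC letters: {bad}")
    if max_mismatch >= len(pattern):
        raise ValueError("max_mismatch must be smaller than the pattern")
    s = seq.upper()
    hits = []

    def scan(text: str, strand: str):
        allowed = [set(IUPAC[ch]) for ch in pattern]
        m = len(pattern)
        for i in range(len(text) - m + 1):
            mm = 0
            for j in range(m):
                if text[i + j] not in allowed[j]:
                    mm += 1
                    if mm > max_mismatch:
                        break
            else:
                if strand == "H":
                    hits.append(MotifHit(name or pattern, i, i + m, "H", mm))
                else:  # report on reference coordinates
                    start = len(text) - (i + m)
                    hits.append(MotifHit(name or pattern, start, start + m, "L", mm))

    scan(s, "H")
    if both_strands:
        scan(reverse_complement(s), "L")
    hits.sort(key=lambda h: (h.mismatches, h.start))
    return hits


def find_str(
    seq: str, min_unit: int = 2, max_unit: int = 10, min_copies: int = 3,
) -> list[STRArray]:
    """Maximal non-extendable tandem arrays of short units.

    Homopolymers (unit length 1) are left to :func:`find_poly_tract`
    unless ``min_unit`` forces a longer representation.  Overlapping
    candidates are resolved greedily by longer span, then smaller unit,
    then leftmost start.  Use :meth:`STRArray.copy_count` to count a
    >=50% partial terminal repeat as a full copy.
    """
    s = seq.upper()
    candidates = _str_candidates(s, min_unit, max_unit, min_copies)
    candidates.sort(key=lambda a: (-(a.end - a.start), len(a.unit), a.start))
    chosen: list[STRArray] = []
    for cand in candidates:
        if all(cand.end <= c.start or cand.start >= c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda a: a.start)
    return chosen


def _str_candidates(s: str, min_unit: int, max_unit: int, min_copies: int):
    out = []
    n = len(s)
    for u in range(min_unit, max_unit + 1):
        i = 0
        while i + u < n:
            if s[i] != s[i + u]:
                i += 1
                continue
            # maximal run of period u starting at i
            j = i
            while j + u < n and s[j + u] == s[j]:
                j += 1
            span = (j + u) - i  # positions i .. j+u-1 are periodic
            copies, partial = divmod(span, u)
            if copies >= min_copies:
                unit_found = s[i : i + u]
                # report each array once, at its canonical unit length:
                # the fundamental period, or its smallest admissible
                # multiple when the period is below min_unit
                p = _fundamental_period(unit_found)
                canonical = p if p >= min_unit else p * -(-min_unit // p)
                if canonical == u:
                    out.append(
                        STRArray(
                            unit=_min_rotation(unit_found),
                            unit_as_found=unit_found,
                            copies=copies,
                            partial=partial,
                            start=i,
                            end=i + span,
                        )
                    )
            i = j + 1
    return out


def _fundamental_period(unit: str) -> int:
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return p
    return len(unit)


def _min_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def find_poly_tract(
    seq: str, base: str = "C", min_len: int = 5, mode: str = "run"
) -> list[PolyTract] | list[TAIsland]:
    """Maximal homopolymer runs, or TA islands interrupting a poly-C tract.

    ``mode='run'`` returns maximal runs of ``base`` of length >= min_len.
    ``mode='ta_island'`` returns TA-repeat stretches flanked by C runs
    (the 'TA island' arrangement inside a poly-C region).
    """
    s = seq.upper()
    if mode == "run":
        runs = []
        i = 0
        while i < len(s):
            if s[i] == base:
                j = i
                while j < len(s) and s[j] == base:
                    j += 1
                if j - i >= min_len:
                    runs.append(PolyTract(base, i, j))
                i = j
            else:
                i += 1
        return runs
    if mode == "ta_island":
        import re

        islands = []
        for m in re.finditer(r"(?<=CC)((?:TA)+)(?=CC)", s):
            islands.append(TAIsland(m.start(1), m.end(1)))
        return islands
    raise ValueError(f"unknown mode {mode!r}")


def find_hairpin(
    seq: str, min_stem: int = 6, max_loop: int = 30, min_loop: int = 3,
    max_candidates: int | None = None,
) -> list[HairpinCandidate]:
    """Perfect inverted repeats able to form a stem-loop.

    Candidates are maximal complementary stems (G:C scored 3, A:T scored
    2) with loop length in [min_loop, max_loop], ranked by pairing score
    and selected greedily without overlap.
    """
    s = seq.upper()
    n = len(s)
    if n < 2 * min_stem + min_loop:
        raise ValueError("sequence too short for a hairpin")
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    raw: list[HairpinCandidate] = []
    # i = last position of 5' arm, loop spans (i+1 .. i+loop)
    for i in range(n):
        for loop in range(min_loop, max_loop + 1):
            j = i + loop + 1  # first position of 3' arm
            if j >= n:
                break
            # extend stem outward while complementary
            k = 0
            while i - k >= 0 and j + k < n and comp.get(s[i - k]) == s[j + k]:
                k += 1
            if k >= min_stem:
                score = sum(
                    PAIR_SCORE.get((s[i - t], s[j + t]), 0) for t in range(k)
                )
                raw.append(
                    HairpinCandidate(
                        stem_start_5p=i - k + 1,
                        stem_len=k,
                        loop_len=loop,
                        stem_start_3p=j,
                        score=score,
                    )
                )
    raw.sort(key=lambda h: (-h.score, h.stem_start_5p, h.loop_len))
    chosen: list[HairpinCandidate] = []
    for cand in raw:
        a, b = cand.span
        if all(b <= c.span[0] or a >= c.span[1] for c in chosen):
            chosen.append(cand)
        if max_candidates and len(chosen) >= max_candidates:
            break
    return chosen


# ---------------------------------------------------------------------------
# domain partitioning
# ---------------------------------------------------------------------------
def partition_domains(cr: str, hits: list[MotifHit]) -> CRAnnotation:
    """Three-domain partition anchored on the F box and CSB1.

    Domain I runs from the CR start to the F-box hit, domain II from the
    F box to CSB1, domain III from CSB1 to the CR end.  Missing anchors
    leave the corresponding boundary unresolved.
    """
    n = len(cr)
    f_hit = _best_hit(hits, "F")
    csb1_hit = _best_hit(hits, "CSB1")
    domains: dict[str, tuple[int, int]] = {}
    unresolved = []
    if f_hit and csb1_hit and f_hit.start < csb1_hit.start:
        domains["I"] = (0, f_hit.start)
        domains["II"] = (f_hit.start, csb1_hit.start)
        domains["III"] = (csb1_hit.start, n)
    elif f_hit:
        domains["I"] = (0, f_hit.start)
        domains["II+III"] = (f_hit.start, n)
        unresolved.append("II/III")
    elif csb1_hit:
        domains["I+II"] = (0, csb1_hit.start)
        domains["III"] = (csb1_hit.start, n)
        unresolved.append("I/II")
    else:
        domains["I+II+III"] = (0, n)
        unresolved.extend(["I/II", "II/III"])
    return CRAnnotation(
        length=n, domains=domains, unresolved=unresolved, motif_hits=list(hits)
    )


def _best_hit(hits: list[MotifHit], name: str) -> MotifHit | None:
    named = [h for h in hits if h.name == name]
    return min(named, key=lambda h: (h.mismatches, h.start)) if named else None


def annotate_control_region(
    cr: str,
    library: list[MotifDef] | None = None,
    str_kwargs: dict | None = None,
    poly_base: str = "C",
    poly_min_len: int = 5,
    hairpin_kwargs: dict | None = None,
) -> CRAnnotation:
    """Full annotation bundle: motifs, domains, tracts, STRs and hairpins."""
    library = library if library is not None else load_motif_library()
    hits: list[MotifHit] = []
    for motif in library:
        found = find_motif(cr, motif.iupac, motif.max_mismatch, name=motif.name)
        if found:
            hits.append(found[0])  # best hit per element
    annotation = partition_domains(cr, hits)
    annotation.poly_tracts = find_poly_tract(cr, poly_base, poly_min_len)
    annotation.ta_islands = find_poly_tract(cr, mode="ta_island")
    annotation.str_arrays = find_str(cr, **(str_kwargs or {}))
    try:
        annotation.hairpins = find_hairpin(cr, **(hairpin_kwargs or {}))
    except ValueError:
        annotation.hairpins = []
    return annotation
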