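"""Synthetic avian mitogenomes with fully recorded planted truth.

The default genome carries the 37 genes of the ancestral avian order
plus a three-domain control region with planted conserved blocks, a
poly-C tract with a TA island, a tandem-repeat array (AACAAAC x 20 by
default), a GC-rich hairpin, polyadenylation-completed stop codons in
COX3/ND4/CYTB and a single-nucleotide frameshift insertion in ND3 —
the architecture reported for large New World vultures.  Every planted
element is verified post-generation and written to the truth record.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np

from ..cr_annotation import (
    annotate_control_region,
    find_hairpin,
    find_motif,
    find_poly_tract,
    find_str,
    load_motif_library,
)
from ..genome_io import (
    GeneFeature,
    Mitogenome,
    detect_frameshift,
    extract_gene,
    load_gene_table,
    reverse_complement,
)
from ..selection.code import sense_codons
from .codons import MITO_BASE_FREQS

NUCS = "ACGT"

#: AT-rich composition typical of the control region (A, C, G, T)
CR_BASE_FREQS = (0.30, 0.28, 0.13, 0.29)

#: sense-strand composition target for L-strand genes (C+G-rich sense)
L_SENSE_FREQS = (0.21, 0.30, 0.26, 0.23)


@dataclass
class CRLayout:
    domain1_len: int = 430
    domain2_len: int = 470
    domain3_len: int = 314
    poly_c_half: int = 6          # C-run length flanking the TA island
    ta_island: str = "TATA"
    str_unit: str = "AACAAAC"
    str_copies: int = 20
    hairpin_arm: str = "GGCAGCCGTG"  # GC-rich 5' arm; 3' arm is its revcomp
    hairpin_loop_len: int = 4

    @property
    def length(self) -> int:
        return self.domain1_len + self.domain2_len + self.domain3_len


@dataclass
class MitogenomeSpec:
    accession: str = "SYN000001"
    taxon: str = "synthetic condor-like vulture"
    seed: int = 0
    gene_lengths: dict = field(default_factory=dict)  # overrides
    comp_h: tuple = MITO_BASE_FREQS        # H-strand genes, sense == H
    comp_l_sense: tuple = L_SENSE_FREQS    # L-strand genes, sense strand
    comp_cr: tuple = CR_BASE_FREQS
    truncated_genes: tuple = ("COX3", "ND4", "CYTB")
    frameshift_gene: str | None = "ND3"
    frameshift_offset: int = 174           # nt offset of the inserted base
    codon_concentration: float | None = 60.0  # Dirichlet jitter on codon usage
    cr: CRLayout = field(default_factory=CRLayout)
    duplicate_pseudo_cr: bool = False      # emulate the OW-vulture rearrangement


def _random_seq(rng, length, freqs) -> str:
    return "".join(rng.choice(list(NUCS), size=length, p=freqs))


def _codon_weights(rng, freqs, concentration):
    """F3x4-flavored codon usage, optionally Dirichlet-jittered."""
    codons = sense_codons()
    base = {b: f for b, f in zip(NUCS, freqs)}
    w = np.array([base[c[0]] * base[c[1]] * base[c[2]] for c in codons])
    w /= w.sum()
    if concentration:
        w = rng.dirichlet(w * len(codons) * concentration)
    return np.asarray(w) / np.sum(w)


def _sample_cds(rng, length, weights, truncated: bool) -> tuple[str, Counter]:
    """ATG + sampled codons + TAA (or a TA truncated terminus)."""
    codons = sense_codons()
    if truncated:
        if length % 3 != 2:
            raise ValueError("truncated CDS length must be 2 mod 3")
        n_inner = (length - 2) // 3 - 1
        tail = "TA"
    else:
        if length % 3:
            raise ValueError("complete CDS length must be a multiple of 3")
        n_inner = length // 3 - 2
        tail = "TAA"
    idx = rng.choice(len(codons), size=n_inner, p=weights)
    counts = Counter()
    counts["ATG"] += 1
    inner = []
    for i in idx:
        inner.append(codons[i])
        counts[codons[i]] += 1
    return "ATG" + "".join(inner) + tail, counts


def _plant_frameshift(sense: str, requested: int) -> tuple[str, int, tuple]:
    """Insert one nucleotide so translational skipping recovers a unique offset.

    A lone insertion is never exactly recoverable: skipping one of the two
    codon positions before it always reopens the frame unless that skip
    creates a stop, and both cannot be stops at once.  Planting the codons
    TTA GAA around the insertion point and inserting an A makes (i) the
    naive frame stop immediately (AGA at the junction), (ii) every earlier
    skip hit a TAA junction stop, and (iii) the skip at the recorded
    offset restore the clean frame — so the earliest rescue equals the
    recorded offset deterministically.

    Returns (new_sense, offset, (codons_added, codons_removed)).
    """
    # snap to the last codon-final position at or before the request
    t = requested - ((requested - 2) % 3)
    if t < 5 or t + 6 > len(sense) - 3:
        raise ValueError("frameshift offset outside the usable CDS body")
    k = (t - 2) // 3  # codon index whose final base is t
    codons_removed = Counter([sense[3 * k : 3 * k + 3],
                              sense[3 * k + 3 : 3 * k + 6]])
    body = sense[: 3 * k] + "TTAGAA" + sense[3 * k + 6 :]
    planted = body[: t + 1] + "A" + body[t + 1 :]
    return planted, t, (Counter(["TTA", "GAA"]), codons_removed)


def _realize_iupac(rng, pattern: str) -> str:
    from ..cr_annotation import IUPAC

    return "".join(rng.choice(list(IUPAC[ch])) for ch in pattern)


def _build_cr(rng, layout: CRLayout, comp, library) -> tuple[str, dict]:
    """Assemble the control region; returns (sequence, element truth)."""
    by_name = {m.name: m for m in library}
    truth: dict = {}

    def pad(k):
        return _random_seq(rng, max(0, k), comp)

    # ---- domain I: pad, poly-C with TA island, ETAS1, pad to length ----
    etas1 = _realize_iupac(rng, by_name["ETAS1"].iupac)
    poly = "C" * layout.poly_c_half + layout.ta_island + "C" * layout.poly_c_half
    lead = layout.domain1_len - len(poly) - len(etas1) - 40
    lead_pad = pad(lead)
    if lead_pad.endswith("C"):  # keep the planted poly-C run maximal
        lead_pad = lead_pad[:-1] + "A"
    tail_pad = pad(layout.domain1_len - lead - len(poly) - len(etas1))
    d1 = lead_pad + poly + etas1 + tail_pad
    poly_start = lead
    truth["poly_c_runs"] = [
        [poly_start, poly_start + layout.poly_c_half],
        [
            poly_start + layout.poly_c_half + len(layout.ta_island),
            poly_start + len(poly),
        ],
    ]
    truth["ta_island"] = [
        poly_start + layout.poly_c_half,
        poly_start + layout.poly_c_half + len(layout.ta_island),
    ]
    truth["motifs"] = {"ETAS1": [poly_start + len(poly), poly_start + len(poly) + len(etas1)]}

    # ---- domain II: F at the boundary, then E, D, C, CSBa, CSBb, BirdBox ----
    order = ["F", "E", "D", "C", "CSBa", "CSBb", "BirdBox"]
    pieces = []
    pos = layout.domain1_len
    total_motif = sum(len(by_name[m].iupac) for m in order)
    gap = (layout.domain2_len - total_motif) // len(order)
    for m in order:
        realized = _realize_iupac(rng, by_name[m].iupac)
        pieces.append(realized)
        truth["motifs"][m] = [pos, pos + len(realized)]
        pos += len(realized)
        if m != order[-1]:
            pieces.append(pad(gap))
            pos += gap
    d2 = "".join(pieces)
    d2 += pad(layout.domain2_len - len(d2))

    # ---- domain III: CSB1 at the boundary, hairpin, STR array, tail ----
    csb1 = _realize_iupac(rng, by_name["CSB1"].iupac)
    pos = layout.domain1_len + layout.domain2_len
    truth["motifs"]["CSB1"] = [pos, pos + len(csb1)]
    arm = layout.hairpin_arm
    loop = pad(layout.hairpin_loop_len)
    hairpin = arm + loop + reverse_complement(arm)
    strs = layout.str_unit * layout.str_copies
    mid_gap = 25
    head = csb1 + pad(mid_gap) + hairpin + pad(mid_gap)
    hp_start = pos + len(csb1) + mid_gap
    truth["hairpin"] = {
        "stem_start_5p": hp_start,
        "stem_len": len(arm),
        "loop_len": layout.hairpin_loop_len,
        "stem_start_3p": hp_start + len(arm) + layout.hairpin_loop_len,
    }
    str_start = pos + len(head)
    truth["str"] = {
        "unit": layout.str_unit,
        "copies": layout.str_copies,
        "start": str_start,
        "end": str_start + len(strs),
    }
    tail_len = layout.domain3_len - len(head) - len(strs)
    if tail_len < 1:
        raise ValueError("domain III too short for its planted elements")
    tail = pad(tail_len)
    # the tail must not extend the repeat array
    while tail[: len(layout.str_unit)] == layout.str_unit or tail[0] == layout.str_unit[0]:
        tail = pad(tail_len)
    d3 = head + strs + tail
    cr = d1 + d2 + d3
    truth["domains"] = {
        "I": [0, layout.domain1_len],
        "II": [layout.domain1_len, layout.domain1_len + layout.domain2_len],
        "III": [layout.domain1_len + layout.domain2_len, layout.length],
    }
    return cr, truth


def simulate_mitogenome(spec: MitogenomeSpec | None = None) -> tuple[Mitogenome, dict]:
    """Generate a synthetic annotated mitogenome and its planted-truth record."""
    spec = spec or MitogenomeSpec()
    library = load_motif_library()
    for attempt in range(25):
        rng = np.random.default_rng((spec.seed, attempt))
        try:
            genome, truth = _generate_once(spec, rng, library)
            _validate(spec, genome, truth, library)
            truth["attempt"] = attempt
            return genome, truth
        except _PlantingCollision:
            continue
    raise RuntimeError("could not realize a genome satisfying all planted properties")


class _PlantingCollision(Exception):
    pass


def _generate_once(spec, rng, library):
    table = load_gene_table()
    lengths = {row["name"]: spec.gene_lengths.get(row["name"], row["length"]) for row in table}
    comp_h = np.asarray(spec.comp_h) / np.sum(spec.comp_h)
    comp_l = np.asarray(spec.comp_l_sense) / np.sum(spec.comp_l_sense)
    comp_cr = np.asarray(spec.comp_cr) / np.sum(spec.comp_cr)
    weights_h = _codon_weights(rng, comp_h, spec.codon_concentration)
    weights_l = _codon_weights(rng, comp_l, spec.codon_concentration)

    parts: list[str] = []
    features: list[GeneFeature] = []
    codon_counts: Counter = Counter()
    truth: dict = {
        "seed": spec.seed,
        "truncated_genes": list(spec.truncated_genes),
        "frameshift": None,
        "features": {},
    }
    pos = 0
    cr_start = None
    cr_truth = {}
    for row in table:
        name, kind, strand = row["name"], row["kind"], row["strand"]
        length = lengths[name]
        if kind == "PCG":
            truncated = name in spec.truncated_genes
            weights = weights_h if strand == "H" else weights_l
            sense, counts = _sample_cds(rng, length, weights, truncated)
            codon_counts.update(counts)
            if spec.frameshift_gene == name:
                sense, t_off, counts_fix = _plant_frameshift(
                    sense, spec.frameshift_offset
                )
                codon_counts.update(counts_fix[0])
                codon_counts.subtract(counts_fix[1])
                length += 1
                truth["frameshift"] = {
                    "gene": name,
                    "offset": t_off,
                    "requested_offset": spec.frameshift_offset,
                }
            seq = sense if strand == "H" else reverse_complement(sense)
        elif kind == "control_region":
            seq, cr_truth = _build_cr(rng, spec.cr, comp_cr, library)
            length = len(seq)
            cr_start = pos
        else:
            comp = comp_h if strand == "H" else comp_l
            sense = _random_seq(rng, length, comp)
            seq = sense if strand == "H" else reverse_complement(sense)
        features.append(GeneFeature(name, kind, pos, pos + length, strand))
        truth["features"][name] = [pos, pos + length, strand]
        parts.append(seq)
        pos += length

    if spec.duplicate_pseudo_cr:
        # degenerate second control region after trnT, as in OW vultures
        pseudo = _random_seq(rng, 300, comp_cr)
        idx = next(i for i, f in enumerate(features) if f.name == "trnT")
        insert_at = features[idx].end
        parts.insert(idx + 1, pseudo)
        shifted = []
        for f in features:
            if f.start >= insert_at:
                shifted.append(
                    GeneFeature(f.name, f.kind, f.start + 300, f.end + 300, f.strand)
                )
            else:
                shifted.append(f)
        features = shifted
        features.append(
            GeneFeature("pseudo_CR", "other", insert_at, insert_at + 300, "H")
        )
        if cr_start is not None and cr_start >= insert_at:
            cr_start += 300
        truth["pseudo_cr"] = [insert_at, insert_at + 300]

    genome = Mitogenome(
        id=spec.accession,
        sequence="".join(parts),
        circular=True,
        features=features,
        source_taxon=spec.taxon,
    )
    truth["cr_start"] = cr_start
    truth["cr"] = {
        k: v for k, v in cr_truth.items()
    }
    truth["codon_counts"] = dict(codon_counts)
    truth["layout"] = asdict(spec.cr)
    return genome, truth


def _validate(spec, genome, truth, library):
    """Check every planted property; raise _PlantingCollision to retry."""
    cr = extract_gene(genome, "CR")
    by_name = {m.name: m for m in library}
    for name, (s, e) in truth["cr"]["motifs"].items():
        motif = by_name[name]
        hits = find_motif(cr, motif.iupac, motif.max_mismatch, name=name)
        if not hits or hits[0].start != s:
            raise _PlantingCollision(f"motif {name} not recovered at {s}")
    annotation = annotate_control_region(cr)
    if annotation.domains.get("I") != tuple(truth["cr"]["domains"]["I"]):
        raise _PlantingCollision("domain I boundary shifted")
    if annotation.domains.get("III") != tuple(truth["cr"]["domains"]["III"]):
        raise _PlantingCollision("domain III boundary shifted")
    planted = truth["cr"]["str"]
    arrays = find_str(cr)
    ok = any(
        a.start == planted["start"]
        and a.copies == planted["copies"]
        and a.unit_as_found == planted["unit"]
        for a in arrays
    )
    if not ok:
        raise _PlantingCollision("STR array not recovered as planted")
    hp = truth["cr"]["hairpin"]
    hairpins = find_hairpin(cr, min_stem=6)
    if not any(
        h.stem_start_5p <= hp["stem_start_5p"]
        and h.stem_start_5p + h.stem_len >= hp["stem_start_5p"] + hp["stem_len"]
        for h in hairpins
    ):
        raise _PlantingCollision("hairpin not recovered")
    runs = find_poly_tract(cr, "C", min_len=spec.cr.poly_c_half)
    spans = {(r.start, r.end) for r in runs}
    if not all(tuple(r) in spans for r in truth["cr"]["poly_c_runs"]):
        raise _PlantingCollision("poly-C runs not recovered")
    if spec.frameshift_gene:
        report = detect_frameshift(extract_gene(genome, spec.frameshift_gene))
        if not report.detected or report.skip_position != truth["frameshift"]["offset"]:
            raise _PlantingCollision("frameshift not recovered at planted offset")


def mutate_genome(
    genome: Mitogenome, n_substitutions: int, seed: int = 0, new_id: str | None = None
) -> tuple[Mitogenome, list[int]]:
    """Point-mutated copy for divergence tests; returns (copy, positions).

    Substitutions are uniform over the sequence and may disrupt reading
    frames — intended for identity/entropy analyses, not translation.
    """
    rng = np.random.default_rng(seed)
    seq = list(genome.sequence)
    positions = sorted(
        rng.choice(len(seq), size=n_substitutions, replace=False).tolist()
    )
    for p in positions:
        alternatives = [b for b in NUCS if b != seq[p]]
        seq[p] = alternatives[rng.integers(3)]
    copy = Mitogenome(
        id=new_id or f"{genome.id}_mut{n_substitutions}",
        sequence="".join(seq),
        circular=genome.circular,
        features=[GeneFeature(f.name, f.kind, f.start, f.end, f.strand, f.notes)
                  for f in genome.features],
        source_taxon=genome.source_taxon,
    )
    return copy, positions
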