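"""Characterize an annotated mitogenome: composition, codon usage, exceptions.

Builds a synthetic condor-like mitogenome (37 genes + control region in
the ancestral avian order) and runs the characterization stack on it.
"""

from mitosel import comp_stats, genome_io
from mitosel.simulate.genomes import MitogenomeSpec, simulate_mitogenome

genome, truth = simulate_mitogenome(MitogenomeSpec(seed=1))
print(f"genome {genome.id}: {len(genome.sequence)} bp, "
      f"{len(genome.features)} features")

profile = comp_stats.base_composition(genome.sequence)
print("base composition (H strand):",
      {b: round(f, 3) for b, f in profile.frequencies.items()})
print(f"AT skew {profile.at_skew:+.3f}, GC skew {profile.gc_skew:+.3f}")
# Negative GC skew = C over G on the heavy strand, the usual avian pattern.

nd6 = comp_stats.base_composition(genome_io.extract_gene(genome, "ND6"))
print(f"ND6 sense-strand G+C {nd6.gc_fraction:.3f} vs genome "
      f"{profile.gc_fraction:.3f}  (the one L-strand PCG is G+C biased)")

print("\nstop-codon status (truncated stops are completed by polyadenylation):")
for gene in ("COX1", "COX3", "ND4", "CYTB"):
    status = genome_io.detect_incomplete_stop(genome, gene)
    print(f"  {gene:5s} {status.status:13s} terminal={status.terminal_codon}")

report = genome_io.detect_frameshift(genome_io.extract_gene(genome, "ND3"))
print(f"\nND3 frameshift: detected={report.detected}, "
      f"skip position {report.skip_position} nt "
      f"(one inserted nucleotide is bypassed during translation)")

signature = genome_io.gene_order_signature(genome)
print("ancestral avian gene order:", genome_io.matches_ancestral(signature))

pcgs = [f.name for f in genome.features if f.kind == "PCG"]
frames = []
for gene in pcgs:
    cds = genome_io.extract_gene(genome, gene)
    rep = genome_io.detect_frameshift(cds)
    if rep.detected:
        cds = cds[: rep.skip_position] + cds[rep.skip_position + 1 :]
    frames.append(cds[: len(cds) - len(cds) % 3])
table = comp_stats.rscu(frames)
print("most-used codons by RSCU:", ", ".join(table.top_codons(7)))
usage = comp_stats.amino_acid_usage(frames, completion="polyA")
top_aa = sorted(usage, key=usage.get, reverse=True)[:7]
print("most frequent amino acids:", ", ".join(top_aa))
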