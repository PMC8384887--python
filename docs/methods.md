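# Methods

## Codon substitution model

The selection engine works on the 60 sense codons of the vertebrate
mitochondrial code (NCBI table 2: `TAA/TAG/AGA/AGG` are stops, `ATA` is
Met, `TGA` is Trp). The instantaneous rate of change between codons
differing at exactly one position is

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

and zero otherwise (multi-nucleotide changes and changes into stop
codons). Each Q is scaled so one unit of branch length equals one
expected substitution per codon site *under that Q*; in mixture models
every site class therefore shares the branch-length scale. This
per-matrix scaling convention is applied identically in simulation and
inference, so parameters are self-consistent; it differs from tools that
scale by the mixture-average rate, which affects only the
interpretation of branch lengths, not likelihood ratios.

Codon frequencies default to F3x4 — position-specific nucleotide
frequencies multiplied per codon, stop codons zeroed and the sense set
renormalized. Unobserved codons are floored at 1e-8 so the reversible
spectral decomposition (symmetrize Q with D = diag(sqrt(pi)), then
`exp(Qt)` by eigendecomposition, with a scaling-and-squaring fallback)
stays defined.

Likelihoods use Felsenstein pruning over pattern-compressed site columns
with per-pattern rescaling; mixture models marginalize site classes at
the root. Every branch/clade/branch-site structure is expressed as an
index matrix `omega_idx[branch, class]` into a vector of distinct omega
values, so all models share one code path. Codon columns containing gaps
or ambiguity map to a uniform tip partial (missing data).

## Models and tests

- **M0**: one omega. **free-ratios**: one omega per branch. **branch**:
  one omega per labeled branch group.
- **M2a_rel**: site classes (omega0 <= 1, 1, omega2) with free
  proportions. **Clade model C**: identical, except the third class has
  a separate omega2 per clade. Their LRT (df = number of extra omega2
  parameters) is the clade-divergence test; relaxation appears as a
  target-clade omega2 approaching 1.
- **Branch-site model A**: classes (omega0, 1, 2a, 2b) with omega2 >= 1
  on the foreground; the null fixes omega2 = 1. Significance uses
  chi-square with df 1, the conservative choice relative to the 50:50
  boundary mixture.

Optimization is bounded L-BFGS-B on transformed coordinates (log kappa
and omegas, stick-breaking logits for proportions; omega in [1e-4, 50],
kappa in [0.1, 99], convergence |dlnL| below ~1e-6). `fit_model`
defaults to a deterministic start plus four seeded random restarts;
`nested_lrt` fits a null/alternative pair with one start each plus three
guards against local optima: the alternative starts from the fitted
null (so lnL_alt >= lnL_null by construction), the null is re-fit from
the alternative's projection and the better null kept, and callers may
supply warm starts (simulation studies chain each replicate from the
previous solution). Branch lengths are fixed to the input tree; the
likelihood is invariant to re-rooting for these reversible models.

Nei–Gojobori (1986) counting — equal-weight pathway averaging with
pathways through stops skipped, Jukes–Cantor correction, omega reported
as undefined (not infinite) when dS = 0 — is implemented independently
of the ML engine and serves as its cross-check. Note that NG86 pathway
averaging can attribute fractional nonsynonymous differences to codon
pairs that diverged through purely synonymous events; tests of the
omega = 0 regime therefore check protein identity, not NG86 counts.

## Comparative statistics

Skews are (A-T)/(A+T) and (G-C)/(G+C), computed on the deposited heavy
strand at genome scope and on the sense strand at gene scope — this is
what makes ND6, the lone L-strand protein gene, stand out as C+G biased.
RSCU is observed count over the uniform-usage expectation within each
synonymous family; within every used family mean RSCU is exactly 1.
Percent identity uses pair deletion (columns with a gap in either
sequence excluded), which stabilizes values across indel-rich control
regions; the affine-gap aligner defaults to match/mismatch/open/extend =
1/-1/-5/-1 (a length-k gap costs open + (k-1)*extend). Entropy profiles
use Shannon entropy in bits per column over non-gap residues (columns
with fewer than two residues carry 0), averaged in 50-bp windows, step
1, reported at window centers.

## Control-region annotation

Element consensi are configuration, not code: a TSV of IUPAC strings
with per-motif mismatch allowances, shipped as editable approximations
of the avian control-region literature (the set includes ETAS2, CSB2 and
CSB3 so their absence is a reportable result, as in vulture CRs).
Domains follow the standard rule: domain I from the CR start to the F
box, domain II from the F box to CSB1, domain III from CSB1 to the end;
a missing anchor leaves that boundary explicitly unresolved. STR
detection enumerates maximal periodic runs for unit lengths 2–10 and
resolves overlaps by longer span, then smaller unit; each array is
reported once at its canonical unit length (the fundamental period, or
its smallest admissible multiple for homopolymer-period runs), with full
copies and the partial remainder separated — a flag can count a >=50%
partial as a copy, since published repeat counts sometimes do. Hairpins
are maximal perfect inverted repeats (loop 3–30 nt, G:C scored 3 and A:T
2), selected greedily by score; no thermodynamic folding is attempted —
the claim supported is structural plausibility, not stability.

## Synthetic data: what it emulates and what it does not

The mitogenome generator reproduces the architecture of a large New
World vulture mitogenome: 37 genes + CR in the chicken-like ancestral
avian order; strand-specific composition (H-strand targets A 31%,
C 32%, G 13%, T 24%; L-strand sense targets C+G-rich); truncated
TA stops in COX3/ND4/CYTB flush against the downstream feature; a
single-nucleotide insertion in ND3; and a control region with planted
elements, including an `(AACAAAC) x 20` repeat array (the condor-like
value; copy number is configurable), a TA island inside the poly-C
tract, and a GC-rich hairpin. An optional pseudo-control-region
duplication emulates the rearranged Old World vulture order. Every
planted feature is re-detected post-generation and written to a truth
record; generation retries with a derived seed on the rare random
collision.

The frameshift plant is engineered, not random: a lone random insertion
is never exactly recoverable, because skipping one of the two codon
positions before it always reopens the frame unless that skip creates a
stop, and both positions cannot create stops at once. The generator
therefore writes the codons `TTA GAA` around the insertion point and
inserts an `A`, which (i) makes the naive frame stop immediately at the
junction (`AGA`), (ii) makes every earlier skip hit a `TAA` junction
stop, and (iii) makes the recorded offset the earliest rescuing skip,
deterministically. Requested offsets are snapped to the nearest
codon-final position.

Codon alignments evolve by drawing the root from pi and each child state
from `exp(Q t)` along its branch, with site classes drawn per site;
stop codons cannot arise because Q carries no rate into them.
Haplotype sets mutate a reference CR with per-domain rates or exact
per-domain segregating-site counts.

What the generators do **not** emulate: sequencing error, indel
evolution within codon alignments, heteroplasmy, gene overlap (real
avian ATP8/ATP6 and ND4L/ND4 overlap; synthetic features are
contiguous), tRNA secondary structure, and among-site rate variation
beyond the omega mixture. Tests passing on these data show the
algorithms recover what was planted under the stated model; they do not
validate annotation of diverged real-world records.

## Simulation-study conditions

The standard verification studies (in `mitosel.studies`, shared by the
test suite and `scripts/acceptance.py`) use balanced two-clade trees
with 0.2 substitutions/codon on tips and 0.1 on internal branches, and
a mixture of 50% strongly purifying sites (omega0 = 0.05), 20% neutral
sites and 30% divergent-class sites — values typical of mitochondrial
protein genes. Parameter recovery under M0 uses 8 taxa, 500 codons,
omega = 0.2, kappa = 2, 20 replicates. The power study uses 8 taxa and
800 codons with divergent-class omega2 of 0.3 (background) versus 1.0
(target) over 50 replicates. The type-I study simulates 200 null genes
of 300 codons (M2a_rel with omega2 = 0.3, the background value) on the
12-taxon version of the tree: at eight taxa the mixture is weakly
identified at this length and the LRT runs measurably hot (empirical
size ~0.10–0.15), while at twelve taxa — comparable to the number of
taxa a real clade-model analysis of raptors would include — the
chi-square(1) approximation holds. This size sensitivity is a known
finite-sample property of clade-model LRTs and is worth checking by
simulation for any new dataset shape.

The pruning-oracle study compares the engine against brute-force
enumeration over all internal-state assignments on 200 random instances
of 3–4 taxa (trifurcating roots keep enumeration at <= 2 internal
nodes) and 1–3 codons, with random mixture structures.

## Known limitations

- Branch lengths are fixed to the input tree (joint estimation is out
  of scope); results inherit whatever error those lengths carry.
- F3x4 is a plug-in estimate, as in common practice; its sampling noise
  is not propagated.
- The clade-model LRT should be interpreted against the simulation
  evidence above for small trees or short genes.
- Clade-specific omega2 *point estimates* carry substantial variance:
  the divergent-class omega trades off against its proportion, and an
  omega2 near 1 is partially confounded with the neutral class on its
  own clade (20-replicate medians of |error| at 800 codons/12 taxa:
  ~0.05 for a clade at omega2 = 0.2, ~0.23 for a clade at omega2 = 0.7).
  Hypothesis tests (the LRT) are the reliable readout; treat fitted
  omega2 values as indicative.
- The control-region motif library is a working approximation;
  real-data studies should curate consensi for their clade.
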