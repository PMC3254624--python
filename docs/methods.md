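# Methods

This note documents the models, parameter choices and numerical decisions
behind `paraspec`, and what the synthetic fixtures do and do not establish.

## Coordinates and sequence conventions

All user-facing coordinates are 1-based inclusive on the forward strand of
the supplied FASTA (the NCBI/dbSNP convention); BED export is 0-based
half-open, with the inverted copy written on the "−" strand. Internally,
0-based half-open indices are used. SNP positions are required to be on the
forward strand of the supplied sequence; the toolkit does not guess strand.
Lower-case input is upper-cased with no soft-masking semantics. FASTA is
written wrapped at 60 columns. SNP lists are accepted as TSV
(id, position, ref, alt, ancestral, ancestral_source) or as a minimal
VCF 4.x file from which only CHROM/POS/ID/REF/ALT are read. Ancestral
alleles are taken from the input annotation only (with a provenance tag:
database vs primate-outgroup alignment); the toolkit never infers ancestral
state itself.

## Inverted-duplication detection

An inverted duplication is found by comparing the sequence `S` to its own
reverse complement `R`: a pair of intervals, one per strand, where one copy
matches the reverse complement of the other.

Pipeline: exact k-mer seeds between `S` and `R` (default `seed_k = 15`;
k-mers occurring more than 16 times are skipped as repetitive), clustering
of seed hits by diagonal (tolerance 25 columns, maximum seed gap 300 bp),
ungapped X-drop extension of each cluster to the block boundaries
(match +1, mismatch −3, termination when the score falls 25 below its
running maximum; the extension is trimmed back to the maximum-scoring
point), then an affine-gap global alignment of the two candidate copies to
obtain the block alignment and identity. Full quadratic alignment of the
whole input is never attempted; copies longer than 1.5 kb are aligned in a
band around the main diagonal (band = length difference + 50).

Three cleanups follow:

* **End trimming.** Seed extension can overrun a boundary into flanking
  sequence that partially matches by chance. Alignment ends are trimmed to
  the maximum-scoring column segment (match +1, mismatch/gap −2), which
  removes overhangs below ~⅓ identity while never touching the interior.
  If the result still falls below the identity threshold, end mismatch
  runs are shaved greedily (from whichever end costs fewer columns) until
  the threshold is met or the block would fall under the minimum length.
* **Palindrome filter.** Self-versus-reverse-complement comparison
  necessarily reports fold-back (hairpin) matches; candidates whose two
  projected intervals overlap by more than 50% of the shorter one are
  discarded.
* **Canonical reporting.** Every physical duplication appears twice in a
  self-comparison (A→B and B→A); only the representation with
  `copy_a.start < copy_b.start` is kept, and blocks whose intervals
  overlap a better block by ≥50% on both copies are dropped. Adjacent
  blocks separated by <100 bp on both copies are merged and re-aligned.

Defaults: minimum identity 90%, minimum block length 300 bp — chosen so
that kb-scale blocks in the mid-90s identity range (the regime of the
IL28A/IL28B pair) are detected with margin.

**Identity definition.** Percent identity is matches / alignment columns,
with gap columns counted in the denominator. This definition is applied
uniformly (block identity, sliding-window profiles, SNP context windows)
so that reported identities are reproducible from the alignment alone.

**Measured accuracy.** On substitution-only planted duplications
(identity 90–99%, 1 kb blocks), recall in the test-suite sweeps is 100%
with boundary error typically under 10 bp. At 90% identity the flanking
sequence occasionally extends the maximum-scoring region past the planted
boundary by ~20 bp (chance matches at better than block identity); no
sequence-based criterion can exclude such overhangs, and they are reported
as part of the block.

## Pairwise alignment

`align_global` is an affine-gap Needleman–Wunsch/Gotoh implementation: a
gap of length L costs `gap_open + L·gap_extend` (defaults +2/−3/−5/−2 for
match/mismatch/open/extend). All three state matrices allow transitions
from all predecessors, so the optimum equals exhaustive enumeration over
every alignment, including adjacent opposite-strand gaps (the test suite
checks this against a brute-force enumerator for all length combinations
up to 6). The traceback tie-break is fixed — diagonal over up (gap in the
second sequence) over left — making output deterministic.

## SNP classification

A SNP is **shared** iff its position falls inside either copy of a
detected block, otherwise **unique**. The toolkit is copy-agnostic: a
query inside copy_b is classified shared with its partner reported in
copy_a, and the report records which copy hosts the query. The partner
base is read in the query's orientation (complemented for inverted
blocks), so it is directly comparable with the SNP's alleles;
`allele_matching_paralogue` is whichever allele equals it (None if
neither, or if the partner column is a gap). Columns where the block
alignment itself is ambiguous (equal-scoring alternatives) are resolved by
the deterministic tie-break above; only that alignment's mapping is
reported.

The context window is ±25 bases around the SNP on its host copy (a
51-column window — the natural symmetric reading of a "50 bp surrounding
sequence"); gap columns count as mismatches, and windows reaching past the
block are truncated and flagged.

## Primer thermodynamics and specificity

Melting temperatures use the unified nearest-neighbor parameter set of
Allawi & SantaLucia (1997) with duplex-initiation terms per terminal base
pair, the entropic salt correction ΔS += 0.368·(N−1)·ln[mon⁺], and
Tm = ΔH / (ΔS + R·ln C_T) − 273.15 with C_T the excess strand
concentration. Defaults: 50 mM monovalent cation, 0.25 µM per strand. The
parameter table is frozen in `primertools.NN_PARAMS`; the test suite
cross-checks against an independent implementation of the same published
table (Biopython's) to within 0.5 °C. The model is deliberately simple and
documented rather than a clone of any proprietary design tool.

Primer binding is modelled ungapped within the footprint; mismatch counts
are per-column 5′→3′, a partner deletion (gap column) counts as a
mismatch, and partner insertions are dropped from the site string
(consistent with the ungapped model — indel mispriming inside a ≤30-mer is
out of scope). The specificity report carries the total mismatch count,
the 3′-terminal flag, and the count over the final five columns, in that
order of importance for blocking extension on the wrong template.

In-silico PCR scans both strands for footprints within a mismatch budget
(optionally requiring a matched 3′ base), pairs every convergent site
combination within the product-size cap, measures product length 5′ end of
the forward site through 5′ end of the reverse site inclusive, and marks
the assay `specific` iff exactly one product exists across all templates.

**Design ranking** (descending priority): total paralogue mismatches over
the pair; number of primers with a 3′-terminal mismatch; mismatches in the
final five columns; combined distance of the two Tm values from the
Tm-range midpoint; shorter product; then coordinates for determinism.
Constraint violations (Tm 58–62 °C, length 15–30 nt, product 80–300 bp,
GC 30–70%, homopolymer runs ≤4) are *flagged* on the candidate rather than
fatal — mirroring assay practice where specificity against the paralogue
outranks textbook parameters — and an all-zero-mismatch candidate list
triggers an explicit "no specificity achievable" warning. Pairing takes
each top-ranked candidate on one side and the best-ranked partner whose
product fits; every returned product covers the target position.

## Genotype statistics

* Allele frequency = allele count / (2 × non-missing samples), per
  population; full precision internally, 2-decimal display rounding in
  table output. A site is polymorphic iff ≥2 distinct alleles are observed.
* Consensus variant calling assumes colinear, substitution-only alignment
  of consensus to reference (the assembly pipeline it models produces no
  indels); a two-base IUPAC code in the consensus becomes a heterozygote
  whose alt is the non-reference base.
* Concordance counts exact unordered diploid genotype equality
  (C/T ≡ T/C); pairs with a missing call on either side are excluded from
  *n* rather than counted discordant.
* The lower confidence limit after *s* successes in *n* trials is the
  (1−*c*) quantile of Beta(*s*+1, *n*−*s*+1) — the posterior under a
  uniform prior, equivalently the one-sided exact (Clopper–Pearson-style)
  bound. It is computed with scipy's regularized-incomplete-beta quantile
  and validated in the tests against the closed form (1−c)^(1/(n+1)) at
  s = n (agreement < 1e−8 over n ≤ 100) and against direct quadrature of
  the density for small n.
* Random-match probability multiplies Hardy–Weinberg genotype frequencies
  (2pq het, p² hom) across markers, assuming marker independence. Linkage
  disequilibrium is not modelled; supplied r² caveats are echoed verbatim
  in the report so the independence assumption stays visible.

## Synthetic data: what it emulates and what it does not

`simulate_inverted_duplication` places a uniform-random i.i.d. ACGT
background, a forward copy, and its reverse complement mutated to the
requested identity by uniformly placed substitutions (optional indels at a
stated rate), after a spacer — mirroring the studied locus geometry. The
defaults are the study conditions: kb-scale blocks, mid-90s percent
identity, 6 shared + 3 unique planted SNPs, three 16-sample populations
for genotype panels. Shared SNPs are planted ≥30 bp inside the copy with
their true partner base recorded; substitution-only mode keeps the
coordinate map exactly computable, which is what makes truth labels exact.

What passing on synthetic data does *not* show: real genomes are not
i.i.d. — low-complexity tracts, tandem repeats and additional homologous
copies can create spurious seeds and binding sites that these fixtures do
not contain; GC structure and real mutation spectra are absent; and the
bundled "TaqMan locus" and 48-sample genotype panel are deterministic
synthetic stand-ins that reproduce the published footprints, mismatch
pattern and aggregate counts exactly, not the real chromosome-19 sequence
or the real per-sample genotypes (which are not bundled). Checks that need
the real build-37 slice (the published amplicon on the genuine template,
the genuine 97.5% gene identity) accept a user-supplied FASTA through the
same interfaces.

## Problem sizes

The test suite and the results script run on 5 kb sequences with 1 kb
planted blocks (20-fixture sweeps over 90–99% identity), brute-force
oracle comparisons on all sequence pairs up to length 6 and on 50 random
1–2 kb templates, and exact checks of the Beta bounds over n ≤ 100 — sizes
chosen so every property is checked exhaustively where enumeration is
feasible and statistically where it is not.

## Known limitations

Two-copy duplications only (no >2-copy repeat families, no genome-scale
all-vs-all scans); no secondary-structure/dimer thermodynamics or
multiplex design; no haplotype phasing, Hardy–Weinberg testing or
association analysis; Sanger chromatogram processing is upstream of the
toolkit, which starts from consensus sequences.
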