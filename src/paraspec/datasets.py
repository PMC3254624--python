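"""Bundled example data for the IL28A/IL28B assay-validation workflow.

Two kinds of objects live here:

* Published inputs — the amplifying primer sets, the TaqMan rs12979860
  primer/probe sequences (with the annotated paralogue-specificity
  positions), and the per-population allele-frequency tables for the nine
  treatment-response SNPs. These are printed reagent sequences and summary
  statistics, usable as inputs to the toolkit.

* Synthetic stand-ins — a deterministic 48-sample genotype panel
  reconstructed to be consistent with every published summary constraint
  (population allele frequencies, the 9/8/7 genotype composition of the
  24-sample commercial-assay subset, the single discordant sample NA18502
  called C/T by sequencing but T/T by the commercial assay, and full
  TaqMan/sequencing concordance), and a synthetic genomic locus carrying
  the TaqMan primer annealing sites with their documented paralogue
  mismatch pattern. The per-sample genotypes and the genomic sequence are
  NOT the real ones (which are not bundled); they are constructions that
  reproduce the published aggregate behaviour exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genostats import GenotypeCall, GenotypePanel
from .primertools import Primer
from .seqio import NucleotideSequence, SnpRecord, reverse_complement

RS12979860 = "rs12979860"

# ---------------------------------------------------------------------------
# published TaqMan assay components (rs12979860)

#: TaqMan amplification primers; `specificity_positions` are the annotated
#: 1-based 5'->3' positions that differ from the paralogous IL28A site
#: (the forward primer's include its 3'-terminal base).
TAQMAN_FORWARD = Primer(name="taqman_fwd", sequence="TTGCGCTGCCCCCAG", intended_strand="forward")
TAQMAN_FORWARD_SPECIFICITY_POSITIONS = (7, 8, 11, 15)
TAQMAN_REVERSE = Primer(name="taqman_rev", sequence="GGAGCGCGGAGTGCAA", intended_strand="reverse")
TAQMAN_REVERSE_SPECIFICITY_POSITIONS = (5, 10, 11)
#: Allele-specific detection probes; the T-allele probe carries the VIC
#: label, the C-allele probe the FAM label.
TAQMAN_PROBE_VIC = Primer(name="probe_VIC", sequence="TCCCCGAAGGCGTGA")
TAQMAN_PROBE_FAM = Primer(name="probe_FAM", sequence="CGAAGGCGCGAAC")
TAQMAN_PRODUCT_BP = 214

#: Published amplifying primer sets for sequencing the two loci:
#: (target gene, fragment size bp, SNPs covered, primer pair 5'->3').
AMPLIFYING_PRIMER_SETS: tuple[dict, ...] = (
    {"target": "IL28B", "size_bp": 1697, "snps": ("rs12980275", "rs8105790"),
     "primers": ("AGCAAGAGGAGGGAAGGAAG", "CCCTGGATAAGCCCCTACAG")},
    {"target": "IL28B", "size_bp": 1115, "snps": ("rs11881222", "rs8103142"),
     "primers": ("TGGGTGTCTTTTCCTCATTG", "CCTCCAATCCCATCAGAG")},
    {"target": "IL28B", "size_bp": 919, "snps": ("rs28416813", "rs4803219"),
     "primers": ("TGACCCTTGGAGTGCGGG", "ATATGCCAGGAGTGGTGG")},
    {"target": "IL28B", "size_bp": 593, "snps": (RS12979860,),
     "primers": ("CCAGCAGCTCCAGGATCG", "GCAGGCGCCTCTCCTATG")},
    {"target": "IL28B", "size_bp": 1291, "snps": ("rs8099917", "rs7248668"),
     "primers": ("TCACCATCCTCCTCTCATCC", "GCACCCAAAGCCTAACCATA")},
    {"target": "IL28A", "size_bp": 476, "snps": (RS12979860,),
     "primers": ("ACACACCCGTCGCTGACC", "CTCTCCCGTCCGCTTCTG")},
    {"target": "IL28A", "size_bp": 2500,
     "snps": ("rs11881222", "rs8103142", "rs28416813", "rs4803219"),
     "primers": ("GCCAATTGGTGAACTGTCAT", "CCCAGCTCATCAAGTGTGTCT")},
    {"target": "IL28A", "size_bp": 990, "snps": ("rs8105790",),
     "primers": ("CCACAAATGAGGGGGACA", "TGGCCAGCTGGTTCTTCTAC")},
)

# ---------------------------------------------------------------------------
# published allele-frequency tables (48-sample Coriell panel, 16 per population)

#: SNPs unique to the IL28B region: allele pair and per-population
#: frequency pairs as printed (2-decimal display).
UNIQUE_SNP_FREQUENCIES: dict[str, dict] = {
    "rs12980275": {"alleles": ("A", "G"),
                   "CEU": (0.56, 0.44), "JPT": (0.91, 0.09), "YRI": (0.47, 0.53)},
    "rs8099917": {"alleles": ("T", "G"),
                  "CEU": (0.75, 0.25), "JPT": (0.91, 0.09), "YRI": (0.97, 0.03)},
    "rs7248668": {"alleles": ("G", "A"),
                  "CEU": (0.75, 0.25), "JPT": (0.91, 0.09), "YRI": (0.97, 0.03)},
}

#: SNPs shared between the IL28B region and the corresponding IL28A region.
SHARED_SNP_FREQUENCIES: dict[str, dict] = {
    "rs8105790": {"alleles": ("T", "C"),
                  "CEU": (0.75, 0.25), "JPT": (0.91, 0.09), "YRI": (0.78, 0.22)},
    "rs11881222": {"alleles": ("A", "G"),
                   "CEU": (0.59, 0.41), "JPT": (0.91, 0.09), "YRI": (0.69, 0.31)},
    "rs8103142": {"alleles": ("T", "C"),
                  "CEU": (0.56, 0.44), "JPT": (0.91, 0.09), "YRI": (0.31, 0.69)},
    "rs28416813": {"alleles": ("C", "G"),
                   "CEU": (0.63, 0.37), "JPT": (0.91, 0.09), "YRI": (0.34, 0.66)},
    "rs4803219": {"alleles": ("C", "T"),
                  "CEU": (0.66, 0.34), "JPT": (0.91, 0.09), "YRI": (0.66, 0.34)},
    RS12979860: {"alleles": ("C", "T"),
                 "CEU": (0.53, 0.47), "JPT": (0.91, 0.09), "YRI": (0.34, 0.66)},
}


def published_frequencies() -> dict[str, dict[str, dict[str, float]]]:
    """All nine SNPs as `freqs[snp][population][allele]` (simulation-ready)."""
    out: dict[str, dict[str, dict[str, float]]] = {}
    for table in (UNIQUE_SNP_FREQUENCIES, SHARED_SNP_FREQUENCIES):
        for snp_id, row in table.items():
            a1, a2 = row["alleles"]
            out[snp_id] = {
                pop: {a1: row[pop][0], a2: row[pop][1]}
                for pop in ("CEU", "JPT", "YRI")
            }
    return out


# ---------------------------------------------------------------------------
# synthetic 48-sample rs12979860 panel (stand-in; see module docstring)

#: Per-population genotype counts (CC, CT, TT) chosen so the allele counts
#: reproduce the printed 2-decimal frequencies over 32 chromosomes:
#: CEU 17C/15T -> 0.53/0.47, JPT 29C/3T -> 0.91/0.09, YRI 11C/21T -> 0.34/0.66.
_PANEL_GENOTYPE_COUNTS = {
    "CEU": {("C", "C"): 5, ("C", "T"): 7, ("T", "T"): 4},
    "JPT": {("C", "C"): 13, ("C", "T"): 3, ("T", "T"): 0},
    "YRI": {("C", "C"): 3, ("C", "T"): 5, ("T", "T"): 8},
}

#: The sample with the published discordant commercial-assay call.
DISCORDANT_SAMPLE = "NA18502"


@dataclass
class Rs12979860Study:
    """Synthetic reconstruction of the rs12979860 validation study calls."""

    panel: GenotypePanel                 # sequencing-derived genotypes
    sequencing_calls: list[GenotypeCall]
    taqman_calls: list[GenotypeCall]     # identical to sequencing (48/48)
    commercial_calls: list[GenotypeCall]  # 24-sample subset; NA18502 -> T/T
    subset_samples: list[str] = field(default_factory=list)


def synthetic_rs12979860_panel() -> Rs12979860Study:
    """Deterministic synthetic stand-in for the 48-sample validation panel.

    Sample genotypes are assigned (not drawn) so that every published
    aggregate is reproduced exactly: population allele frequencies, the
    9 CC / 8 CT / 7 TT composition of the 24-sample commercial subset, one
    discordant sample (NA18502, C/T by sequencing and TaqMan, T/T by the
    commercial assay) and full TaqMan concordance.
    """
    panel = GenotypePanel()
    sequencing: list[GenotypeCall] = []
    by_genotype: dict[tuple[str, str], list[str]] = {}
    for pop, counts in _PANEL_GENOTYPE_COUNTS.items():
        idx = 0
        for genotype, n in counts.items():
            for _ in range(n):
                idx += 1
                sample = f"SYN_{pop}_{idx:02d}"
                if pop == "YRI" and genotype == ("C", "T") and DISCORDANT_SAMPLE not in by_genotype.get(genotype, []):
                    sample = DISCORDANT_SAMPLE
                call = GenotypeCall(sample_id=sample, snp_id=RS12979860, alleles=genotype)
                panel.add(call, population=pop)
                sequencing.append(call)
                by_genotype.setdefault(genotype, []).append(sample)

    taqman = [
        GenotypeCall(sample_id=c.sample_id, snp_id=RS12979860, alleles=c.alleles)
        for c in sequencing
    ]

    # 24-sample commercial subset: 9 CC, 8 CT (including NA18502), 7 TT
    cc = by_genotype[("C", "C")][:9]
    ct = [DISCORDANT_SAMPLE] + [
        s for s in by_genotype[("C", "T")] if s != DISCORDANT_SAMPLE
    ][:7]
    tt = by_genotype[("T", "T")][:7]
    subset = cc + ct + tt
    commercial = [
        GenotypeCall(
            sample_id=s,
            snp_id=RS12979860,
            alleles=("T", "T") if s == DISCORDANT_SAMPLE else panel.calls[(s, RS12979860)].alleles,
        )
        for s in subset
    ]
    return Rs12979860Study(
        panel=panel,
        sequencing_calls=sequencing,
        taqman_calls=taqman,
        commercial_calls=commercial,
        subset_samples=subset,
    )


# ---------------------------------------------------------------------------
# synthetic TaqMan locus (stand-in for the genomic slice, which is not bundled)

#: Probe-strand context around the SNP implied by the two probe sequences:
#: left flank + [C|T] + right flank (FAM matches the C haplotype, VIC the T).
_PROBE_CONTEXT_LEFT = "TCCCCGAAGGCG"
_PROBE_CONTEXT_RIGHT = "GAAC"

#: Extra paralogue substitutions planted outside the primer footprints so the
#: synthetic copies sit at a realistic mid-90s percent identity.
_EXTRA_PARALOGUE_SUBS = (130, 160, 230, 250, 330, 380)


@dataclass
class SyntheticTaqmanLocus:
    """A synthetic two-copy locus carrying the published TaqMan footprints."""

    locus: NucleotideSequence            # B-like copy + spacer + inverted A-like copy
    template_b: NucleotideSequence       # B-like region alone (forward strand)
    template_a: NucleotideSequence       # A-like region alone (as an inverted copy)
    snp: SnpRecord                       # the rs12979860-like site on template_b
    snp_on_locus: SnpRecord              # same site in locus coordinates
    forward_footprint: tuple[int, int]   # on template_b, 1-based inclusive
    reverse_footprint: tuple[int, int]


def _next_base(b: str) -> str:
    order = "ACGT"
    return order[(order.index(b) + 1) % 4]


def synthetic_taqman_locus(seed: int = 20120110) -> SyntheticTaqmanLocus:
    """Build a synthetic locus reproducing the TaqMan assay's geometry.

    The B-like copy carries the published forward and reverse primer
    annealing sites spaced so the product is exactly 214 bp (5'-to-5'),
    with the probe-implied SNP context between them. The A-like copy is the
    same region with substitutions planted at the documented
    paralogue-specificity positions of each primer (4 under the forward
    primer, including its 3'-terminal base; 3 under the reverse) plus a few
    background substitutions, then inserted in inverted orientation after a
    spacer. Deterministic for a given seed; the sequence is synthetic — only
    the primer/probe footprints and their mismatch pattern are the
    published ones.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def rand(n: int) -> str:
        return "".join(bases[rng.integers(0, 4, size=n)])

    fwd = TAQMAN_FORWARD.sequence
    rev_site = reverse_complement(TAQMAN_REVERSE.sequence)
    context = _PROBE_CONTEXT_LEFT + "C" + _PROBE_CONTEXT_RIGHT
    filler1 = rand(80)
    filler2_len = (
        TAQMAN_PRODUCT_BP - len(fwd) - len(filler1) - len(context) - len(rev_site)
    )
    filler2 = rand(filler2_len)
    amplicon = fwd + filler1 + context + filler2 + rev_site
    assert len(amplicon) == TAQMAN_PRODUCT_BP

    bg_left, bg_right = rand(100), rand(100)
    region_b = bg_left + amplicon + bg_right
    snp_pos_b = len(bg_left) + len(fwd) + len(filler1) + len(_PROBE_CONTEXT_LEFT) + 1

    fwd_start = len(bg_left) + 1
    fwd_fp = (fwd_start, fwd_start + len(fwd) - 1)
    rev_end = len(bg_left) + TAQMAN_PRODUCT_BP
    rev_fp = (rev_end - len(TAQMAN_REVERSE) + 1, rev_end)

    # plant the documented paralogue mismatches into the A-like copy
    a_chars = list(region_b)
    for p in TAQMAN_FORWARD_SPECIFICITY_POSITIONS:
        pos = fwd_fp[0] + p - 1
        a_chars[pos - 1] = _next_base(a_chars[pos - 1])
    for p in TAQMAN_REVERSE_SPECIFICITY_POSITIONS:
        pos = rev_fp[1] - (p - 1)  # reverse primer 5' end sits at rev_fp[1]
        a_chars[pos - 1] = _next_base(a_chars[pos - 1])
    for pos in _EXTRA_PARALOGUE_SUBS:
        a_chars[pos - 1] = _next_base(a_chars[pos - 1])
    region_a_forwardlike = "".join(a_chars)

    spacer = rand(300)
    locus_res = region_b + spacer + reverse_complement(region_a_forwardlike)
    locus = NucleotideSequence(id="synthetic_taqman_locus", residues=locus_res)
    template_b = NucleotideSequence(id="synthetic_IL28B_like", residues=region_b)
    template_a = NucleotideSequence(
        id="synthetic_IL28A_like", residues=reverse_complement(region_a_forwardlike)
    )
    snp = SnpRecord(id=RS12979860, position=snp_pos_b, ref_allele="C", alt_allele="T")
    snp_on_locus = SnpRecord(
        id=RS12979860, position=snp_pos_b, ref_allele="C", alt_allele="T"
    )
    return SyntheticTaqmanLocus(
        locus=locus,
        template_b=template_b,
        template_a=template_a,
        snp=snp,
        snp_on_locus=snp_on_locus,
        forward_footprint=fwd_fp,
        reverse_footprint=rev_fp,
    )
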