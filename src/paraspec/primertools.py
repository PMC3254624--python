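"""Primer/probe specificity scoring, in-silico PCR, and paralogue-aware design.

The central idea: when a genotyping target sits inside a segmental
duplication, assay specificity is driven by placing primer annealing sites
where the two copies differ, with a mismatch at the primer's 3' terminus
being the strongest lever (polymerase extension is blocked there). This
module counts per-column primer-versus-paralogue mismatches, predicts PCR
products by scanning for convergent binding sites, and designs primer pairs
that maximize paralogue mismatches around a target SNP.

The binding model is ungapped within a primer footprint; indels between the
copies are handled only through the duplication coordinate map (a partner
gap column counts as a mismatch).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from .dupfinder import CoordinateMap, Interval
from .seqio import BASES, NucleotideSequence, SnpRecord, reverse_complement

GAP = "-"

# Nearest-neighbor duplex parameters (unified oligonucleotide set of
# Allawi & SantaLucia 1997): delta-H kcal/mol, delta-S cal/(mol*K).
NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
#: Duplex initiation terms per terminal base pair.
NN_INIT_AT = (2.3, 4.1)
NN_INIT_GC = (0.1, -2.8)
NN_SYMMETRY = (0.0, -1.4)
GAS_CONSTANT = 1.987  # cal/(mol*K)


@dataclass(frozen=True)
class Primer:
    """An oligonucleotide written 5'->3'."""

    name: str
    sequence: str
    intended_target: str | None = None
    intended_strand: str | None = None  # "forward" | "reverse"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - BASES
        if bad:
            raise ValueError(f"primer {self.name}: ambiguous/illegal bases {sorted(bad)}")
        if not self.sequence:
            raise ValueError(f"primer {self.name}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingSite:
    """An ungapped primer footprint on a template's forward strand.

    `start`/`end` are 1-based inclusive forward-strand coordinates. For a
    '+' site the primer 5' end sits at `start`; for a '-' site it sits at
    `end` and the primer 3' end points leftward.
    """

    template: str
    start: int
    end: int
    strand: str
    mismatches: int

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class PrimerSpecificityReport:
    """Per-primer mismatch audit against the paralogous annealing site."""

    primer: Primer
    target_site: BindingSite | None
    paralogue_site: BindingSite | None
    paralogue_site_sequence: str | None
    mismatches_vs_paralogue: int
    terminal_3prime_mismatch: bool
    mismatches_in_last5: int
    tm_celsius: float
    mismatch_positions: tuple[int, ...] = ()  # 1-based from the primer 5' end

    def __post_init__(self) -> None:
        if not (
            self.mismatches_vs_paralogue
            >= self.mismatches_in_last5
            >= int(self.terminal_3prime_mismatch)
        ):
            raise ValueError("inconsistent mismatch bookkeeping")
        if self.mismatches_vs_paralogue > len(self.primer):
            raise ValueError("more mismatches than primer length")


@dataclass
class AmpliconPrediction:
    """A predicted PCR product from one convergent primer-site pair.

    `length_bp` is measured 5' end of the forward-binding site through the
    5' end of the reverse-binding site, inclusive.
    """

    template: str
    forward_primer: str
    reverse_primer: str
    forward_site: BindingSite
    reverse_site: BindingSite
    length_bp: int
    specific: bool = False


def melting_temperature(
    seq: str,
    monovalent_mM: float = 50.0,
    primer_uM: float = 0.25,
    template_uM: float = 0.25,
) -> float:
    """Nearest-neighbor duplex melting temperature in degrees Celsius.

    Uses the unified NN parameter set above with duplex-initiation terms per
    terminal base pair, the entropic monovalent-salt correction
    dS += 0.368 * (N-1) * ln[mon+], and Tm = dH / (dS + R ln CT) - 273.15
    with CT the excess strand concentration (C_primer - C_template/2, or
    C_primer for a self-complementary oligo).
    """
    s = seq.upper()
    if len(s) < 8:
        raise ValueError("Tm calculation requires length >= 8")
    bad = set(s) - BASES
    if bad:
        raise ValueError(f"ambiguous bases not allowed in Tm calculation: {sorted(bad)}")
    if monovalent_mM <= 0 or primer_uM <= 0:
        raise ValueError("concentrations must be positive")

    dh = 0.0
    ds = 0.0
    for a, b in zip(s, s[1:]):
        h, v = NN_PARAMS[a + b]
        dh += h
        ds += v
    for terminal in (s[0], s[-1]):
        h, v = NN_INIT_AT if terminal in "AT" else NN_INIT_GC
        dh += h
        ds += v
    selfcomp = s == reverse_complement(s)
    if selfcomp:
        dh += NN_SYMMETRY[0]
        ds += NN_SYMMETRY[1]
        ct = primer_uM * 1e-6
    else:
        ct = (primer_uM - template_uM / 2.0) * 1e-6
    ds += 0.368 * (len(s) - 1) * math.log(monovalent_mM / 1000.0)
    return (1000.0 * dh) / (ds + GAS_CONSTANT * math.log(ct)) - 273.15


def mismatch_count(
    primer: Primer,
    site: str,
    tm_conditions: dict | None = None,
    target_site: BindingSite | None = None,
    paralogue_site: BindingSite | None = None,
) -> PrimerSpecificityReport:
    """Column-wise primer-versus-site comparison, 5'->3'.

    `site` is the paralogous annealing site written in the primer's 5'->3'
    orientation, one character per primer base; a gap marker '-' (a partner
    deletion at that column) counts as a mismatch. The 3'-terminal flag is
    set iff the final primer base's column mismatches; `mismatches_in_last5`
    covers the final 5 columns.
    """
    site = site.upper()
    if len(site) != len(primer):
        raise ValueError(
            f"site length {len(site)} != primer length {len(primer)} "
            f"(gapped sites must carry explicit '-' columns)"
        )
    mism = tuple(
        idx + 1
        for idx, (p, q) in enumerate(zip(primer.sequence, site))
        if p != q
    )
    last5 = sum(1 for pos in mism if pos > len(primer) - 5)
    terminal = len(primer) in mism
    tm = melting_temperature(primer.sequence, **(tm_conditions or {}))
    return PrimerSpecificityReport(
        primer=primer,
        target_site=target_site,
        paralogue_site=paralogue_site,
        paralogue_site_sequence=site,
        mismatches_vs_paralogue=len(mism),
        terminal_3prime_mismatch=terminal,
        mismatches_in_last5=last5,
        tm_celsius=tm,
        mismatch_positions=mism,
    )


def _window_mismatches(template: str, query: str) -> np.ndarray:
    """Mismatch count of `query` against every offset of `template`."""
    t = np.frombuffer(template.encode(), dtype="S1")
    q = np.frombuffer(query.encode(), dtype="S1")
    if len(t) < len(q):
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(t, len(q))
    return (windows != q).sum(axis=1)


def find_binding_sites(
    primer: Primer,
    template: NucleotideSequence,
    max_mismatches: int = 0,
    require_3prime_match: bool = False,
) -> list[BindingSite]:
    """Scan both strands of a template for ungapped primer footprints.

    Exact-footprint matching with at most `max_mismatches` mismatches;
    with `require_3prime_match`, sites whose column under the primer's
    3'-terminal base mismatches are discarded. Sites are sorted by
    forward-strand start position.
    """
    seq = template.residues
    n = len(primer)
    if len(seq) < n:
        return []
    sites: list[BindingSite] = []

    fwd_mm = _window_mismatches(seq, primer.sequence)
    rc = reverse_complement(primer.sequence)
    rev_mm = _window_mismatches(seq, rc)
    t = np.frombuffer(seq.encode(), dtype="S1")

    for off in np.nonzero(fwd_mm <= max_mismatches)[0]:
        if require_3prime_match and seq[off + n - 1] != primer.sequence[-1]:
            continue
        sites.append(
            BindingSite(template.id, int(off) + 1, int(off) + n, "+", int(fwd_mm[off]))
        )
    for off in np.nonzero(rev_mm <= max_mismatches)[0]:
        # primer 3' terminus pairs with the leftmost template base of the window
        if require_3prime_match and seq[off] != rc[0]:
            continue
        sites.append(
            BindingSite(template.id, int(off) + 1, int(off) + n, "-", int(rev_mm[off]))
        )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicons(
    fwd: Primer,
    rev: Primer,
    templates: list[NucleotideSequence],
    max_mismatches: int = 0,
    max_product_bp: int = 5000,
    require_3prime_match: bool = False,
) -> list[AmpliconPrediction]:
    """Predict PCR products from every convergent pair of binding sites.

    A product arises when one primer binds '+' and the other binds '-'
    downstream, the product length (5'-to-5', inclusive) is at least the
    two primer lengths combined and at most `max_product_bp`. `specific` is
    True on every prediction iff exactly one product exists across all
    templates.
    """
    preds: list[AmpliconPrediction] = []
    min_len = len(fwd) + len(rev)
    for template in templates:
        sites = {
            fwd.name: find_binding_sites(fwd, template, max_mismatches, require_3prime_match),
            rev.name: find_binding_sites(rev, template, max_mismatches, require_3prime_match),
        }
        for left, right in ((fwd, rev), (rev, fwd)):
            for sl in sites[left.name]:
                if sl.strand != "+":
                    continue
                for sr in sites[right.name]:
                    if sr.strand != "-":
                        continue
                    length = sr.five_prime - sl.five_prime + 1
                    if min_len <= length <= max_product_bp:
                        preds.append(
                            AmpliconPrediction(
                                template=template.id,
                                forward_primer=left.name,
                                reverse_primer=right.name,
                                forward_site=sl,
                                reverse_site=sr,
                                length_bp=length,
                            )
                        )
    specific = len(preds) == 1
    for p in preds:
        p.specific = specific
    preds.sort(key=lambda p: (p.template, p.forward_site.start, p.length_bp))
    return preds


# ---------------------------------------------------------------------------
# paralogue-site extraction and design


def paralogue_site_string(
    cmap: CoordinateMap,
    footprint: Interval,
    host_copy: str,
    primer_strand: str,
) -> str:
    """The paralogous annealing site under a primer footprint, 5'->3'.

    Reads the partner row of the block alignment over the columns that
    consume the footprint's positions on the host copy, then orients the
    string to match the primer's 5'->3' direction so it can be compared
    column-by-column with the primer sequence. Partner deletions appear as
    '-'; partner insertions (columns with a gap on the host side) are
    dropped, consistent with the ungapped binding model.
    """
    aln = cmap.block.alignment
    partner_row = aln.aligned_b if host_copy == "a" else aln.aligned_a
    pos_to_col = cmap.position_to_column(host_copy)
    cols = sorted(
        pos_to_col[p]
        for p in range(footprint.start, footprint.end + 1)
        if p in pos_to_col
    )
    chars = [partner_row[k] for k in cols]
    if len(chars) != footprint.length:
        raise ValueError(
            f"footprint [{footprint.start},{footprint.end}] not fully inside "
            f"{cmap.block.block_id} copy_{host_copy}"
        )
    inverted = cmap.block.orientation == "inverted"
    # rows are written in copy_a forward orientation; aligned_b is the
    # reverse complement of the copy_b forward-strand slice
    site = "".join(chars)
    if host_copy == "a":
        oriented = site if primer_strand == "+" else _revcomp_gapped(site)
    else:
        if inverted:
            # aligned_a read left-to-right runs antiparallel to copy_b's
            # forward strand, so a '+' primer on copy_b needs the flip
            oriented = _revcomp_gapped(site) if primer_strand == "+" else site
        else:
            oriented = site if primer_strand == "+" else _revcomp_gapped(site)
    return oriented


def _revcomp_gapped(s: str) -> str:
    return "".join(
        GAP if c == GAP else reverse_complement(c) for c in reversed(s)
    )


def specificity_report(
    primer: Primer,
    footprint: Interval,
    strand: str,
    cmap: CoordinateMap,
    host_copy: str = "a",
    tm_conditions: dict | None = None,
) -> PrimerSpecificityReport:
    """Mismatch audit of a primer at a known footprint inside a block."""
    site = paralogue_site_string(cmap, footprint, host_copy, strand)
    target = BindingSite(cmap.block.block_id, footprint.start, footprint.end, strand, 0)
    return mismatch_count(primer, site, tm_conditions, target_site=target)


@dataclass(frozen=True)
class DesignConstraints:
    """Primer-pair design constraints; violations are flagged, not fatal."""

    tm_range: tuple[float, float] = (58.0, 62.0)
    length_range: tuple[int, int] = (15, 30)
    product_range: tuple[int, int] = (80, 300)
    gc_range: tuple[float, float] = (30.0, 70.0)
    max_homopolymer: int = 4


@dataclass
class PrimerPairCandidate:
    forward: PrimerSpecificityReport
    reverse: PrimerSpecificityReport
    product_length: int
    total_mismatches: int
    relaxations: tuple[str, ...] = ()


@dataclass
class DesignResult:
    candidates: list[PrimerPairCandidate]
    warnings: list[str] = field(default_factory=list)


def gc_percent(seq: str) -> float:
    return 100.0 * sum(c in "GC" for c in seq) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _constraint_flags(seq: str, tm: float, c: DesignConstraints) -> list[str]:
    flags = []
    if not c.tm_range[0] <= tm <= c.tm_range[1]:
        flags.append(f"tm {tm:.1f} outside {c.tm_range}")
    gc = gc_percent(seq)
    if not c.gc_range[0] <= gc <= c.gc_range[1]:
        flags.append(f"gc {gc:.0f}% outside {c.gc_range}")
    run = max_homopolymer_run(seq)
    if run > c.max_homopolymer:
        flags.append(f"homopolymer run {run} > {c.max_homopolymer}")
    return flags


def design_specific_primers(
    target_position: int,
    cmap: CoordinateMap,
    reference: NucleotideSequence,
    constraints: DesignConstraints | None = None,
    host_copy: str = "a",
    max_candidates_per_side: int = 30,
    max_pairs: int = 10,
    tm_conditions: dict | None = None,
) -> DesignResult:
    """Design paralogue-specific primer pairs flanking a target inside a block.

    Candidate footprints are enumerated over the allowed lengths and
    positions on the host copy (forward primers ending upstream of the
    target, reverse primers starting downstream), scored against the
    paralogous site from the coordinate map, and paired subject to the
    product-size range; every returned pair's product covers the target.
    Ranking (descending priority): total paralogue mismatches of the pair;
    3'-terminal mismatches; mismatches in the final 5 columns; distance of
    each Tm from the Tm-range midpoint; shorter product. Constraint
    violations (Tm, GC, homopolymer runs) are flagged per candidate rather
    than discarded — mirrors assay practice where specificity trumps
    textbook parameters. All-zero mismatch candidates trigger a
    'no specificity achievable' warning.
    """
    c = constraints or DesignConstraints()
    block = cmap.block
    interval = block.copy_a if host_copy == "a" else block.copy_b
    if not interval.contains(target_position):
        raise ValueError(
            f"target {target_position} outside {block.block_id} copy_{host_copy}"
        )
    min_len, max_len = c.length_range
    _, product_max = c.product_range
    seq = reference.residues
    warnings: list[str] = []

    def score_side(strand: str) -> list[PrimerSpecificityReport]:
        reports = []
        if strand == "+":
            end_range = range(
                target_position - 1,
                max(interval.start + min_len - 2, target_position - product_max) - 1,
                -1,
            )
        else:
            end_range = range(
                target_position + 1,
                min(interval.end - min_len + 2, target_position + product_max) + 1,
            )
        for anchor in end_range:
            for length in range(min_len, max_len + 1):
                if strand == "+":
                    fp = Interval(anchor - length + 1, anchor)
                    if fp.start < interval.start:
                        continue
                    pseq = seq[fp.start - 1 : fp.end]
                else:
                    fp_end = anchor + length - 1
                    if fp_end > interval.end:
                        continue
                    fp = Interval(anchor, fp_end)
                    pseq = reverse_complement(seq[fp.start - 1 : fp.end])
                primer = Primer(
                    name=f"{'fwd' if strand == '+' else 'rev'}_{fp.start}_{fp.end}",
                    sequence=pseq,
                )
                reports.append(
                    specificity_report(primer, fp, strand, cmap, host_copy, tm_conditions)
                )
        reports.sort(
            key=lambda r: (
                -r.mismatches_vs_paralogue,
                -int(r.terminal_3prime_mismatch),
                -r.mismatches_in_last5,
                r.target_site.start,
            )
        )
        return reports

    fwd_reports = score_side("+")
    rev_reports = score_side("-")
    if not fwd_reports or not rev_reports:
        return DesignResult([], ["no primer footprint fits inside the block"])

    def make_pair(fr: PrimerSpecificityReport, rr: PrimerSpecificityReport, product: int):
        flags = [
            f"forward: {f}" for f in _constraint_flags(fr.primer.sequence, fr.tm_celsius, c)
        ] + [
            f"reverse: {f}" for f in _constraint_flags(rr.primer.sequence, rr.tm_celsius, c)
        ]
        return PrimerPairCandidate(
            forward=fr,
            reverse=rr,
            product_length=product,
            total_mismatches=fr.mismatches_vs_paralogue + rr.mismatches_vs_paralogue,
            relaxations=tuple(flags),
        )

    # for each top candidate on one side, take the best-ranked partner on the
    # other side whose product length fits
    pairs_by_key: dict[tuple, PrimerPairCandidate] = {}
    lo, hi = c.product_range
    for fr in fwd_reports[:max_candidates_per_side]:
        for rr in rev_reports:
            product = rr.target_site.end - fr.target_site.start + 1
            if lo <= product <= hi:
                key = (fr.target_site.start, fr.target_site.end,
                       rr.target_site.start, rr.target_site.end)
                pairs_by_key.setdefault(key, make_pair(fr, rr, product))
                break
    for rr in rev_reports[:max_candidates_per_side]:
        for fr in fwd_reports:
            product = rr.target_site.end - fr.target_site.start + 1
            if lo <= product <= hi:
                key = (fr.target_site.start, fr.target_site.end,
                       rr.target_site.start, rr.target_site.end)
                pairs_by_key.setdefault(key, make_pair(fr, rr, product))
                break
    pairs = list(pairs_by_key.values())
    mid_tm = sum(c.tm_range) / 2.0
    if not pairs:
        # retry ignoring the product-size floor, flagged as a relaxation
        for fr in fwd_reports[:5]:
            for rr in rev_reports[:5]:
                product = rr.target_site.end - fr.target_site.start + 1
                if product > product_max:
                    continue
                pairs.append(
                    PrimerPairCandidate(
                        forward=fr,
                        reverse=rr,
                        product_length=product,
                        total_mismatches=fr.mismatches_vs_paralogue
                        + rr.mismatches_vs_paralogue,
                        relaxations=("product size below requested range",),
                    )
                )
        if pairs:
            warnings.append("product-size range relaxed")
    pairs.sort(
        key=lambda p: (
            -p.total_mismatches,
            -(
                int(p.forward.terminal_3prime_mismatch)
                + int(p.reverse.terminal_3prime_mismatch)
            ),
            -(p.forward.mismatches_in_last5 + p.reverse.mismatches_in_last5),
            abs(p.forward.tm_celsius - mid_tm) + abs(p.reverse.tm_celsius - mid_tm),
            p.product_length,
            p.forward.target_site.start,
            p.reverse.target_site.start,
        )
    )
    pairs = pairs[:max_pairs]
    if pairs and all(p.total_mismatches == 0 for p in pairs):
        warnings.append(
            "no specificity achievable: the two copies are identical across "
            "every candidate annealing site"
        )
    if not pairs:
        warnings.append("no primer pair satisfies the product-size constraints")
    return DesignResult(pairs, warnings)


# ---------------------------------------------------------------------------
# probe validation


@dataclass
class ProbeValidation:
    probe_name: str
    footprint: Interval
    strand: str
    matched_allele: str
    discriminating_offset: int  # 1-based from the probe 5' end


def validate_probe_pair(
    probes: list[Primer],
    snp: SnpRecord,
    template: NucleotideSequence,
) -> list[ProbeValidation]:
    """Check that two allele-specific probes discriminate a SNP on a template.

    Each probe must map (either strand) to a footprint covering the SNP
    position and match the template perfectly when exactly one allele is
    substituted at the SNP; the two probes must cover different alleles.
    Raises naming the probe when no such placement exists.
    """
    if len(probes) != 2:
        raise ValueError("validate_probe_pair requires exactly two probes")
    seq = template.residues
    results: list[ProbeValidation] = []
    for probe in probes:
        found = None
        for allele in snp.alleles:
            variant = seq[: snp.position - 1] + allele + seq[snp.position :]
            for strand, oriented in (("+", probe.sequence), ("-", reverse_complement(probe.sequence))):
                mm = _window_mismatches(variant, oriented)
                for off in np.nonzero(mm == 0)[0]:
                    start, end = int(off) + 1, int(off) + len(probe)
                    if not start <= snp.position <= end:
                        continue
                    if strand == "+":
                        offset = snp.position - start + 1
                    else:
                        offset = end - snp.position + 1
                    found = ProbeValidation(
                        probe_name=probe.name,
                        footprint=Interval(start, end),
                        strand=strand,
                        matched_allele=allele,
                        discriminating_offset=offset,
                    )
                    break
                if found:
                    break
            if found:
                break
        if found is None:
            raise ValueError(
                f"probe {probe.name} does not map to the template over the SNP "
                f"{snp.id} for either allele"
            )
        results.append(found)
    if results[0].matched_allele == results[1].matched_allele:
        raise ValueError(
            f"both probes match allele {results[0].matched_allele}; "
            "the pair does not discriminate the SNP"
        )
    return results


# ---------------------------------------------------------------------------
# tabular I/O


def read_primer_table(path) -> list[Primer]:
    """TSV with header (name, sequence[, role]) -> primers; role kept as strand hint."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    primers = []
    for row in df.itertuples(index=False):
        role = getattr(row, "role", None)
        primers.append(
            Primer(
                name=row.name if isinstance(row.name, str) else str(row[0]),
                sequence=row.sequence,
                intended_strand=role if role in ("forward", "reverse") else None,
            )
        )
    return primers


def specificity_reports_to_tsv(reports: list[PrimerSpecificityReport]) -> str:
    buf = io.StringIO()
    buf.write(
        "name\tsequence\tlength\ttm_celsius\tmismatches_vs_paralogue\t"
        "terminal_3prime_mismatch\tmismatches_in_last5\tmismatch_positions\t"
        "paralogue_site\n"
    )
    for r in reports:
        buf.write(
            "\t".join(
                [
                    r.primer.name,
                    r.primer.sequence,
                    str(len(r.primer)),
                    f"{r.tm_celsius:.1f}",
                    str(r.mismatches_vs_paralogue),
                    "yes" if r.terminal_3prime_mismatch else "no",
                    str(r.mismatches_in_last5),
                    ",".join(map(str, r.mismatch_positions)) or ".",
                    r.paralogue_site_sequence or ".",
                ]
            )
            + "\n"
        )
    return buf.getvalue()


def amplicons_to_tsv(preds: list[AmpliconPrediction]) -> str:
    buf = io.StringIO()
    buf.write(
        "template\tforward_primer\treverse_primer\tforward_start\tforward_end\t"
        "reverse_start\treverse_end\tlength_bp\tspecific\n"
    )
    for p in preds:
        buf.write(
            f"{p.template}\t{p.forward_primer}\t{p.reverse_primer}\t"
            f"{p.forward_site.start}\t{p.forward_site.end}\t{p.reverse_site.start}\t"
            f"{p.reverse_site.end}\t{p.length_bp}\t{'yes' if p.specific else 'no'}\n"
        )
    return buf.getvalue()
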