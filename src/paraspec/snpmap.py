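"""Classify SNPs as unique to one locus or shared with a duplicate copy.

A SNP is "shared" when its position falls inside either copy of a detected
duplication block: its flanking sequence then also exists (near-identically)
in the paralogue, so a non-specific assay could read through to the wrong
copy. For shared SNPs the module reports the partner position and base, which
of the SNP's two alleles matches the paralogue (a candidate paralogous
sequence variant pattern), which matches the ancestral allele, and the local
identity of the alignment around the site.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

from .dupfinder import CoordinateMap, DuplicationBlock, build_coordinate_map
from .seqio import (
    NucleotideSequence,
    SnpRecord,
    complement_base,
    validate_snp_on_reference,
)

GAP = "-"


@dataclass
class SnpDuplicationReport:
    """Classification of one SNP relative to the duplication structure.

    For shared SNPs, `paralogue_base` is given in the query copy's reading
    orientation: for an inverted block it is the complement of the partner
    position's forward-strand base, so it is directly comparable to the
    SNP's alleles.
    """

    snp: SnpRecord
    classification: str  # "unique" | "shared"
    block: DuplicationBlock | None = None
    host_copy: str | None = None  # "a" | "b"
    paralogue_position: int | None = None
    paralogue_base: str | None = None  # base or GAP marker
    allele_matching_paralogue: str | None = None
    allele_matching_ancestral: str | None = None
    context_identity_percent: float | None = None
    context_truncated: bool = False

    def __post_init__(self) -> None:
        if (self.classification == "unique") != (self.block is None):
            raise ValueError("unique classification iff no block")


def classify_snp(
    snp: SnpRecord,
    blocks: list[DuplicationBlock],
    reference: NucleotideSequence,
    maps: dict[str, CoordinateMap] | None = None,
) -> SnpDuplicationReport:
    """Classify a SNP as unique or shared and locate its paralogue partner.

    Shared iff the position falls inside any block's copy_a or copy_b
    interval. The partner position/base come from the block's coordinate
    map; a SNP whose alignment column has a gap on the partner side gets
    the gap marker and no matching allele. Blocks may host the SNP in
    either copy; the report records which.
    """
    validate_snp_on_reference(snp, reference)
    for block in blocks:
        copy = block.host_copy(snp.position)
        if copy is None:
            continue
        cmap = (maps or {}).get(block.block_id) or build_coordinate_map(block)
        partner = (cmap.a_to_b if copy == "a" else cmap.b_to_a).get(snp.position)
        if partner is None:
            paralogue_base = GAP
        else:
            fwd = reference.base_at(partner)
            paralogue_base = (
                complement_base(fwd) if block.orientation == "inverted" else fwd
            )
        report = SnpDuplicationReport(
            snp=snp,
            classification="shared",
            block=block,
            host_copy=copy,
            paralogue_position=partner,
            paralogue_base=paralogue_base,
        )
        return allele_paralogue_report(report)
    return SnpDuplicationReport(snp=snp, classification="unique")


def allele_paralogue_report(report: SnpDuplicationReport) -> SnpDuplicationReport:
    """Fill the allele-vs-paralogue and allele-vs-ancestral comparison.

    Sets `allele_matching_paralogue` to whichever of the SNP's two alleles
    equals the paralogue base (None when neither does, or when the partner
    column is a gap) and `allele_matching_ancestral` analogously. A missing
    ancestral annotation yields None without error.
    """
    if report.classification != "shared" or report.paralogue_base is None:
        raise ValueError(
            f"allele_paralogue_report requires a shared SNP with a paralogue base "
            f"({report.snp.id} is {report.classification})"
        )
    snp = report.snp
    if report.paralogue_base in snp.alleles:
        report.allele_matching_paralogue = report.paralogue_base
    else:
        report.allele_matching_paralogue = None
    if snp.ancestral_allele is not None and snp.ancestral_allele in snp.alleles:
        report.allele_matching_ancestral = snp.ancestral_allele
    else:
        report.allele_matching_ancestral = None
    return report


def snp_context_identity(
    report: SnpDuplicationReport,
    cmap: CoordinateMap,
    flank: int = 25,
) -> float:
    """Identity of the alignment window around a shared SNP.

    The window covers positions [pos - flank, pos + flank] on the SNP's host
    copy (default flank 25: a 51-column window). Gap columns count as
    mismatches. A window reaching past the block is truncated to the block
    and flagged via `report.context_truncated`. The result is stored in
    `report.context_identity_percent` and returned.
    """
    if report.classification != "shared" or report.block is None:
        raise ValueError(f"{report.snp.id} is not a shared SNP")
    if flank < 1:
        raise ValueError("flank must be >= 1")
    block = report.block
    pos = report.snp.position
    host = report.host_copy or "a"
    interval = block.copy_a if host == "a" else block.copy_b
    lo = pos - flank
    hi = pos + flank
    truncated = False
    if lo < interval.start:
        lo = interval.start
        truncated = True
    if hi > interval.end:
        hi = interval.end
        truncated = True
    idx = 0 if host == "a" else 1
    cols = [
        k
        for k, pair in enumerate(cmap.columns)
        if pair[idx] is not None and lo <= pair[idx] <= hi
    ]
    # include gap-on-host columns interior to the window
    k0, k1 = min(cols), max(cols)
    mask = cmap.block.alignment.match_mask()
    window = mask[k0 : k1 + 1]
    identity = 100.0 * float(window.sum()) / len(window)
    report.context_identity_percent = identity
    report.context_truncated = truncated
    return identity


def classify_panel(
    snps: list[SnpRecord],
    blocks: list[DuplicationBlock],
    reference: NucleotideSequence,
    flank: int = 25,
) -> list[SnpDuplicationReport]:
    """Classify a list of SNPs, completing paralogue and context fields."""
    maps = {b.block_id: build_coordinate_map(b) for b in blocks}
    reports = []
    for snp in snps:
        rep = classify_snp(snp, blocks, reference, maps=maps)
        if rep.classification == "shared" and rep.block is not None:
            snp_context_identity(rep, maps[rep.block.block_id], flank=flank)
        reports.append(rep)
    return reports


def reports_to_tsv(reports: list[SnpDuplicationReport]) -> str:
    """One row per SNP: classification, partner coordinates, allele matches."""
    buf = io.StringIO()
    buf.write(
        "id\tposition\tref\talt\tclassification\tblock_id\thost_copy\t"
        "paralogue_position\tparalogue_base\tallele_matching_paralogue\t"
        "allele_matching_ancestral\tcontext_identity_percent\tcontext_truncated\n"
    )
    for r in reports:
        s = r.snp
        ctx = (
            f"{r.context_identity_percent:.1f}"
            if r.context_identity_percent is not None
            else "."
        )
        buf.write(
            "\t".join(
                [
                    s.id,
                    str(s.position),
                    s.ref_allele,
                    s.alt_allele,
                    r.classification,
                    r.block.block_id if r.block else ".",
                    r.host_copy or ".",
                    str(r.paralogue_position or "."),
                    r.paralogue_base or ".",
                    r.allele_matching_paralogue or ".",
                    r.allele_matching_ancestral or ".",
                    ctx,
                    "yes" if r.context_truncated else "no",
                ]
            )
            + "\n"
        )
    return buf.getvalue()
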