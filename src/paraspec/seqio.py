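"""Sequence and SNP input/output plus core nucleotide-string services.

All user-facing coordinates in this package are 1-based inclusive (the
NCBI/dbSNP convention); 0-based half-open indices are used internally and
in BED output only. SNP positions are interpreted on the forward strand of
the supplied FASTA sequence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical unambiguous DNA bases.
BASES = frozenset("ACGT")

#: All IUPAC nucleotide one-letter codes (uppercase).
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

#: Two-base IUPAC ambiguity code for each unordered pair of distinct bases.
_HET_CODES = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

#: Base sets denoted by each IUPAC code.
IUPAC_EXPANSION = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class ParseError(ValueError):
    """Raised when an input file is malformed; names the offending line."""


class AncestralSource(str, enum.Enum):
    """Provenance of an ancestral-allele annotation."""

    DB = "db"
    PRIMATE_ALIGNMENT = "primate_alignment"
    UNKNOWN = "unknown"


@dataclass
class NucleotideSequence:
    """A named DNA sequence over the IUPAC alphabet.

    Residues are upper-cased on construction; soft-masking (lower case) has
    no meaning here.
    """

    id: str
    residues: str
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id {self.id!r} is empty or contains whitespace")
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def base_at(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise ValueError(f"position {position} outside sequence {self.id!r}")
        return self.residues[position - 1]

    def reverse_complement(self, new_id: str | None = None) -> "NucleotideSequence":
        return NucleotideSequence(
            id=new_id or f"{self.id}_rc",
            residues=reverse_complement(self.residues),
            description=self.description,
        )


@dataclass
class SnpRecord:
    """A biallelic SNP on a reference sequence (1-based position)."""

    id: str
    position: int
    ref_allele: str
    alt_allele: str
    ancestral_allele: str | None = None
    ancestral_source: AncestralSource = AncestralSource.UNKNOWN

    def __post_init__(self) -> None:
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        for name, a in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if a not in BASES:
                raise ValueError(f"{name} allele {a!r} of {self.id} is not one of A/C/G/T")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.id}: ref and alt alleles are identical")
        if self.position < 1:
            raise ValueError(f"SNP {self.id}: position must be >= 1")
        if self.ancestral_allele is not None:
            self.ancestral_allele = self.ancestral_allele.upper()
            if self.ancestral_allele not in BASES:
                raise ValueError(
                    f"SNP {self.id}: ancestral allele {self.ancestral_allele!r} invalid"
                )
        if not isinstance(self.ancestral_source, AncestralSource):
            self.ancestral_source = AncestralSource(self.ancestral_source)

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.ref_allele, self.alt_allele)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string.

    Ambiguity codes are complemented by their base sets (R<->Y, S<->S,
    W<->W, K<->M, B<->V, D<->H, N<->N).
    """
    s = seq.upper()
    bad = set(s) - IUPAC_CODES
    if bad:
        raise ValueError(f"illegal nucleotide characters: {sorted(bad)}")
    return str(Seq(s).reverse_complement())


def complement_base(base: str) -> str:
    """Complement of a single IUPAC code."""
    return reverse_complement(base)


def iupac_het_code(allele1: str, allele2: str) -> str:
    """IUPAC ambiguity code for a heterozygote of two distinct bases.

    Symmetric in its arguments; raises if the alleles are identical (a
    homozygote has no ambiguity code) or not plain bases.
    """
    a, b = allele1.upper(), allele2.upper()
    if a not in BASES or b not in BASES:
        raise ValueError(f"alleles must be unambiguous bases, got {allele1!r}/{allele2!r}")
    if a == b:
        raise ValueError(f"identical alleles {a!r}: not a heterozygote")
    return _HET_CODES[frozenset((a, b))]


def expand_iupac(code: str) -> tuple[str, ...]:
    """The set of plain bases an IUPAC code stands for."""
    try:
        return tuple(IUPAC_EXPANSION[code.upper()])
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a (multi-)FASTA file into NucleotideSequence records.

    Residues are upper-cased; record order is preserved; an empty file
    yields an empty list. Illegal characters raise ParseError naming the
    first offending line.
    """
    path = Path(path)
    records: list[NucleotideSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        bad = set(residues) - IUPAC_CODES
        if bad:
            raise ParseError(
                f"{path}: record {rec.id!r} line {_find_bad_line(path, bad)}: "
                f"illegal nucleotide characters {sorted(bad)}"
            )
        if not residues:
            raise ParseError(f"{path}: record {rec.id!r} has no sequence")
        records.append(
            NucleotideSequence(
                id=rec.id, residues=residues, description=rec.description or None
            )
        )
    return records


def _find_bad_line(path: Path, bad_chars: set[str]) -> int:
    bad = {c.upper() for c in bad_chars} | {c.lower() for c in bad_chars}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip()) & bad:
                return lineno
    return 0


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA, wrapped at `width` columns (default 60)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description or "")
        for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


_SNP_COLUMNS = ["id", "position", "ref", "alt", "ancestral", "ancestral_source"]


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    """Read a SNP list from TSV with header columns
    id, position, ref, alt[, ancestral[, ancestral_source]].
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["", "."], keep_default_na=False)
    missing = {"id", "position", "ref", "alt"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    snps = []
    for row in df.itertuples(index=False):
        anc = getattr(row, "ancestral", None)
        anc = None if (anc is None or pd.isna(anc)) else anc
        src = getattr(row, "ancestral_source", None)
        src = AncestralSource.UNKNOWN if (src is None or pd.isna(src)) else AncestralSource(src)
        snps.append(
            SnpRecord(
                id=row.id,
                position=int(row.position),
                ref_allele=row.ref,
                alt_allele=row.alt,
                ancestral_allele=anc,
                ancestral_source=src,
            )
        )
    return snps


def write_snp_table(snps: Iterable[SnpRecord], path: str | Path) -> None:
    rows = [
        {
            "id": s.id,
            "position": s.position,
            "ref": s.ref_allele,
            "alt": s.alt_allele,
            "ancestral": s.ancestral_allele or ".",
            "ancestral_source": s.ancestral_source.value,
        }
        for s in snps
    ]
    pd.DataFrame(rows, columns=_SNP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_snp_vcf(path: str | Path) -> list[SnpRecord]:
    """Read SNPs from a minimal VCF 4.x file.

    Only CHROM/POS/ID/REF/ALT are used; all other fields are ignored.
    Multiallelic records and non-SNP alleles raise ParseError.
    """
    import pysam

    snps: list[SnpRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                raise ParseError(
                    f"{path}: record {rec.id or rec.pos} is not a biallelic SNP"
                )
            snps.append(
                SnpRecord(
                    id=rec.id or f"snp_{rec.pos}",
                    position=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alts[0],
                )
            )
    return snps


def validate_snp_on_reference(snp: SnpRecord, reference: NucleotideSequence) -> None:
    """Check the SNP position lies on the reference (1..len)."""
    if not 1 <= snp.position <= len(reference):
        raise ValueError(
            f"SNP {snp.id} position {snp.position} outside reference "
            f"{reference.id!r} (length {len(reference)})"
        )
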