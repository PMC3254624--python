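"""Genotype-panel statistics and assay validation.

Covers the population-genetics bookkeeping of a genotyping validation study:
allele-frequency tables per population, polymorphic/monomorphic site
classification, variant calling from Sanger consensus sequences (IUPAC
ambiguity codes expand to heterozygotes), exact concordance between two
assays with one-sided Beta lower confidence bounds, and the random-match
probability used to rule out sample mix-ups.

The concordance bound: after s identical calls in n paired trials, the
posterior over the true concordance probability (uniform prior) is
Beta(s+1, n-s+1); the one-sided lower limit at confidence c is the (1-c)
quantile of that distribution. For s = n this has the closed form
(1-c)^(1/(n+1)).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import beta as beta_dist

from .seqio import BASES, NucleotideSequence, SnpRecord, expand_iupac, iupac_het_code

MISSING = "."


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered diploid call for one sample at one SNP (None = missing)."""

    sample_id: str
    snp_id: str
    alleles: tuple[str, str] | None

    def __post_init__(self) -> None:
        if self.alleles is not None:
            a, b = (x.upper() for x in self.alleles)
            if a not in BASES or b not in BASES:
                raise ValueError(
                    f"{self.sample_id}/{self.snp_id}: alleles must be A/C/G/T"
                )
            object.__setattr__(self, "alleles", tuple(sorted((a, b))))

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    def same_genotype(self, other: "GenotypeCall") -> bool:
        if self.is_missing or other.is_missing:
            return False
        return self.alleles == other.alleles


@dataclass
class GenotypePanel:
    """Samples x SNPs unordered diploid calls with population labels."""

    calls: dict[tuple[str, str], GenotypeCall] = field(default_factory=dict)
    populations: dict[str, str] = field(default_factory=dict)

    def add(self, call: GenotypeCall, population: str | None = None) -> None:
        key = (call.sample_id, call.snp_id)
        if key in self.calls:
            raise ValueError(f"duplicate call for {key}")
        self.calls[key] = call
        if population is not None:
            self.populations[call.sample_id] = population

    @property
    def sample_ids(self) -> list[str]:
        return sorted({s for s, _ in self.calls})

    @property
    def snp_ids(self) -> list[str]:
        return sorted({m for _, m in self.calls})

    def calls_for_snp(self, snp_id: str) -> list[GenotypeCall]:
        calls = [c for (s, m), c in self.calls.items() if m == snp_id]
        if not calls:
            raise ValueError(f"unknown SNP {snp_id!r}")
        return sorted(calls, key=lambda c: c.sample_id)

    def calls_for_sample(self, sample_id: str) -> list[GenotypeCall]:
        return sorted(
            (c for (s, m), c in self.calls.items() if s == sample_id),
            key=lambda c: c.snp_id,
        )


@dataclass
class FrequencyRow:
    """Allele frequencies for one SNP in one group."""

    group: str
    counts: dict[str, int]
    chromosomes: int

    @property
    def frequencies(self) -> dict[str, float]:
        return {a: n / self.chromosomes for a, n in self.counts.items()}

    def display(self, allele_order: tuple[str, str] | None = None, decimals: int = 2) -> str:
        """'0.53/0.47'-style rendering, 2 decimals by default."""
        order = allele_order or tuple(sorted(self.counts, key=self.counts.get, reverse=True))
        return "/".join(f"{self.frequencies.get(a, 0.0):.{decimals}f}" for a in order)


@dataclass
class ConcordanceResult:
    """Exact agreement between two call lists with Beta lower bounds."""

    n: int
    s: int
    discordant: list[tuple[str, tuple[str, str], tuple[str, str]]]
    lower_bounds: dict[float, float]

    def __post_init__(self) -> None:
        if not 0 <= self.s <= self.n:
            raise ValueError("need 0 <= s <= n")
        if len(self.discordant) != self.n - self.s:
            raise ValueError("discordant list inconsistent with s and n")

    @property
    def concordance(self) -> float:
        return self.s / self.n


def allele_frequencies(
    panel: GenotypePanel, snp_id: str, by_population: bool = True
) -> dict[str, FrequencyRow]:
    """Allele counts and frequencies for one SNP, per population group.

    Frequency = allele count / (2 x non-missing samples); frequencies per
    group sum to 1. With `by_population` False a single 'ALL' group is
    returned. Missing calls are excluded.
    """
    calls = [c for c in panel.calls_for_snp(snp_id) if not c.is_missing]
    if not calls:
        raise ValueError(f"SNP {snp_id!r} has no non-missing calls")
    groups: dict[str, list[GenotypeCall]] = {}
    for c in calls:
        group = panel.populations.get(c.sample_id, "ALL") if by_population else "ALL"
        groups.setdefault(group, []).append(c)
    out = {}
    for group, gcalls in sorted(groups.items()):
        counts: dict[str, int] = {}
        for c in gcalls:
            for a in c.alleles:
                counts[a] = counts.get(a, 0) + 1
        out[group] = FrequencyRow(group=group, counts=counts, chromosomes=2 * len(gcalls))
    return out


def classify_site(panel: GenotypePanel, snp_id: str) -> str:
    """'polymorphic' iff at least two distinct alleles are observed."""
    calls = [c for c in panel.calls_for_snp(snp_id) if not c.is_missing]
    if not calls:
        raise ValueError(f"SNP {snp_id!r}: all calls missing")
    alleles = {a for c in calls for a in c.alleles}
    return "polymorphic" if len(alleles) >= 2 else "monomorphic"


def call_variants_from_consensus(
    consensus: NucleotideSequence,
    reference: NucleotideSequence,
    offset: int = 1,
) -> list[SnpRecord]:
    """Call substitution variants of a consensus against a reference.

    The consensus (e.g. from assembled Sanger reads) aligns colinearly at
    1-based `offset` on the reference; it may contain two-base IUPAC
    ambiguity codes (R/Y/S/W/K/M), which expand to heterozygote calls whose
    alt is the non-reference base. Positions are reported on the reference
    coordinate system. Indels are outside the contract and surface as a
    length error.
    """
    if offset < 1 or offset + len(consensus) - 1 > len(reference):
        raise ValueError(
            f"consensus (length {len(consensus)}) at offset {offset} exceeds "
            f"reference length {len(reference)}"
        )
    calls: list[SnpRecord] = []
    for i, code in enumerate(consensus.residues):
        pos = offset + i
        ref_base = reference.residues[pos - 1]
        if code == ref_base:
            continue
        obs = expand_iupac(code)
        if len(obs) > 2:
            raise ValueError(
                f"position {pos}: code {code!r} is not a biallelic observation"
            )
        non_ref = [b for b in obs if b != ref_base]
        if not non_ref:
            continue
        if len(non_ref) > 1:
            # homozygous difference or het with neither allele matching ref
            alt = non_ref[0] if len(obs) == 1 else non_ref[0]
        else:
            alt = non_ref[0]
        calls.append(
            SnpRecord(
                id=f"{consensus.id}_{pos}",
                position=pos,
                ref_allele=ref_base,
                alt_allele=alt,
            )
        )
    return calls


def apply_variants(
    reference: NucleotideSequence, calls: list[SnpRecord], het_as_iupac: bool = True
) -> NucleotideSequence:
    """Write calls back onto the reference (hets become ambiguity codes)."""
    residues = list(reference.residues)
    for c in calls:
        residues[c.position - 1] = (
            iupac_het_code(c.ref_allele, c.alt_allele) if het_as_iupac else c.alt_allele
        )
    return NucleotideSequence(id=f"{reference.id}_variant", residues="".join(residues))


def beta_lower_bound(s: int, n: int, confidence: float) -> float:
    """Exact one-sided lower confidence limit on a success probability.

    Returns the (1-confidence) quantile of Beta(s+1, n-s+1): the value p*
    with P(p <= p*) = 1-confidence under the posterior after s successes in
    n trials. For s = n this equals (1-confidence)^(1/(n+1)).
    """
    if not 0 <= s <= n or n < 1:
        raise ValueError("need 0 <= s <= n and n >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    return float(beta_dist.ppf(1.0 - confidence, s + 1, n - s + 1))


def concordance(
    calls_a: list[GenotypeCall],
    calls_b: list[GenotypeCall],
    confidences: tuple[float, ...] = (0.95, 0.99),
) -> ConcordanceResult:
    """Exact unordered-genotype concordance between two assays.

    Samples are matched by id (both lists must be for the same SNP); pairs
    with a missing call on either side are excluded from n. Order of input
    does not affect the result.
    """
    snps = {c.snp_id for c in calls_a} | {c.snp_id for c in calls_b}
    if len(snps) != 1:
        raise ValueError(f"concordance requires a single SNP, got {sorted(snps)}")
    a_by_sample = {c.sample_id: c for c in calls_a}
    b_by_sample = {c.sample_id: c for c in calls_b}
    shared = sorted(set(a_by_sample) & set(b_by_sample))
    if not shared:
        raise ValueError("no overlapping samples between the two call lists")
    n = s = 0
    discordant = []
    for sample in shared:
        ca, cb = a_by_sample[sample], b_by_sample[sample]
        if ca.is_missing or cb.is_missing:
            continue
        n += 1
        if ca.same_genotype(cb):
            s += 1
        else:
            discordant.append((sample, ca.alleles, cb.alleles))
    if n == 0:
        raise ValueError("no pairs with calls on both sides")
    bounds = {conf: beta_lower_bound(s, n, conf) for conf in confidences}
    return ConcordanceResult(n=n, s=s, discordant=discordant, lower_bounds=bounds)


def random_match_probability(
    profile: list[GenotypeCall],
    freqs: dict[str, dict[str, float]],
    ld_caveats: list[str] | None = None,
) -> float:
    """Probability a random individual matches a multi-marker genotype profile.

    Product over markers of the Hardy-Weinberg genotype frequency of the
    observed call (2pq for a heterozygote, p^2 for a homozygote), assuming
    marker independence. Linkage-disequilibrium caveats, when supplied, are
    reported verbatim alongside rather than modelled. A probability below
    ~0.01 is the conventional threshold for excluding a sample mix-up.
    """
    if not profile:
        raise ValueError("empty profile")
    prob = 1.0
    for call in profile:
        if call.is_missing:
            continue
        try:
            marker = freqs[call.snp_id]
        except KeyError:
            raise ValueError(f"no frequencies for marker {call.snp_id!r}") from None
        a, b = call.alleles
        for allele in (a, b):
            if allele not in marker:
                raise ValueError(
                    f"allele {allele!r} of {call.snp_id} absent from frequency table"
                )
        prob *= (2.0 if a != b else 1.0) * marker[a] * marker[b]
    return prob


# ---------------------------------------------------------------------------
# tabular I/O


def read_genotype_panel(path: str | Path) -> GenotypePanel:
    """TSV with header (sample, population, snp, allele1, allele2); '.' = missing."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[""], keep_default_na=False)
    panel = GenotypePanel()
    for row in df.itertuples(index=False):
        alleles = None
        if row.allele1 != MISSING and row.allele2 != MISSING:
            alleles = (row.allele1, row.allele2)
        panel.add(
            GenotypeCall(sample_id=row.sample, snp_id=row.snp, alleles=alleles),
            population=row.population,
        )
    return panel


def write_genotype_panel(panel: GenotypePanel, path: str | Path) -> None:
    rows = []
    for (sample, snp), call in sorted(panel.calls.items()):
        a1, a2 = call.alleles if call.alleles else (MISSING, MISSING)
        rows.append(
            {
                "sample": sample,
                "population": panel.populations.get(sample, "ALL"),
                "snp": snp,
                "allele1": a1,
                "allele2": a2,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def frequency_table_tsv(
    panel: GenotypePanel,
    snp_ids: list[str],
    allele_orders: dict[str, tuple[str, str]] | None = None,
) -> str:
    """Per-population frequency report mirroring a published-table layout."""
    buf = io.StringIO()
    buf.write("snp\tgroup\talleles\tfrequencies\tchromosomes\n")
    for snp_id in snp_ids:
        rows = allele_frequencies(panel, snp_id, by_population=True)
        order = (allele_orders or {}).get(snp_id)
        for group, row in rows.items():
            shown = order or tuple(sorted(row.counts, key=row.counts.get, reverse=True))
            buf.write(
                f"{snp_id}\t{group}\t{'/'.join(shown)}\t{row.display(shown)}\t"
                f"{row.chromosomes}\n"
            )
    return buf.getvalue()


def concordance_to_json(result: ConcordanceResult) -> dict:
    return {
        "n": result.n,
        "s": result.s,
        "concordance": result.concordance,
        "discordant": [
            {"sample": s, "call_a": "/".join(a), "call_b": "/".join(b)}
            for s, a, b in result.discordant
        ],
        "lower_bounds": {str(k): v for k, v in result.lower_bounds.items()},
    }
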