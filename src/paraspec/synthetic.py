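"""Ground-truthed synthetic fixtures for the whole toolkit.

Generates (i) a sequence carrying an inverted duplication — a copy placed
forward, its reverse complement mutated to a requested percent identity
placed after a spacer, mirroring the two-copies-on-opposite-strands
structure of an IL28A/IL28B-like locus — with planted shared and unique
SNPs and full truth labels; and (ii) genotype panels drawn under
Hardy-Weinberg proportions from stated per-population allele frequencies.

Background sequence is uniform i.i.d. ACGT; copy-B divergence is
substitution-only by default (keeps the coordinate map exact), with an
optional indel rate for exercising gapped paths. Everything is reproducible
byte-for-byte from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genostats import GenotypeCall, GenotypePanel
from .seqio import (
    BASES,
    NucleotideSequence,
    SnpRecord,
    complement_base,
    reverse_complement,
    write_fasta,
    write_snp_table,
)

_BASE_ARRAY = np.array(list("ACGT"))


@dataclass
class PlantedSnp:
    """A planted SNP plus its truth label."""

    snp: SnpRecord
    truth_label: str  # "unique" | "shared"
    true_paralogue_position: int | None = None
    true_paralogue_base: str | None = None  # in the host copy's reading orientation


@dataclass
class SyntheticTruth:
    """A generated fixture with its planted ground truth."""

    sequence: NucleotideSequence
    block_a: tuple[int, int]  # 1-based inclusive, forward copy
    block_b: tuple[int, int]  # 1-based inclusive, inverted copy
    identity_percent: float  # realized identity of the planted pair
    snps: list[PlantedSnp] = field(default_factory=list)
    seed: int = 0
    params: dict = field(default_factory=dict)

    def truth_labels(self) -> dict[str, str]:
        return {p.snp.id: p.truth_label for p in self.snps}

    def snp_records(self) -> list[SnpRecord]:
        return [p.snp for p in self.snps]

    def write(self, outdir: str | Path, prefix: str = "fixture") -> dict[str, Path]:
        """Materialize FASTA + SNP TSV + truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / f"{prefix}.fasta"
        snps = outdir / f"{prefix}_snps.tsv"
        truth = outdir / f"{prefix}_truth.json"
        write_fasta([self.sequence], fasta)
        write_snp_table(self.snp_records(), snps)
        truth.write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "params": self.params,
                    "block_a": list(self.block_a),
                    "block_b": list(self.block_b),
                    "identity_percent": self.identity_percent,
                    "snps": [
                        {
                            "id": p.snp.id,
                            "position": p.snp.position,
                            "truth_label": p.truth_label,
                            "true_paralogue_position": p.true_paralogue_position,
                            "true_paralogue_base": p.true_paralogue_base,
                        }
                        for p in self.snps
                    ],
                },
                indent=2,
            )
        )
        return {"fasta": fasta, "snps": snps, "truth": truth}


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASE_ARRAY[rng.integers(0, 4, size=n)])


def _substitute(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def simulate_inverted_duplication(
    total_length: int = 5000,
    block_length: int = 1000,
    spacer_length: int = 1000,
    identity_percent: float = 96.0,
    n_shared_snps: int = 6,
    n_unique_snps: int = 3,
    seed: int = 0,
    indel_rate: float = 0.0,
    snp_margin: int = 30,
) -> SyntheticTruth:
    """Plant an inverted duplication with labelled shared and unique SNPs.

    Copy A is placed forward; its reverse complement, mutated down to
    `identity_percent` by uniform substitutions (plus optional indels at
    `indel_rate` per base), is placed `spacer_length` bp downstream. Shared
    SNPs are planted inside copy A at least `snp_margin` bp from its edges;
    unique SNPs land outside both copies. The defaults mirror the studied
    locus geometry: kb-scale blocks at mid-90s identity with a 6-shared /
    3-unique SNP split.
    """
    if not 50.0 < identity_percent <= 100.0:
        raise ValueError("identity_percent must be in (50, 100]")
    if total_length < 2 * block_length + spacer_length:
        raise ValueError("total_length too small for the requested geometry")
    rng = np.random.default_rng(seed)

    margin = total_length - 2 * block_length - spacer_length
    lead = margin // 2
    tail = margin - lead
    if n_unique_snps > 0 and max(lead, tail) < snp_margin + 2:
        raise ValueError("margins too small to place unique SNPs outside the copies")

    copy_a = _random_bases(rng, block_length)

    # mutate the reverse complement of copy A down to the requested identity
    b_seq = list(reverse_complement(copy_a))
    n_sub = int(round((1.0 - identity_percent / 100.0) * block_length))
    sub_positions = rng.choice(block_length, size=n_sub, replace=False)
    for p in sub_positions:
        b_seq[p] = _substitute(rng, b_seq[p])
    if indel_rate > 0:
        keep = rng.random(len(b_seq)) >= indel_rate
        inserted = rng.random(len(b_seq)) < indel_rate
        out = []
        for i, ch in enumerate(b_seq):
            if keep[i]:
                out.append(ch)
            if inserted[i]:
                out.append(str(_BASE_ARRAY[rng.integers(0, 4)]))
        b_seq = out
    copy_b = "".join(b_seq)

    lead_seq = _random_bases(rng, lead)
    spacer = _random_bases(rng, spacer_length)
    tail_seq = _random_bases(rng, tail)
    full = lead_seq + copy_a + spacer + copy_b + tail_seq

    a_start = lead + 1
    a_end = lead + block_length
    b_start = lead + block_length + spacer_length + 1
    b_end = b_start + len(copy_b) - 1

    identity = 100.0 * (block_length - n_sub) / block_length if indel_rate == 0 else (
        100.0 * (block_length - n_sub) / max(block_length, len(copy_b))
    )

    seq = NucleotideSequence(id=f"synthetic_dup_seed{seed}", residues=full)

    snps: list[PlantedSnp] = []
    # shared SNPs: inside copy A, away from edges, unique positions
    interior = np.arange(snp_margin, block_length - snp_margin)
    if n_shared_snps > 0:
        shared_offsets = np.sort(rng.choice(interior, size=n_shared_snps, replace=False))
    else:
        shared_offsets = np.array([], dtype=int)
    for k, off in enumerate(shared_offsets):
        pos = a_start + int(off)
        ref = seq.base_at(pos)
        alt = _substitute(rng, ref)
        # partner of copy-A offset `off` (0-based) under the inversion:
        # copy-B offset (block_length-1-off) before indels; forward position
        par_pos = b_end - int(off) if indel_rate == 0 else None
        par_base = None
        if par_pos is not None:
            par_base = complement_base(seq.base_at(par_pos))
        snps.append(
            PlantedSnp(
                snp=SnpRecord(
                    id=f"shared_{k + 1}", position=pos, ref_allele=ref, alt_allele=alt
                ),
                truth_label="shared",
                true_paralogue_position=par_pos,
                true_paralogue_base=par_base,
            )
        )
    # unique SNPs: outside both copies (lead, spacer or tail)
    outside: list[int] = []
    for lo, hi in (
        (1 + snp_margin, lead - snp_margin),
        (a_end + 1 + snp_margin, b_start - 1 - snp_margin),
        (b_end + 1 + snp_margin, len(full) - snp_margin),
    ):
        outside.extend(range(lo, hi + 1))
    if n_unique_snps > len(outside):
        raise ValueError("not enough sequence outside the copies for unique SNPs")
    unique_positions = sorted(
        int(p) for p in rng.choice(np.array(outside), size=n_unique_snps, replace=False)
    )
    for k, pos in enumerate(unique_positions):
        ref = seq.base_at(pos)
        alt = _substitute(rng, ref)
        snps.append(
            PlantedSnp(
                snp=SnpRecord(
                    id=f"unique_{k + 1}", position=pos, ref_allele=ref, alt_allele=alt
                ),
                truth_label="unique",
            )
        )

    return SyntheticTruth(
        sequence=seq,
        block_a=(a_start, a_end),
        block_b=(b_start, b_end),
        identity_percent=identity,
        snps=snps,
        seed=seed,
        params={
            "total_length": total_length,
            "block_length": block_length,
            "spacer_length": spacer_length,
            "identity_percent": identity_percent,
            "n_shared_snps": n_shared_snps,
            "n_unique_snps": n_unique_snps,
            "indel_rate": indel_rate,
        },
    )


def simulate_genotype_panel(
    freqs: dict[str, dict[str, dict[str, float]]],
    n_per_population: int = 16,
    seed: int = 0,
    sample_prefix: str = "S",
) -> GenotypePanel:
    """Draw a genotype panel under Hardy-Weinberg proportions.

    `freqs[snp_id][population][allele] = frequency`; frequencies must sum
    to 1 per SNP/population. The default panel size (16 per population)
    matches a three-population, 48-sample validation design.
    """
    rng = np.random.default_rng(seed)
    panel = GenotypePanel()
    populations = sorted({pop for by_pop in freqs.values() for pop in by_pop})
    samples = {
        pop: [f"{sample_prefix}_{pop}_{i + 1:02d}" for i in range(n_per_population)]
        for pop in populations
    }
    for snp_id in sorted(freqs):
        for pop in sorted(freqs[snp_id]):
            table = freqs[snp_id][pop]
            alleles = sorted(table)
            p = np.array([table[a] for a in alleles], dtype=float)
            if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValueError(
                    f"frequencies for {snp_id}/{pop} must be non-negative and sum to 1"
                )
            draws = rng.choice(len(alleles), size=(n_per_population, 2), p=p)
            for sample, (i, j) in zip(samples[pop], draws):
                panel.add(
                    GenotypeCall(
                        sample_id=sample,
                        snp_id=snp_id,
                        alleles=(alleles[i], alleles[j]),
                    ),
                    population=pop,
                )
    return panel
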