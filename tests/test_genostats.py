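import random

import numpy as np
import pytest

from oracles import beta_quantile_by_quadrature
from paraspec import genostats, synthetic
from paraspec.genostats import (
    GenotypeCall,
    GenotypePanel,
    allele_frequencies,
    beta_lower_bound,
    call_variants_from_consensus,
    classify_site,
    concordance,
    random_match_probability,
)
from paraspec.seqio import NucleotideSequence


def _panel_from_counts(counts, snp="rs_test", pop="CEU"):
    panel = GenotypePanel()
    i = 0
    for genotype, n in counts.items():
        for _ in range(n):
            i += 1
            panel.add(GenotypeCall(f"S{i:02d}", snp, genotype), population=pop)
    return panel


class TestAlleleFrequencies:
    def test_29_of_32_chromosomes_rounds_to_091(self):
        """16 samples with allele counts 29/3 display as 0.91/0.09."""
        panel = _panel_from_counts(
            {("C", "C"): 13, ("C", "T"): 3, ("T", "T"): 0}, pop="JPT"
        )
        rows = allele_frequencies(panel, "rs_test")
        row = rows["JPT"]
        assert row.counts == {"C": 29, "T": 3}
        assert row.display(("C", "T")) == "0.91/0.09"

    def test_monomorphic_displays_100(self):
        panel = _panel_from_counts({("T", "T"): 16})
        row = allele_frequencies(panel, "rs_test")["CEU"]
        assert row.display(("T", "C")) == "1.00/0.00"
        assert sum(row.frequencies.values()) == pytest.approx(1.0)

    def test_matches_brute_force_recount(self):
        rng = random.Random(71)
        panel = GenotypePanel()
        expected = {}
        for i in range(40):
            g = tuple(sorted(rng.choice("ACGT") + rng.choice("ACGT")))
            panel.add(GenotypeCall(f"S{i}", "m", g), population="ALL")
            for a in g:
                expected[a] = expected.get(a, 0) + 1
        row = allele_frequencies(panel, "m", by_population=False)["ALL"]
        assert row.counts == expected
        assert sum(row.frequencies.values()) == pytest.approx(1.0)

    def test_unknown_snp_rejected(self):
        panel = _panel_from_counts({("A", "A"): 2})
        with pytest.raises(ValueError):
            allele_frequencies(panel, "nope")


class TestClassifySite:
    def test_polymorphic_and_monomorphic(self):
        poly = _panel_from_counts({("A", "A"): 1, ("A", "G"): 1})
        mono = _panel_from_counts({("T", "T"): 5})
        assert classify_site(poly, "rs_test") == "polymorphic"
        assert classify_site(mono, "rs_test") == "monomorphic"

    def test_invariant_to_orderings(self):
        p1 = GenotypePanel()
        p1.add(GenotypeCall("a", "m", ("C", "T")))
        p1.add(GenotypeCall("b", "m", ("T", "T")))
        p2 = GenotypePanel()
        p2.add(GenotypeCall("b", "m", ("T", "T")))
        p2.add(GenotypeCall("a", "m", ("T", "C")))  # allele order flipped
        assert classify_site(p1, "m") == classify_site(p2, "m")

    def test_all_missing_rejected(self):
        panel = GenotypePanel()
        panel.add(GenotypeCall("a", "m", None))
        with pytest.raises(ValueError):
            classify_site(panel, "m")


class TestCallVariantsFromConsensus:
    def test_equal_sequences_yield_no_calls(self):
        ref = NucleotideSequence(id="r", residues="ACGTACGTAC")
        cons = NucleotideSequence(id="c", residues="ACGTACGTAC")
        assert call_variants_from_consensus(cons, ref) == []

    def test_ambiguity_code_expands_to_heterozygote(self):
        ref = NucleotideSequence(id="r", residues="AACCAGGTT")
        cons = NucleotideSequence(id="c", residues="AAYCAGGTT")
        (call,) = call_variants_from_consensus(cons, ref)
        assert (call.position, call.ref_allele, call.alt_allele) == (3, "C", "T")

    def test_offset_coordinates(self):
        ref = NucleotideSequence(id="r", residues="TTTTAACCAGGTT")
        cons = NucleotideSequence(id="c", residues="AACCAGGTA")
        calls = call_variants_from_consensus(cons, ref, offset=5)
        assert [(c.position, c.alt_allele) for c in calls] == [(13, "A")]

    def test_length_overrun_rejected(self):
        ref = NucleotideSequence(id="r", residues="ACGT")
        cons = NucleotideSequence(id="c", residues="ACGTA")
        with pytest.raises(ValueError):
            call_variants_from_consensus(cons, ref)

    def test_matches_per_position_brute_force(self):
        rng = random.Random(73)
        ref_str = "".join(rng.choice("ACGT") for _ in range(200))
        cons = list(ref_str)
        expected = []
        for pos in sorted(rng.sample(range(200), 12)):
            ref_base = cons[pos]
            if rng.random() < 0.5:
                alt = rng.choice([b for b in "ACGT" if b != ref_base])
                from paraspec.seqio import iupac_het_code
                cons[pos] = iupac_het_code(ref_base, alt)
                expected.append((pos + 1, ref_base, alt))
            else:
                alt = rng.choice([b for b in "ACGT" if b != ref_base])
                cons[pos] = alt
                expected.append((pos + 1, ref_base, alt))
        ref = NucleotideSequence(id="r", residues=ref_str)
        consensus = NucleotideSequence(id="c", residues="".join(cons))
        calls = call_variants_from_consensus(consensus, ref)
        assert [(c.position, c.ref_allele, c.alt_allele) for c in calls] == expected

    def test_substitution_round_trip(self):
        """Applying the calls back onto the reference reconstructs the
        consensus (heterozygotes as ambiguity codes)."""
        rng = random.Random(74)
        ref_str = "".join(rng.choice("ACGT") for _ in range(150))
        cons = list(ref_str)
        for pos in rng.sample(range(150), 8):
            ref_base = cons[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
            from paraspec.seqio import iupac_het_code
            cons[pos] = iupac_het_code(ref_base, alt)
        ref = NucleotideSequence(id="r", residues=ref_str)
        consensus = NucleotideSequence(id="c", residues="".join(cons))
        calls = call_variants_from_consensus(consensus, ref)
        rebuilt = genostats.apply_variants(ref, calls)
        assert rebuilt.residues == consensus.residues


class TestConcordance:
    def test_identical_lists(self):
        calls = [GenotypeCall(f"S{i}", "m", ("C", "T")) for i in range(48)]
        res = concordance(calls, list(calls))
        assert (res.n, res.s) == (48, 48)
        assert res.discordant == []

    def test_one_discordant_het_vs_hom(self):
        a = [GenotypeCall(f"S{i}", "m", ("C", "T")) for i in range(24)]
        b = [GenotypeCall(f"S{i}", "m", ("C", "T")) for i in range(23)]
        b.append(GenotypeCall("S23", "m", ("T", "T")))
        res = concordance(a, b)
        assert (res.n, res.s) == (24, 23)
        assert res.discordant == [("S23", ("C", "T"), ("T", "T"))]

    def test_shuffle_invariance(self):
        rng = random.Random(79)
        a = [GenotypeCall(f"S{i}", "m", tuple(sorted(rng.choice("CT") + rng.choice("CT"))))
             for i in range(30)]
        b = [GenotypeCall(f"S{i}", "m", tuple(sorted(rng.choice("CT") + rng.choice("CT"))))
             for i in range(30)]
        res1 = concordance(a, b)
        rng.shuffle(a)
        rng.shuffle(b)
        res2 = concordance(a, b)
        assert (res1.n, res1.s, res1.discordant) == (res2.n, res2.s, res2.discordant)

    def test_missing_pairs_excluded_from_n(self):
        a = [GenotypeCall(f"S{i}", "m", ("C", "C")) for i in range(32)]
        b = [GenotypeCall(f"S{i}", "m", ("C", "C") if i >= 2 else None)
             for i in range(32)]
        res = concordance(a, b)
        assert (res.n, res.s) == (30, 30)

    def test_mixed_snps_rejected(self):
        a = [GenotypeCall("S1", "m1", ("C", "C"))]
        b = [GenotypeCall("S1", "m2", ("C", "C"))]
        with pytest.raises(ValueError):
            concordance(a, b)


class TestBetaLowerBound:
    def test_closed_form_at_full_concordance(self):
        for n in (1, 10, 48, 100):
            for c in (0.9, 0.95, 0.99):
                assert beta_lower_bound(n, n, c) == pytest.approx(
                    (1 - c) ** (1 / (n + 1)), abs=1e-10
                )

    def test_matches_quadrature_oracle_small_n(self):
        for n in range(1, 6):
            for s in range(n + 1):
                for c in (0.9, 0.95):
                    got = beta_lower_bound(s, n, c)
                    want = beta_quantile_by_quadrature(s, n, 1 - c)
                    assert got == pytest.approx(want, abs=1e-4)

    def test_monotonic_in_s_and_confidence(self):
        n = 30
        values = [beta_lower_bound(s, n, 0.95) for s in range(n + 1)]
        assert all(x < y for x, y in zip(values, values[1:]))
        confs = [beta_lower_bound(28, n, c) for c in (0.8, 0.9, 0.95, 0.99)]
        assert all(x > y for x, y in zip(confs, confs[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            beta_lower_bound(5, 4, 0.95)
        with pytest.raises(ValueError):
            beta_lower_bound(3, 4, 1.0)


class TestRandomMatchProbability:
    def test_single_het_marker_half(self):
        profile = [GenotypeCall("s", "m1", ("A", "G"))]
        freqs = {"m1": {"A": 0.5, "G": 0.5}}
        assert random_match_probability(profile, freqs) == pytest.approx(0.5)

    def test_product_rule_two_markers(self):
        profile = [GenotypeCall("s", "m1", ("A", "G")),
                   GenotypeCall("s", "m2", ("C", "T"))]
        freqs = {"m1": {"A": 0.5, "G": 0.5}, "m2": {"C": 0.5, "T": 0.5}}
        assert random_match_probability(profile, freqs) == pytest.approx(0.25)

    def test_matches_per_marker_hand_product(self):
        rng = random.Random(83)
        profile, freqs, expected = [], {}, 1.0
        for i in range(9):
            p = rng.uniform(0.1, 0.9)
            freqs[f"m{i}"] = {"A": p, "G": 1 - p}
            genotype = tuple(sorted(rng.choice("AG") + rng.choice("AG")))
            profile.append(GenotypeCall("s", f"m{i}", genotype))
            a, b = genotype
            expected *= (2 if a != b else 1) * freqs[f"m{i}"][a] * freqs[f"m{i}"][b]
        assert random_match_probability(profile, freqs) == pytest.approx(expected)

    def test_unknown_allele_rejected(self):
        profile = [GenotypeCall("s", "m1", ("A", "G"))]
        with pytest.raises(ValueError):
            random_match_probability(profile, {"m1": {"A": 1.0}})


class TestPanelIO:
    def test_round_trip_with_missing(self, tmp_path):
        panel = GenotypePanel()
        panel.add(GenotypeCall("S1", "m", ("C", "T")), population="CEU")
        panel.add(GenotypeCall("S2", "m", None), population="YRI")
        p = tmp_path / "panel.tsv"
        genostats.write_genotype_panel(panel, p)
        back = genostats.read_genotype_panel(p)
        assert back.calls[("S1", "m")].alleles == ("C", "T")
        assert back.calls[("S2", "m")].is_missing
        assert back.populations == {"S1": "CEU", "S2": "YRI"}

    def test_duplicate_call_rejected(self):
        panel = GenotypePanel()
        panel.add(GenotypeCall("S1", "m", ("C", "T")))
        with pytest.raises(ValueError):
            panel.add(GenotypeCall("S1", "m", ("C", "C")))
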