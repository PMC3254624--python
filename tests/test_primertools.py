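import random

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt

from oracles import brute_force_amplicons, brute_force_binding_sites, revcomp
from paraspec import datasets, dupfinder, primertools, synthetic
from paraspec.dupfinder import Interval
from paraspec.primertools import (
    DesignConstraints,
    Primer,
    design_specific_primers,
    find_binding_sites,
    melting_temperature,
    mismatch_count,
    predict_amplicons,
    validate_probe_pair,
)
from paraspec.seqio import NucleotideSequence, SnpRecord, reverse_complement


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestMeltingTemperature:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_reference_implementation(self, seed):
        """Cross-implementation oracle: same published nearest-neighbor
        parameter table computed by Biopython, agreement within 0.5 C."""
        rng = random.Random(seed)
        seq = _random_seq(rng, 20)
        mine = melting_temperature(seq)
        ref = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, dnac1=250, dnac2=250,
                       saltcorr=5)
        assert mine == pytest.approx(ref, abs=0.5)

    def test_gc_substitution_raises_tm(self):
        rng = random.Random(99)
        for _ in range(10):
            seq = list(_random_seq(rng, 20))
            at_positions = [i for i, c in enumerate(seq) if c in "AT"]
            if not at_positions:
                continue
            base_tm = melting_temperature("".join(seq))
            i = rng.choice(at_positions)
            seq[i] = "G" if seq[i] == "A" else "C"
            assert melting_temperature("".join(seq)) > base_tm

    def test_duplex_symmetry(self):
        rng = random.Random(3)
        for _ in range(10):
            seq = _random_seq(rng, 22)
            assert melting_temperature(seq) == pytest.approx(
                melting_temperature(reverse_complement(seq)), abs=1e-9
            )

    def test_rejects_ambiguous_and_short(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTNACGTACG")
        with pytest.raises(ValueError):
            melting_temperature("ACGTACG")


class TestMismatchCount:
    def test_published_forward_primer_audit(self, taqman_locus):
        """The forward amplification primer carries 4 paralogue mismatches
        including its 3'-terminal base."""
        blocks = dupfinder.find_inverted_duplications(taqman_locus.locus)
        cmap = dupfinder.build_coordinate_map(blocks[0])
        rep = primertools.specificity_report(
            datasets.TAQMAN_FORWARD, Interval(*taqman_locus.forward_footprint),
            "+", cmap,
        )
        assert rep.mismatches_vs_paralogue == 4
        assert rep.terminal_3prime_mismatch
        assert rep.mismatch_positions == datasets.TAQMAN_FORWARD_SPECIFICITY_POSITIONS

    def test_published_reverse_primer_audit(self, taqman_locus):
        blocks = dupfinder.find_inverted_duplications(taqman_locus.locus)
        cmap = dupfinder.build_coordinate_map(blocks[0])
        rep = primertools.specificity_report(
            datasets.TAQMAN_REVERSE, Interval(*taqman_locus.reverse_footprint),
            "-", cmap,
        )
        assert rep.mismatches_vs_paralogue == 3
        assert not rep.terminal_3prime_mismatch
        assert rep.mismatch_positions == datasets.TAQMAN_REVERSE_SPECIFICITY_POSITIONS

    def test_identical_site_zero_mismatches(self):
        p = Primer(name="p", sequence="ACGTACGTACGTACG")
        rep = mismatch_count(p, p.sequence)
        assert rep.mismatches_vs_paralogue == 0
        assert not rep.terminal_3prime_mismatch
        assert rep.mismatches_in_last5 == 0

    def test_gap_column_counts_as_mismatch(self):
        p = Primer(name="p", sequence="ACGTACGTACGTACG")
        site = p.sequence[:5] + "-" + p.sequence[6:]
        rep = mismatch_count(p, site)
        assert rep.mismatches_vs_paralogue == 1
        assert rep.mismatch_positions == (6,)

    def test_length_mismatch_rejected(self):
        p = Primer(name="p", sequence="ACGTACGTACGTACG")
        with pytest.raises(ValueError):
            mismatch_count(p, p.sequence[:-1])

    def test_symmetric_under_joint_reverse_complement(self):
        rng = random.Random(13)
        for _ in range(20):
            seq = _random_seq(rng, 18)
            site = list(seq)
            for i in rng.sample(range(18), 3):
                site[i] = rng.choice([b for b in "ACGT" if b != site[i]])
            site = "".join(site)
            p1 = Primer(name="p", sequence=seq)
            p2 = Primer(name="prc", sequence=reverse_complement(seq))
            r1 = mismatch_count(p1, site)
            r2 = mismatch_count(p2, reverse_complement(site))
            assert r1.mismatches_vs_paralogue == r2.mismatches_vs_paralogue


class TestFindBindingSites:
    def test_planted_exact_site(self):
        rng = random.Random(21)
        primer = Primer(name="p", sequence=_random_seq(rng, 20))
        bg = _random_seq(rng, 500)
        template = NucleotideSequence(id="t", residues=bg[:200] + primer.sequence + bg[200:])
        sites = find_binding_sites(primer, template, max_mismatches=0)
        assert [(s.start, s.strand) for s in sites] == [(201, "+")]

    def test_mismatch_threshold(self):
        rng = random.Random(22)
        primer = Primer(name="p", sequence=_random_seq(rng, 20))
        planted = list(primer.sequence)
        for i in (5, 12):
            planted[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[planted[i]]
        template = NucleotideSequence(
            id="t", residues=_random_seq(rng, 150) + "".join(planted) + _random_seq(rng, 150)
        )
        assert find_binding_sites(primer, template, max_mismatches=1) == []
        sites = find_binding_sites(primer, template, max_mismatches=2)
        assert len(sites) == 1 and sites[0].mismatches == 2

    def test_three_prime_anchor_rule(self):
        rng = random.Random(23)
        primer = Primer(name="p", sequence=_random_seq(rng, 20))
        planted = list(primer.sequence)
        planted[-1] = {"A": "C", "C": "G", "G": "T", "T": "A"}[planted[-1]]
        template = NucleotideSequence(
            id="t", residues=_random_seq(rng, 100) + "".join(planted) + _random_seq(rng, 100)
        )
        assert find_binding_sites(primer, template, 1, require_3prime_match=True) == []
        assert len(find_binding_sites(primer, template, 1)) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_scan(self, seed):
        rng = random.Random(seed)
        primer = Primer(name="p", sequence=_random_seq(rng, 8))
        template = NucleotideSequence(id="t", residues=_random_seq(rng, 1000))
        for max_mm in (0, 1, 2):
            got = [
                (s.start, s.strand, s.mismatches)
                for s in find_binding_sites(primer, template, max_mm)
            ]
            assert got == brute_force_binding_sites(primer.sequence, template.residues, max_mm)


class TestPredictAmplicons:
    def test_closed_form_length(self):
        rng = random.Random(31)
        fwd = Primer(name="f", sequence=_random_seq(rng, 20))
        rev = Primer(name="r", sequence=_random_seq(rng, 20))
        bg = _random_seq(rng, 1000)
        # forward footprint at 101-120; reverse site 5' end at position 300
        residues = (
            bg[:100] + fwd.sequence + bg[120:280]
            + reverse_complement(rev.sequence) + bg[300:]
        )
        template = NucleotideSequence(id="t", residues=residues)
        preds = predict_amplicons(fwd, rev, [template])
        assert len(preds) == 1
        assert preds[0].length_bp == 200
        assert preds[0].specific

    def test_specific_despite_lone_forward_site_elsewhere(self):
        rng = random.Random(32)
        fwd = Primer(name="f", sequence=_random_seq(rng, 20))
        rev = Primer(name="r", sequence=_random_seq(rng, 20))
        bg = _random_seq(rng, 600)
        t1 = NucleotideSequence(
            id="t1",
            residues=bg[:100] + fwd.sequence + bg[120:300]
            + reverse_complement(rev.sequence) + bg[320:],
        )
        t2 = NucleotideSequence(
            id="t2", residues=_random_seq(rng, 200) + fwd.sequence + _random_seq(rng, 200)
        )
        preds = predict_amplicons(fwd, rev, [t1, t2])
        assert len(preds) == 1
        assert preds[0].template == "t1"
        assert preds[0].specific

    def test_two_products_not_specific(self):
        rng = random.Random(33)
        fwd = Primer(name="f", sequence=_random_seq(rng, 20))
        rev = Primer(name="r", sequence=_random_seq(rng, 20))
        unit = fwd.sequence + _random_seq(rng, 100) + reverse_complement(rev.sequence)
        template = NucleotideSequence(
            id="t", residues=unit + _random_seq(rng, 300) + unit
        )
        preds = predict_amplicons(fwd, rev, [template], max_product_bp=200)
        assert len(preds) == 2
        assert all(not p.specific for p in preds)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_double_scan(self, seed):
        """Oracle equivalence on random 2 kb templates with short primers
        (short enough to produce incidental sites)."""
        rng = random.Random(seed + 1000)
        fwd = Primer(name="f", sequence=_random_seq(rng, 7))
        rev = Primer(name="r", sequence=_random_seq(rng, 7))
        template = NucleotideSequence(id="t", residues=_random_seq(rng, 2000))
        preds = predict_amplicons(fwd, rev, [template], max_mismatches=0,
                                  max_product_bp=500)
        got = sorted(
            (p.forward_site.five_prime, p.reverse_site.five_prime, p.length_bp)
            for p in preds
        )
        want = brute_force_amplicons(fwd.sequence, rev.sequence, template.residues,
                                     0, 500)
        assert got == want


class TestDesignSpecificPrimers:
    def _fixture(self, identity=94.0, seed=51):
        truth = synthetic.simulate_inverted_duplication(
            seed=seed, identity_percent=identity
        )
        blocks = dupfinder.find_inverted_duplications(truth.sequence)
        (block,) = blocks
        cmap = dupfinder.build_coordinate_map(block)
        target = block.copy_a.start + block.copy_a.length // 2
        return truth, block, cmap, target

    def test_products_cover_target_and_counts_rescore_exactly(self):
        truth, block, cmap, target = self._fixture()
        result = design_specific_primers(target, cmap, truth.sequence)
        assert result.candidates
        for cand in result.candidates:
            fs = cand.forward.target_site
            rs = cand.reverse.target_site
            assert fs.start <= target <= rs.end
            assert cand.product_length == rs.end - fs.start + 1
            # re-scoring through mismatch_count reproduces the counts
            re_f = primertools.specificity_report(
                cand.forward.primer, Interval(fs.start, fs.end), "+", cmap
            )
            assert re_f.mismatches_vs_paralogue == cand.forward.mismatches_vs_paralogue

    def test_top_candidate_covers_planted_mismatch_cluster(self):
        """A dense cluster of paralogue differences just upstream of the
        target must attract the top-ranked forward primer."""
        rng = np.random.default_rng(53)
        bases = np.array(list("ACGT"))
        copy_a = "".join(bases[rng.integers(0, 4, 800)])
        b_read = list(copy_a)
        cluster = range(295, 300)  # 5 differences at offsets 295..299
        for off in cluster:
            b_read[off] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b_read[off]]
        b_forward = reverse_complement("".join(b_read))
        spacer = "".join(bases[rng.integers(0, 4, 400)])
        lead = "".join(bases[rng.integers(0, 4, 200)])
        tail = "".join(bases[rng.integers(0, 4, 200)])
        seq = NucleotideSequence(id="cl", residues=lead + copy_a + spacer + b_forward + tail)
        blocks = dupfinder.find_inverted_duplications(seq)
        (block,) = blocks
        cmap = dupfinder.build_coordinate_map(block)
        target = 200 + 400  # 100 bp downstream of the cluster
        result = design_specific_primers(target, cmap, seq)
        top = result.candidates[0]
        fs = top.forward.target_site
        cluster_positions = {200 + off + 1 for off in cluster}
        assert cluster_positions & set(range(fs.start, fs.end + 1))
        assert top.forward.mismatches_vs_paralogue >= 4

    def test_identical_copies_warn_no_specificity(self):
        truth, block, cmap, target = self._fixture(identity=100.0, seed=57)
        result = design_specific_primers(target, cmap, truth.sequence)
        assert result.candidates
        assert all(c.total_mismatches == 0 for c in result.candidates)
        assert any("no specificity achievable" in w for w in result.warnings)

    def test_ranking_deterministic(self):
        truth, block, cmap, target = self._fixture()
        r1 = design_specific_primers(target, cmap, truth.sequence)
        r2 = design_specific_primers(target, cmap, truth.sequence)
        key = lambda r: [
            (c.forward.primer.sequence, c.reverse.primer.sequence) for c in r.candidates
        ]
        assert key(r1) == key(r2)

    def test_target_outside_block_rejected(self):
        truth, block, cmap, target = self._fixture()
        with pytest.raises(ValueError):
            design_specific_primers(5, cmap, truth.sequence)


class TestValidateProbePair:
    def test_published_probes_discriminate_the_snp(self, taqman_locus):
        results = validate_probe_pair(
            [datasets.TAQMAN_PROBE_VIC, datasets.TAQMAN_PROBE_FAM],
            taqman_locus.snp, taqman_locus.template_b,
        )
        alleles = {r.probe_name: r.matched_allele for r in results}
        assert alleles == {"probe_VIC": "T", "probe_FAM": "C"}
        for r in results:
            assert r.footprint.start <= taqman_locus.snp.position <= r.footprint.end

    def test_synthetic_pair_one_mismatch_structure(self):
        rng = random.Random(61)
        bg = _random_seq(rng, 300)
        snp_pos = 150
        template = NucleotideSequence(id="t", residues=bg[:149] + "C" + bg[150:])
        probe_c = Primer(name="pc", sequence=template.residues[140:160])
        t_variant = template.residues[:149] + "T" + template.residues[150:]
        probe_t = Primer(name="pt", sequence=t_variant[140:160])
        snp = SnpRecord(id="s", position=snp_pos, ref_allele="C", alt_allele="T")
        results = validate_probe_pair([probe_c, probe_t], snp, template)
        assert {r.matched_allele for r in results} == {"C", "T"}
        assert all(r.discriminating_offset == 10 for r in results)

    def test_probe_not_overlapping_snp_fails(self):
        rng = random.Random(62)
        template = NucleotideSequence(id="t", residues=_random_seq(rng, 300))
        snp = SnpRecord(id="s", position=150,
                        ref_allele=template.residues[149],
                        alt_allele={"A": "G", "G": "A", "C": "T", "T": "C"}[template.residues[149]])
        away = Primer(name="away", sequence=template.residues[200:220])
        other = Primer(name="cover", sequence=template.residues[140:160])
        with pytest.raises(ValueError, match="away"):
            validate_probe_pair([away, other], snp, template)
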