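"""Diagnostic screen, amplicon extraction, cut-site scanning, digestion,
CAPS conversion and match-rate validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import capsforge as cf
from capsforge.diagnostic_caps import (
    AmbiguousAmpliconError,
    ScreenConfig,
    compute_match_rate,
    diagnostic_screen,
    digest_fragments,
    extract_amplicon,
    find_cut_sites,
    snp_to_caps,
)
from capsforge.genotype_io import IUPAC_CODES, EnzymeDefinition, GenotypeCall
from conftest import make_matrix

ENZYMES = {e.name: e for e in cf.read_enzyme_table()}


class TestScreen:
    def _screen(self, column, toy_panel, n_target=9, n_other=15, **kw):
        m = make_matrix([column])
        panel = toy_panel(m.samples[:n_target], m.samples[n_target:])
        return diagnostic_screen(m, panel, ScreenConfig(**kw))

    def test_fixed_groups_with_different_alleles_pass(self, toy_panel):
        hits = self._screen(["A/A"] * 9 + ["G/G"] * 15, toy_panel)
        assert len(hits) == 1
        assert hits[0].target_allele == "A" and hits[0].other_allele == "G"
        assert hits[0].n_target_concordant == 9
        assert hits[0].n_other_concordant == 15

    def test_heterozygote_in_target_group_disqualifies(self, toy_panel):
        hits = self._screen(["A/A"] * 8 + ["A/G"] + ["G/G"] * 15, toy_panel)
        assert hits == []

    def test_monomorphic_across_everyone_fails(self, toy_panel):
        assert self._screen(["A/A"] * 24, toy_panel) == []

    def test_missing_calls_do_not_disqualify(self, toy_panel):
        hits = self._screen(["A/A"] * 7 + ["-/-", "A/-"] + ["G/G"] * 15, toy_panel)
        assert len(hits) == 1

    def test_tolerated_discordance_budget(self, toy_panel):
        col = ["A/A"] * 8 + ["G/G"] + ["G/G"] * 15
        assert self._screen(col, toy_panel) == []
        assert len(self._screen(col, toy_panel, max_discordant_per_group=1)) == 1

    def test_rescreening_is_a_fixed_point(self, noiseless_bundle):
        m, panel = noiseless_bundle["matrix"], noiseless_bundle["panel"]
        hits = diagnostic_screen(m, panel)
        keys = {(h.chrom, h.pos) for h in hits}
        mask = m.variants.set_index(["chrom", "pos"]).index.isin(keys)
        again = diagnostic_screen(m.subset_variants(mask), panel)
        assert {(h.chrom, h.pos) for h in again} == keys


class TestAmplicon:
    REF = {"Chr1": "".join(np.random.default_rng(0).choice(list("ACGT"), 600))}

    def test_flank_arithmetic(self):
        amp = extract_amplicon(self.REF, "Chr1", 300, ("A", "G"), flank_bp=77)
        assert amp.length == 155  # 77 + 1 + 77
        assert amp.snp_offset == 77
        assert amp.sequences["A"][77] == "A" and amp.sequences["G"][77] == "G"
        assert amp.sequences["A"][:77] == amp.sequences["G"][:77]

    def test_primer_pair_defines_amplicon(self):
        seq = self.REF["Chr1"]
        fwd = seq[249:269]
        rev_rc = seq[330:350]
        from capsforge.genotype_io import reverse_complement
        amp = extract_amplicon(self.REF, "Chr1", 300, ("A", "C"),
                               primer_pair=(fwd, reverse_complement(rev_rc)))
        # amplicon spans 1-based [250, 350] inclusive
        assert amp.start == 250 and amp.length == 101
        assert amp.snp_offset == 50

    def test_absent_reverse_primer_is_an_error(self):
        with pytest.raises(AmbiguousAmpliconError, match="reverse"):
            extract_amplicon(self.REF, "Chr1", 300, ("A", "C"),
                             primer_pair=(self.REF["Chr1"][249:269], "GGGGGGGGGGGGGGGG"))

    def test_tiny_amplicon_warns(self):
        with pytest.warns(UserWarning, match="guard range"):
            extract_amplicon(self.REF, "Chr1", 300, ("A", "C"), flank_bp=10)


def brute_force_cuts(seq, enzyme):
    """Independent oracle: test every window on both strands by IUPAC
    letter-set membership."""
    from capsforge.genotype_io import reverse_complement

    def matches(window, motif):
        return len(window) == len(motif) and all(
            b in IUPAC_CODES[m] for b, m in zip(window, motif))

    k = len(enzyme.recognition)
    cuts = set()
    for s in range(len(seq) - k + 1):
        w = seq[s:s + k]
        if matches(w, enzyme.recognition):
            cuts.add(s + enzyme.cut_offset_top)
        if matches(w, reverse_complement(enzyme.recognition)):
            cuts.add(s + k - enzyme.cut_offset_bottom)
    return sorted(c for c in cuts if 0 < c < len(seq))


class TestCutSites:
    def test_ecori_single_site(self):
        assert find_cut_sites("AAAGAATTCAAA", ENZYMES["EcoRI"]) == [4]  # G^AATTC

    def test_motif_free_sequence(self):
        assert find_cut_sites("ACACACACAC", ENZYMES["EcoRI"]) == []

    def test_degenerate_apeki_both_expansions(self):
        seq = "TTTGCAGCTTTTTGCTGCTTT"  # G^CWGC with W = A and W = T
        cuts = find_cut_sites(seq, ENZYMES["ApeKI"])
        assert cuts == brute_force_cuts(seq, ENZYMES["ApeKI"])
        assert len(cuts) == 2

    def test_type_iis_cut_outside_recognition(self):
        # BsrI ACTGG cuts 1 nt past the motif end on the top strand
        seq = "TTTTTACTGGTTTTT"
        assert find_cut_sites(seq, ENZYMES["BsrI"]) == [5 + 6]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 1000))))
        for name in ("EcoRI", "ApeKI", "BsrI", "BbsI", "EcoNI", "AccI"):
            assert find_cut_sites(seq, ENZYMES[name]) == brute_force_cuts(seq, ENZYMES[name])

    def test_agrees_with_reference_catalog_implementation(self):
        from Bio import Restriction
        from Bio.Seq import Seq

        rng = np.random.default_rng(123)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=700))
            for e in ENZYMES.values():
                ours = find_cut_sites(seq, e)
                theirs = sorted(p - 1 for p in getattr(Restriction, e.name).search(Seq(seq)))
                assert ours == [c for c in theirs if 0 < c < len(seq)], e.name


class TestDigestion:
    @pytest.mark.parametrize("length,cuts,expect", [
        (155, [54], [54, 101]),     # one cut: the classic two-band pattern
        (410, [119], [119, 291]),
        (200, [], [200]),
        (100, [20, 70], [20, 50, 30]),
    ])
    def test_fragments(self, length, cuts, expect):
        assert digest_fragments(length, cuts) == expect

    def test_out_of_range_cut_rejected(self):
        with pytest.raises(ValueError):
            digest_fragments(100, [100])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(length=st.integers(2, 5000),
           data=st.data())
    def test_conservation_on_random_cut_sets(self, length, data):
        cuts = data.draw(st.lists(st.integers(1, length - 1), max_size=12))
        frags = digest_fragments(length, cuts)
        assert sum(frags) == length
        assert all(f > 0 for f in frags)


class TestSnpToCaps:
    def _diag(self, chrom="Chr1", pos=300, target="A", other="G"):
        from capsforge.diagnostic_caps import DiagnosticSNP
        return DiagnosticSNP(chrom, pos, target, other)

    def test_allele_creating_hindiii_site(self):
        # the A allele completes AAGCTT (HindIII) that the G allele breaks
        left = "TGCATGCATG" * 6                       # 60 nt, HindIII-free
        right = "GCATGCATGC" * 6
        seq = left + "A" + "G" + "GCTT" + right        # reference carries G
        ref = {"Chr1": seq}
        snp_pos = 62                                   # 1-based: the G above
        amp = extract_amplicon(ref, "Chr1", snp_pos, ("A", "G"), flank_bp=40)
        assert "AAGCTT" in amp.sequences["A"]
        assert "AAGCTT" not in amp.sequences["G"]
        cands = snp_to_caps(self._diag(pos=snp_pos, target="A", other="G"),
                            amp, [ENZYMES["HindIII"]])
        assert len(cands) == 1 and cands[0].enzyme == "HindIII"
        assert len(cands[0].fragments["A"]) == 2
        assert cands[0].fragments["G"] == (amp.length,)
        assert sum(cands[0].fragments["A"]) == amp.length

    def test_snp_far_from_any_motif(self):
        ref = {"Chr1": "AC" * 200}
        amp = extract_amplicon(ref, "Chr1", 200, ("A", "G"), flank_bp=60)
        assert snp_to_caps(self._diag(pos=200), amp, list(ENZYMES.values())) == []

    def test_degenerate_position_change_is_not_a_candidate(self):
        # ApeKI tolerates both W alleles (A/T) at its center: not allele-differential
        left = "CGCGCGCGCG" * 5
        right = "GCCGCGCGCG" * 5
        seq = left + "GC" + "A" + "GC" + right
        ref = {"Chr1": seq}
        pos = len(left) + 3  # the W position
        amp = extract_amplicon(ref, "Chr1", pos, ("A", "T"), flank_bp=30)
        cands = snp_to_caps(self._diag(pos=pos, target="A", other="T"),
                            amp, [ENZYMES["ApeKI"]])
        assert cands == []
        for allele in ("A", "T"):
            assert brute_force_cuts(amp.sequences[allele], ENZYMES["ApeKI"]) \
                == find_cut_sites(amp.sequences[allele], ENZYMES["ApeKI"])


class TestMatchRate:
    def H(self, sym):
        from capsforge.genotype_io import _expand_symbol
        return _expand_symbol(sym)

    def test_identical_vectors(self):
        a = [self.H("G")] * 24
        r = compute_match_rate(a, list(a))
        assert r.match_rate == 1.0 and r.compared == 24

    def test_two_discordant_of_24_rounds_to_092(self):
        a = [self.H("T")] * 24
        b = [self.H("T")] * 22 + [self.H("C"), self.H("Y")]
        assert compute_match_rate(a, b).match_rate == 0.92  # 22/24 = 0.9167

    def test_half_missing_consistent_counts_concordant(self):
        a = [self.H("G")] * 23 + [GenotypeCall("G", ".")]
        b = [self.H("G")] * 24
        r = compute_match_rate(a, b)
        assert r.match_rate == 1.0 and r.compared == 24

    def test_half_missing_contradiction_is_discordant(self):
        a = [self.H("G")] * 23 + [GenotypeCall("A", ".")]
        b = [self.H("G")] * 24
        assert compute_match_rate(a, b).match_rate == 0.96

    def test_fully_missing_pair_excluded(self):
        a = [self.H("G")] * 3 + [self.H("-")]
        b = [self.H("G")] * 3 + [self.H("-")]
        r = compute_match_rate(a, b)
        assert r.compared == 3 and r.excluded_missing == 1

    def test_all_missing_undefined(self):
        with pytest.raises(ValueError):
            compute_match_rate([self.H("-")], [self.H("-")])
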