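import numpy as np
import pandas as pd
import pytest
from scipy import stats

import plastedit as pe
from plastedit.caller import CallerParams

from conftest import make_pileup
from _oracles import brute_force_call, random_pileup_frame


class TestCallRules:
    def test_clear_ctu_site_efficiency_and_pvalue(self):
        """DNA C*30; RNA fwd clean T*24, C*6: a C-to-U call at efficiency
        0.80 with the exact binomial tail p-value."""
        pl = make_pileup([{"pos": 1, "ref": "C", "dna": {"C": 30},
                           "fwd_clean": {"T": 24, "C": 6}}])
        (s,) = pe.call_sites(pl)
        assert s.type == "C-to-U" and s.strand == "+"
        assert s.efficiency == pytest.approx(0.80)
        assert s.p_value == pytest.approx(stats.binom.sf(23, 30, 0.001))
        assert s.p_value < 1e-3

    def test_polymorphism_rejected(self):
        """DNA C*20, T*10: major-allele fraction 0.667 < 0.95, no call."""
        pl = make_pileup([{"pos": 1, "ref": "C", "dna": {"C": 20, "T": 10},
                           "fwd_clean": {"T": 25, "C": 5}}])
        assert pe.call_sites(pl) == []

    def test_reference_only_rna_silent(self):
        pl = make_pileup([{"pos": i, "ref": "C", "dna": {"C": 30},
                           "fwd_clean": {"C": 40}} for i in range(1, 6)])
        assert pe.call_sites(pl) == []

    def test_dna_consensus_mismatch_skipped(self):
        """Pure non-reference DNA consensus: possible assembly error,
        never called."""
        pl = make_pileup([{"pos": 1, "ref": "C", "dna": {"T": 30},
                           "fwd_clean": {"T": 40}}])
        assert pe.call_sites(pl) == []

    def test_minus_strand_site_complemented(self):
        """Edited reads on the reverse orientation: genomic G->A reads a
        C-to-U event on the transcribed strand."""
        pl = make_pileup([{"pos": 1, "ref": "G", "dna": {"G": 30},
                           "rev_clean": {"A": 24, "G": 6}}])
        (s,) = pe.call_sites(pl)
        assert s.strand == "-" and s.type == "C-to-U"
        assert s.ref_sense == "C" and s.edit_sense == "T"

    def test_strand_purity_suppresses_ambiguous(self):
        """Edited base spread across both orientations fails purity."""
        pl = make_pileup([{"pos": 1, "ref": "C", "dna": {"C": 30},
                           "fwd_clean": {"T": 20, "C": 10},
                           "rev_clean": {"T": 20, "C": 10}}])
        assert pe.call_sites(pl) == []

    def test_min_efficiency_floor(self):
        pl = make_pileup([{"pos": 1, "ref": "C", "dna": {"C": 30},
                           "fwd_clean": {"T": 4, "C": 96}}])
        assert pe.call_sites(pl) == []


class TestRescue:
    def test_rescued_site_from_all_pool(self):
        """Clean depth 2 < 10 but the indel-inclusive pool supports a
        C-to-U at efficiency 0.75."""
        pl = make_pileup([{"pos": 1, "ref": "C", "dna": {"C": 30},
                           "fwd_clean": {"T": 2},
                           "fwd_all": {"T": 15, "C": 5}}])
        (s,) = pe.call_sites(pl)
        assert s.rescued and s.efficiency == pytest.approx(0.75)

    def test_clean_pass_not_duplicated(self):
        pl = make_pileup([{"pos": 1, "ref": "C", "dna": {"C": 30},
                           "fwd_clean": {"T": 24, "C": 6},
                           "fwd_all": {"T": 30, "C": 8}}])
        sites = pe.call_sites(pl)
        assert len(sites) == 1 and not sites[0].rescued

    def test_dna_rejection_is_final(self):
        pl = make_pileup([{"pos": 1, "ref": "C", "dna": {"C": 20, "T": 10},
                           "fwd_clean": {"T": 2},
                           "fwd_all": {"T": 30, "C": 5}}])
        assert pe.call_sites(pl) == []

    def test_rescue_disabled(self):
        pl = make_pileup([{"pos": 1, "ref": "C", "dna": {"C": 30},
                           "fwd_clean": {"T": 2},
                           "fwd_all": {"T": 15, "C": 5}}])
        assert pe.call_sites(pl, CallerParams(rescue_enabled=False)) == []


class TestClassifyAndSupport:
    def _site(self, pos, strand, ref_sense, edit_sense):
        return pe.EditingSite("p", pos, strand, ref_sense, edit_sense,
                              0.5, 30, 30, 1e-9)

    def test_type_labels(self):
        assert self._site(1, "+", "C", "T").type == "C-to-U"
        assert self._site(1, "-", "C", "T").type == "C-to-U"
        assert self._site(1, "+", "G", "A").type == "G-to-A"

    def test_antisense_flagged(self):
        gene = pe.GeneModel("g1", "CDS", "-", [(1, 300)])
        s = pe.classify_type(self._site(100, "+", "C", "T"), [gene])
        assert s.antisense_candidate

    def test_sense_agreement_unflagged(self):
        gene = pe.GeneModel("g1", "CDS", "+", [(1, 300)])
        s = pe.classify_type(self._site(100, "+", "C", "T"), [gene])
        assert not s.antisense_candidate

    @pytest.mark.parametrize("ctu_pos,same_strand,expected", [
        (1100, True, True),    # within 150 bp
        (1150, True, True),    # inclusive boundary
        (1151, True, False),   # just beyond
        (1100, False, False),  # opposite strand
    ])
    def test_gta_cooccurrence_window(self, ctu_pos, same_strand, expected):
        gta = self._site(1000, "+", "G", "A")
        ctu = self._site(ctu_pos, "+" if same_strand else "-", "C", "T")
        pe.flag_gta_support([gta, ctu])
        assert gta.gta_supported is expected


class TestProperties:
    def test_threshold_monotonicity(self):
        """Raising any threshold never increases the number of calls."""
        rng = np.random.default_rng(5)
        pl = pe.Pileup(random_pileup_frame(rng, 150), 4)
        base = CallerParams()
        n0 = len(pe.call_sites(pl, base))
        stricter = [
            CallerParams(min_dna_depth=20), CallerParams(min_rna_depth=20),
            CallerParams(min_edited_reads=6),
            CallerParams(dna_major_allele_min_fraction=0.99),
            CallerParams(alpha=1e-6), CallerParams(min_efficiency=0.2),
            CallerParams(strand_purity=0.99),
        ]
        for p in stricter:
            assert len(pe.call_sites(pl, p)) <= n0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        """On small pileups the vectorised caller equals an exhaustive
        independent application of the rule set."""
        rng = np.random.default_rng(seed)
        pl = pe.Pileup(random_pileup_frame(rng, 200), 4)
        params = CallerParams()
        got = {(s.pos, s.strand, s.edit_sense, s.rescued)
               for s in pe.call_sites(pl, params)}
        expect = brute_force_call(pl, params)
        assert got == expect

    def test_efficiency_is_exact_ratio(self, small_dataset):
        _, _, _, _, pileup = small_dataset
        for s in pe.call_sites(pileup):
            assert 0.0 <= s.efficiency <= 1.0
            k = round(s.efficiency * s.rna_depth)
            assert abs(s.efficiency - k / s.rna_depth) < 1e-12
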