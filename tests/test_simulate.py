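import numpy as np
import pandas as pd
import pytest

import plastedit as pe
from plastedit.core import ValidationError
from plastedit.simulate import PlantedSite, SimTruth


class TestReference:
    def test_invariants(self, small_dataset):
        _, genome, genes, _, _ = small_dataset
        spans = sorted(g.span for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2, "genes overlap or lack an intergenic gap"
        for g in genes:
            if g.biotype == "CDS":
                seq = g.spliced_sequence(genome)
                assert len(seq) % 3 == 0 and not g.partial
                assert seq.startswith("ATG") and seq[-3:] in {"TAA", "TAG", "TGA"}
                internal = {seq[i:i + 3] for i in range(3, len(seq) - 3, 3)}
                assert internal.isdisjoint({"TAA", "TAG", "TGA"})

    def test_zero_genes_pure_intergenic(self):
        cfg = pe.SimConfig(genome_length=2000, n_cds=0, n_trna=0, n_rrna=0,
                           n_ctu_sites=0, n_gta_sites=0,
                           polymorphism_decoy_count=0, indel_adjacent_count=0)
        genome, genes = pe.simulate_reference(cfg)
        assert genes == [] and genome.length == 2000

    def test_determinism(self):
        cfg = pe.SimConfig(genome_length=8000, n_cds=5, seed=3)
        a = pe.simulate_dataset(cfg)
        b = pe.simulate_dataset(cfg)
        assert a[0].sequence == b[0].sequence
        assert a[2].frame().equals(b[2].frame())
        assert a[3].frame.equals(b[3].frame)

    def test_infeasible_packing_errors(self):
        cfg = pe.SimConfig(genome_length=2000, n_cds=18)
        with pytest.raises(ValidationError, match="genome"):
            pe.simulate_reference(cfg)


class TestPlanting:
    def test_zero_sites_empty_truth(self):
        cfg = pe.SimConfig(genome_length=8000, n_cds=5, n_ctu_sites=0,
                           n_gta_sites=0, polymorphism_decoy_count=0)
        genome, genes = pe.simulate_reference(cfg)
        truth = pe.plant_sites(genome, genes, cfg)
        assert truth.sites == []

    def test_minus_strand_ctu_is_genomic_g(self, small_dataset):
        _, genome, genes, truth, _ = small_dataset
        for s in truth.sites:
            genomic = genome.sequence[s.pos - 1]
            if s.type == "C-to-U":
                assert genomic == ("C" if s.strand == "+" else "G")
            else:
                assert genomic == ("G" if s.strand == "+" else "C")

    def test_positions_unique_and_decoys_disjoint(self, small_dataset):
        _, _, _, truth, _ = small_dataset
        pos = [s.pos for s in truth.sites]
        assert len(pos) == len(set(pos))
        assert set(pos).isdisjoint(truth.decoy_positions)

    def test_minus_one_pyrimidine_bias_recovered(self):
        """Planted C-to-U sites carry the configured -1 pyrimidine bias
        (binomial check at n=100, fixed seed)."""
        cfg = pe.SimConfig(genome_length=30_000, n_ctu_sites=100, n_gta_sites=0,
                           polymorphism_decoy_count=0, indel_adjacent_count=0,
                           seed=23)
        genome, genes = pe.simulate_reference(cfg)
        truth = pe.plant_sites(genome, genes, cfg)
        gm = {g.gene_id: g for g in genes}
        n_pyr = 0
        for s in truth.sites:
            g = gm[s.gene_id]
            sense = g.spliced_sequence(genome)
            sp = g.spliced_position(s.pos)
            n_pyr += sense[sp - 2] in "CT"
        frac = n_pyr / len(truth.sites)
        p = cfg.ctu_pyrimidine_bias
        sd = np.sqrt(p * (1 - p) / len(truth.sites))
        assert abs(frac - p) <= 3 * sd

    def test_insufficient_positions_error(self):
        cfg = pe.SimConfig(genome_length=3000, n_cds=1, n_trna=0, n_rrna=0,
                           cds_length_range=(300, 300), n_ctu_sites=500)
        genome, genes = pe.simulate_reference(cfg)
        with pytest.raises(ValidationError, match="eligible"):
            pe.plant_sites(genome, genes, cfg)


class TestPileupSimulation:
    def _one_site_setup(self, efficiency, rna_depth=50, e=0.0):
        cfg = pe.SimConfig(genome_length=5000, n_cds=3, n_trna=0, n_rrna=0,
                           n_ctu_sites=0, n_gta_sites=0, error_rate=e,
                           rna_depth=rna_depth, polymorphism_decoy_count=0,
                           indel_adjacent_count=0, seed=7)
        genome, genes = pe.simulate_reference(cfg)
        g = next(g for g in genes if g.strand == "+")
        sense = g.spliced_sequence(genome)
        sp = sense.index("C", 3) + 1
        pos = g.exons[0][0] + sp - 1
        site = PlantedSite(chrom=genome.id, pos=pos, strand="+", type="C-to-U",
                           efficiency=efficiency, gene_id=g.gene_id)
        truth = SimTruth(sites=[site], decoy_positions=[])
        pileup = pe.simulate_pileups(genome, genes, truth, cfg,
                                     np.random.default_rng(99))
        return site, pileup

    def test_full_efficiency_no_error_all_edited(self):
        site, pileup = self._one_site_setup(1.0, e=0.0)
        row = pileup.frame[pileup.frame.pos == site.pos].iloc[0]
        assert row["rna_fwd_clean_T"] > 0 and row["rna_fwd_clean_C"] == 0

    def test_observed_fraction_tracks_efficiency(self):
        site, pileup = self._one_site_setup(0.8, rna_depth=1000, e=0.0)
        row = pileup.frame[pileup.frame.pos == site.pos].iloc[0]
        n = row["rna_fwd_clean_T"] + row["rna_fwd_clean_C"]
        frac = row["rna_fwd_clean_T"] / n
        assert abs(frac - 0.8) <= 3 * np.sqrt(0.8 * 0.2 / n)

    def test_indel_suppression_depletes_clean_pool(self):
        cfg = pe.SimConfig(genome_length=12_000, n_cds=8, n_ctu_sites=30,
                           n_gta_sites=0, indel_adjacent_count=30,
                           clean_suppression=0.9, polymorphism_decoy_count=0,
                           seed=13)
        genome, genes, truth, pileup = pe.simulate_dataset(cfg)
        ratios = []
        for s in truth.sites:
            row = pileup.frame[pileup.frame.pos == s.pos].iloc[0]
            allc = sum(row[f"rna_fwd_all_{b}"] + row[f"rna_rev_all_{b}"] for b in "ACGT")
            clean = sum(row[f"rna_fwd_clean_{b}"] + row[f"rna_rev_clean_{b}"] for b in "ACGT")
            ratios.append(clean / allc)
        assert abs(np.mean(ratios) - 0.1) < 0.03

    def test_no_sites_no_error_caller_silent(self):
        cfg = pe.SimConfig(genome_length=8000, n_cds=5, n_ctu_sites=0,
                           n_gta_sites=0, error_rate=0.0,
                           polymorphism_decoy_count=0, indel_adjacent_count=0)
        _, _, _, pileup = pe.simulate_dataset(cfg)
        assert pe.call_sites(pileup) == []


class TestSiteMatrix:
    def test_determinism(self):
        tree = pe.default_tree()
        a = pe.simulate_site_matrix(tree, 0.5, 1.0, 50, seed=4)
        b = pe.simulate_site_matrix(tree, 0.5, 1.0, 50, seed=4)
        assert a.equals(b)

    def test_loss_dominated_limit(self):
        tree = pe.read_tree("((A:5,B:5):5,C:5);")
        m = pe.simulate_site_matrix(tree, 0.01, 100.0, 300, seed=1)
        assert m.to_numpy().mean() < 0.01

    def test_symmetric_rates_stationary_half(self):
        tree = pe.read_tree("((A:50,B:50):50,C:50);")
        m = pe.simulate_site_matrix(tree, 1.0, 1.0, 4000, seed=2)
        freq = m.to_numpy().mean()
        assert abs(freq - 0.5) < 0.05
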