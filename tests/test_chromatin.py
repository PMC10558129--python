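"""Window RPKM, TSS metaprofiles, replicate peak consensus, feature
assignment and the nucleosome-occupancy proxy."""

import numpy as np
import pandas as pd
import pytest

from stemchrom import chromatin
from stemchrom.chromatin import (assign_feature, atac_h3k4_ratio, consensus_peaks,
                                 max_signal_region, nucleosome_occupancy,
                                 tss_metaprofile, tss_windows, window_rpkm)


def frame(rows, cols=("contig", "start", "end")):
    return pd.DataFrame(rows, columns=list(cols))


class TestWindowRPKM:
    def test_formula(self):
        frags = frame([("c", 1000, 1100)])
        win = frame([("g", "c", 500, 2500)], cols=("gene_id", "contig", "start", "end"))
        rpkm = window_rpkm(frags, win, library_size=1_000_000)
        assert rpkm.iloc[0] == pytest.approx(0.5)

    def test_empty_fragments_give_zero(self):
        win = frame([("g", "c", 0, 2000)], cols=("gene_id", "contig", "start", "end"))
        rpkm = window_rpkm(frame([]), win, library_size=10)
        assert rpkm.iloc[0] == 0.0

    def test_zero_library_rejected(self):
        win = frame([("g", "c", 0, 2000)], cols=("gene_id", "contig", "start", "end"))
        with pytest.raises(ValueError):
            window_rpkm(frame([]), win, library_size=0)

    def test_counts_match_brute_force_overlap(self, rng):
        starts = rng.integers(0, 5000, 100)
        frags = frame([("c", s, s + rng.integers(30, 400)) for s in starts])
        wins = frame([(f"g{i}", "c", int(a), int(a) + 500)
                      for i, a in enumerate(rng.integers(0, 5000, 20))],
                     cols=("gene_id", "contig", "start", "end"))
        rpkm = window_rpkm(frags, wins, library_size=1000)
        for _, w in wins.iterrows():
            brute = sum(1 for _, f in frags.iterrows()
                        if f["start"] < w["end"] and f["end"] > w["start"])
            assert rpkm.loc[w["gene_id"]] == pytest.approx(brute * 1e9 / (500 * 1000))

    def test_additive_over_disjoint_fragment_subsets(self, rng):
        frags = frame([("c", int(s), int(s) + 100) for s in rng.integers(0, 3000, 60)])
        win = frame([("g", "c", 500, 2500)], cols=("gene_id", "contig", "start", "end"))
        total = window_rpkm(frags, win, library_size=100).iloc[0]
        a = window_rpkm(frags.iloc[:30], win, library_size=100).iloc[0]
        b = window_rpkm(frags.iloc[30:], win, library_size=100).iloc[0]
        assert total == pytest.approx(a + b)


def gene_row(gene_id, contig, start, end, strand):
    return {"gene_id": gene_id, "contig": contig, "start": start, "end": end,
            "strand": strand}


class TestTSSMetaprofile:
    def test_uniform_coverage_is_flat(self):
        frags = frame([("c", s, s + 100) for s in range(0, 20000, 10)])
        genes = pd.DataFrame([gene_row("g", "c", 10000, 12000, "+")])
        prof = tss_metaprofile(frags, genes, library_size=len(frags))
        assert prof.values.max() / prof.values.min() < 1.05

    def test_minus_strand_mass_flips_upstream(self):
        # fragment 150 bp 5' of a minus-strand TSS lies at higher coordinates
        tss = 5000
        genes = pd.DataFrame([gene_row("g", "c", 4000, tss + 1, "-")])
        frags = frame([("c", tss + 150, tss + 170)])
        prof = tss_metaprofile(frags, genes, library_size=1)
        mass = prof.positions[prof.values > 0]
        assert (mass < 0).all()
        assert abs(mass.mean() + 155) < 15

    def test_gene_order_invariance(self, small_genome, small_atac):
        genome, _ = small_genome
        frags = small_atac.for_sample("brain")
        genes = genome.genes.head(10)
        a = tss_metaprofile(frags, genes, library_size=len(frags))
        b = tss_metaprofile(frags, genes.iloc[::-1], library_size=len(frags))
        assert np.allclose(a.values, b.values)

    def test_planted_architectures_recovered(self, small_genome, small_atac):
        genome, truth = small_genome
        cls = truth.gene_classes
        frags = small_atac.for_sample("brain")
        brain = genome.genes[genome.genes["gene_id"].isin(cls[cls == "brain"].index)]
        const = genome.genes[genome.genes["gene_id"].isin(cls[cls == "constitutive"].index)]
        am_brain = tss_metaprofile(frags, brain, library_size=len(frags)).argmax_position()
        am_const = tss_metaprofile(frags, const, library_size=len(frags)).argmax_position()
        assert -300 <= am_brain <= -100
        assert -50 <= am_const <= 50


class TestRatio:
    def test_equal_signals_give_zero(self):
        r = atac_h3k4_ratio(pd.Series([5.0]), pd.Series([5.0]))
        assert r.iloc[0] == 0.0

    def test_arithmetic(self):
        r = atac_h3k4_ratio(pd.Series([4.0]), pd.Series([16.0]), pseudocount=1.0)
        assert r.iloc[0] == pytest.approx(np.log2(5 / 17))

    def test_negative_rpkm_rejected(self):
        with pytest.raises(ValueError):
            atac_h3k4_ratio(pd.Series([-1.0]), pd.Series([1.0]))

    def test_constitutive_below_tissue_in_matching_isolation(
            self, small_genome, small_atac, small_plan):
        from stemchrom import simulate

        genome, truth = small_genome
        k4 = simulate.generate_fragments(small_plan, genome, truth, "H3K4me3")
        cls = truth.gene_classes
        win = tss_windows(genome.genes, upstream=1000, downstream=1000)
        a = small_atac.for_sample("brain")
        h = k4.for_sample("brain")
        ar = window_rpkm(a, win, library_size=len(a))
        kr = window_rpkm(h, win, library_size=len(h))
        ratio = atac_h3k4_ratio(ar, kr)
        tissue_med = ratio[cls.reindex(ratio.index) == "brain"].median()
        const_med = ratio[cls.reindex(ratio.index) == "constitutive"].median()
        assert const_med < tissue_med


def peaks(rows):
    return pd.DataFrame(rows, columns=["contig", "start", "end", "neg_log10_p"])


class TestConsensusPeaks:
    def test_peak_in_all_replicates_retained(self):
        rep = peaks([("c", 100, 200, 5.0)])
        reps = [rep.assign(neg_log10_p=v) for v in (5.0, 6.0, 7.0)]
        out = consensus_peaks(reps)
        assert len(out) == 1 and out.iloc[0]["start"] == 100

    def test_peak_in_two_of_three_dropped(self):
        rep = peaks([("c", 100, 200, 9.0)])
        out = consensus_peaks([rep, rep, peaks([])])
        assert out.empty

    def test_score_exactly_four_dropped(self):
        rep = peaks([("c", 100, 200, 5.0)])
        out = consensus_peaks([rep, rep, peaks([("c", 100, 200, 4.0)])])
        assert out.empty

    def test_identical_replicates_return_own_intervals(self):
        rep = peaks([("c", 100, 200, 8.0), ("c", 500, 650, 6.0)])
        out = consensus_peaks([rep.copy(), rep.copy(), rep.copy()])
        assert out[["start", "end"]].values.tolist() == [[100, 200], [500, 650]]

    def test_union_coordinates(self):
        reps = [peaks([("c", 100, 210, 8.0)]), peaks([("c", 90, 205, 8.0)]),
                peaks([("c", 105, 220, 8.0)])]
        out = consensus_peaks(reps)
        assert out.iloc[0][["start", "end"]].tolist() == [90, 220]

    def test_wrong_replicate_count_rejected(self):
        with pytest.raises(ValueError):
            consensus_peaks([peaks([]), peaks([])])


class TestAssignFeature:
    def annotation(self):
        genes = pd.DataFrame([gene_row("g1", "c", 5000, 8000, "+")])
        exons = frame([("c", 5000, 5500), ("c", 7000, 8000)])
        repeats = frame([("c", 7100, 7300), ("c", 12000, 12500)])
        return genes, exons, repeats

    def summit_peaks(self, positions):
        return pd.DataFrame([{"contig": "c", "start": p, "end": p + 1, "summit": 0}
                             for p in positions])

    def test_priority_rules(self):
        genes, exons, repeats = self.annotation()
        cats = assign_feature(self.summit_peaks([4500, 5200, 6000, 7200, 12100, 20000]),
                              genes, repeats, exons=exons)
        # 4500: promoter; 5200: exon; 6000: intron; 7200: exon beats TE;
        # 12100: TE; 20000: intergenic
        assert cats.tolist() == ["promoter", "exon", "intron", "exon", "TE", "intergenic"]

    def test_minus_strand_promoter(self):
        genes = pd.DataFrame([gene_row("g1", "c", 5000, 8000, "-")])
        cats = assign_feature(self.summit_peaks([8500]), genes, frame([]))
        assert cats.iloc[0] == "promoter"

    def test_matches_hand_enumerated_oracle(self, rng):
        genes, exons, repeats = self.annotation()
        positions = rng.integers(0, 15000, 20)
        cats = assign_feature(self.summit_peaks(positions), genes, repeats, exons=exons)

        def oracle(p):
            if 3000 <= p < 5000:
                return "promoter"
            if (5000 <= p < 5500) or (7000 <= p < 8000):
                return "exon"
            if 5000 <= p < 8000:
                return "intron"
            if (7100 <= p < 7300) or (12000 <= p < 12500):
                return "TE"
            return "intergenic"

        assert cats.tolist() == [oracle(int(p)) for p in positions]

    def test_summit_off_contig_rejected(self):
        genes, exons, repeats = self.annotation()
        with pytest.raises(ValueError):
            assign_feature(self.summit_peaks([99999]), genes, repeats,
                           contig_sizes={"c": 20000})


class TestMaxSignalRegion:
    def test_single_hot_bin(self):
        pos = np.arange(-2000, 0, 100, dtype=float)
        val = np.zeros_like(pos)
        val[pos == -300] = 12.0
        assert max_signal_region(pos, val) == (-300.0, 12.0)

    def test_below_threshold_returns_none(self):
        pos = np.arange(-2000, 0, 100, dtype=float)
        val = np.full_like(pos, 8.0)
        assert max_signal_region(pos, val) is None

    def test_tie_breaks_toward_tss(self):
        pos = np.arange(-2000, 0, 50, dtype=float)
        val = np.zeros_like(pos)
        val[pos == -400] = 15.0
        val[pos == -150] = 15.0
        assert max_signal_region(pos, val)[0] == -150.0


class TestNucleosomeOccupancy:
    def test_short_fragments_only_give_zero_profile(self):
        genes = pd.DataFrame([gene_row("g", "c", 5000, 7000, "+")])
        frags = frame([("c", s, s + 80) for s in range(4000, 6000, 20)])
        with pytest.warns(UserWarning, match="no nucleosome-sized"):
            prof = nucleosome_occupancy(frags, genes)
        assert (prof.values == 0).all()

    def test_uniform_nucleosomal_fragments_flat_near_one(self):
        genes = pd.DataFrame([gene_row("g", "c", 20000, 22000, "+")])
        frags = frame([("c", s, s + 200) for s in range(15000, 25000, 5)])
        prof = nucleosome_occupancy(frags, genes)
        inner = np.abs(prof.positions) <= 700
        assert np.allclose(prof.values[inner], 1.0, atol=0.05)

    def test_planted_phasing_recovered(self, small_genome, small_atac):
        genome, truth = small_genome
        cls = truth.gene_classes
        const = genome.genes[genome.genes["gene_id"].isin(cls[cls == "constitutive"].index)]
        prof = nucleosome_occupancy(small_atac.for_sample("neoblast"), const)
        minus1, plus1 = chromatin.profile_modes(prof)
        assert abs(minus1 - (-180)) <= 30
        assert abs(plus1 - 120) <= 30
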