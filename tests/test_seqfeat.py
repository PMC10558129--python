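"""Promoter extraction, composition, T-stretches, tandem repeats, k-mer
enrichment and PWM scanning, each checked against independent brute-force
oracles where the spec plants one."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemchrom import seqfeat
from stemchrom.seqfeat import (PWM, PromoterSeq, composition_profile, count_kmers,
                               extract_promoters, kmer_enrichment,
                               motif_class_frequency, revcomp, scan_pwm,
                               scan_sequence, t_stretch_stats, tandem_repeat_scan)

dna = st.text(alphabet="ACGT", min_size=0, max_size=80)


def genes_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "strand"])


class TestExtractPromoters:
    def test_plus_strand_window(self):
        genome = {"c": "AAACCC"}
        genes = genes_df([("g", "c", 3, 6, "+")])
        out = extract_promoters(genome, genes, upstream=3)
        assert out[0].sequence == "AAA"

    def test_minus_strand_returns_reverse_complement(self):
        # mirror of the plus case: gene on the minus strand with TSS at 2,
        # upstream bases are genomic 3..5 ("CCC"), reported as "GGG"
        genome = {"c": "AAACCC"}
        genes = genes_df([("g", "c", 0, 3, "-")])
        out = extract_promoters(genome, genes, upstream=3)
        assert out[0].sequence == "GGG"

    def test_roundtrip_reembedding(self, small_genome):
        genome, _ = small_genome
        proms = extract_promoters(genome.sequences, genome.genes, upstream=200)
        genes = genome.genes.set_index("gene_id")
        for p in proms[:20]:
            row = genes.loc[p.gene_id]
            if row.strand == "+":
                original = genome.sequences[row.contig][row.tss - 200:row.tss]
            else:
                original = revcomp(genome.sequences[row.contig][row.tss + 1:row.tss + 201])
            assert p.sequence == original

    def test_truncation_flagged(self):
        genome = {"c": "ACGTACGT"}
        genes = genes_df([("g", "c", 2, 8, "+")])
        out = extract_promoters(genome, genes, upstream=5)
        assert out[0].truncated and len(out[0].sequence) == 2


class TestComposition:
    def test_all_a_input(self):
        proms = [PromoterSeq("g", "A" * 20, (10, 10))]
        prof = composition_profile(proms)
        assert (prof["A"] == 1.0).all()

    def test_alternating_dinucleotide(self):
        proms = [PromoterSeq(f"g{i}", "AT" * 10, (10, 10)) for i in range(4)]
        prof = composition_profile(proms)
        assert set(prof.loc[prof["A"] == 1.0].index) == set(range(0, 20, 2))
        assert (prof["AT"] == 1.0).all()

    def test_fractions_sum_to_one(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(10)]
        prof = composition_profile([PromoterSeq(f"g{i}", s, (15, 15))
                                    for i, s in enumerate(seqs)])
        assert np.allclose(prof[list("ACGT")].sum(axis=1), 1.0)


def t_run_oracle(seq, min_len):
    return [len(m.group()) for m in re.finditer("T+", seq) if len(m.group()) >= min_len]


class TestTStretches:
    def test_worked_example(self):
        runs = seqfeat.t_runs("TTTTTATTTTTT", min_len=5)
        assert runs == [5, 6]

    def test_all_a_has_none(self):
        assert seqfeat.t_runs("A" * 50, min_len=5) == []

    def test_min_len_validation(self):
        with pytest.raises(ValueError):
            t_stretch_stats([PromoterSeq("g", "TTTT", (4, 0))],
                            pd.Series({"g": "x"}), min_len=1)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(dna, st.integers(min_value=2, max_value=6))
    def test_matches_regex_oracle(self, seq, min_len):
        assert seqfeat.t_runs(seq, min_len) == t_run_oracle(seq, min_len)

    def test_class_comparison_detects_planted_difference(self, rng):
        rich = ["".join(rng.choice(list("ACGT"), 60)) + "TTTTTT" + "A" * 10 + "TTTTT"
                for _ in range(30)]
        poor = ["".join(rng.choice(list("ACG"), 80)) for _ in range(30)]
        proms = ([PromoterSeq(f"r{i}", s, (len(s), 0)) for i, s in enumerate(rich)]
                 + [PromoterSeq(f"p{i}", s, (len(s), 0)) for i, s in enumerate(poor)])
        classes = pd.Series({p.gene_id: p.gene_id[0] for p in proms})
        counts, tests = t_stretch_stats(proms, classes)
        assert counts[[p.gene_id for p in proms[:30]]].min() >= 2
        assert tests.iloc[0]["p_bonferroni"] < 0.01


def tandem_oracle(seq, u, min_units):
    """Directly extend period-u runs from every start; keep maximal ones."""
    found = []
    i = 0
    n = len(seq)
    while i + 2 * u <= n:
        j = i
        while j + u < n and seq[j] == seq[j + u]:
            j += 1
        span = j - i + u if j > i else 0
        if span // u >= min_units:
            found.append((i, span // u, seq[i:i + u]))
            i = j
        else:
            i += 1
    return found


class TestTandemRepeats:
    def test_att_array(self):
        out = tandem_repeat_scan([PromoterSeq("g", "ATTATTATT", (9, 0))])
        assert len(out) == 1
        row = out.iloc[0]
        assert row["n_units"] == 3 and row["unit"] == "ATT" and row["at_only"]

    def test_two_units_below_threshold(self):
        out = tandem_repeat_scan([PromoterSeq("g", "ACGACG", (6, 0))], min_units=3)
        assert out.empty

    def test_non_at_units_flagged(self):
        out = tandem_repeat_scan([PromoterSeq("g", "ACGACGACG", (9, 0))])
        assert not out.iloc[0]["at_only"]

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(dna, st.sampled_from([2, 3]))
    def test_matches_brute_force(self, seq, u):
        ours = tandem_repeat_scan([PromoterSeq("g", seq, (len(seq), 0))], unit_len=u)
        got = [(r["start"], r["n_units"], r["unit"]) for _, r in ours.iterrows()]
        assert got == tandem_oracle(seq, u, 3)


def kmer_oracle(seqs, k):
    counts = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if "N" not in w:
                counts[w] = counts.get(w, 0) + 1
    return counts


class TestKmers:
    def test_counts_match_sliding_window_oracle(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(5)]
        assert count_kmers(seqs, 4) == kmer_oracle(seqs, 4)

    def test_background_equals_foreground_gives_null_enrichment(self, rng):
        proms = [PromoterSeq(f"g{i}", "".join(rng.choice(list("ACGT"), 60)), (60, 0))
                 for i in range(20)]
        enr = kmer_enrichment(proms, proms, k=5)
        assert enr["log2_enrichment"].abs().max() < 0.75
        assert (enr["p_adj"] > 0.05).mean() > 0.95

    def test_planted_nonamer_ranks_first(self, rng):
        planted = "ATTTATTTA"
        fg = []
        for i in range(50):
            s = "".join(rng.choice(list("ACGT"), 60))
            fg.append(s[:20] + planted + s[29:])
        for i in range(50):
            fg.append("".join(rng.choice(list("ACGT"), 60)))
        bg = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(100)]
        enr = kmer_enrichment([PromoterSeq(f"f{i}", s, (60, 0)) for i, s in enumerate(fg)],
                              [PromoterSeq(f"b{i}", s, (60, 0)) for i, s in enumerate(bg)],
                              k=9)
        assert enr.iloc[0]["kmer"] == planted

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            kmer_enrichment([PromoterSeq("g", "ACGTACGTACGT", (12, 0))], [], k=4)

    def test_type_one_error_controlled_under_resampled_background(self, rng):
        # background drawn from the same distribution as the foreground:
        # across seeds, few k-mers should pass BH < 0.05
        fractions = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            fg = [PromoterSeq(f"f{i}", "".join(r.choice(list("ACGT"), 100)), (100, 0))
                  for i in range(30)]
            bg = [PromoterSeq(f"b{i}", "".join(r.choice(list("ACGT"), 100)), (100, 0))
                  for i in range(30)]
            enr = kmer_enrichment(fg, bg, k=4)
            fractions.append((enr["p_adj"] < 0.05).mean())
        assert np.mean(fractions) <= 0.05


class TestPWM:
    def test_row_normalisation_enforced(self):
        with pytest.raises(ValueError):
            PWM("bad", np.full((6, 4), 0.3))

    def test_consensus_scores_highest_at_offset_zero(self):
        pwm = seqfeat.load_core_motifs()["TF8"]
        hits = scan_sequence(pwm.consensus, pwm, threshold=-np.inf)
        assert hits[0][0] == 0
        assert hits[0][1] == max(h[1] for h in hits)

    def test_uniform_pwm_scores_zero(self):
        pwm = PWM("uniform", np.full((5, 4), 0.25),
                  {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25})
        hits = scan_sequence("ACGTACGTAC", pwm, threshold=-np.inf)
        assert all(abs(s) < 1e-12 for _, s in hits)

    def test_scan_matches_exhaustive_oracle(self, rng):
        pwm_mat = rng.dirichlet(np.ones(4), size=10)
        pwm = PWM("rand", pwm_mat, {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3})
        lo = pwm.log_odds()
        idx = {b: i for i, b in enumerate("ACGT")}
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 30))
            ours = scan_sequence(seq, pwm, threshold=1.0)
            oracle = []
            for off in range(len(seq) - 10 + 1):
                s = sum(lo[j, idx[c]] for j, c in enumerate(seq[off:off + 10]))
                if s >= 1.0:
                    oracle.append((off, s))
            assert [o for o, _ in ours] == [o for o, _ in oracle]
            assert np.allclose([s for _, s in ours], [s for _, s in oracle])

    def test_reverse_complement_symmetry(self, rng):
        pwm = PWM("rand", rng.dirichlet(np.ones(4), size=8),
                  {"A": 0.35, "C": 0.15, "G": 0.15, "T": 0.35})
        seq = "".join(rng.choice(list("ACGT"), 8))
        fwd = scan_sequence(seq, pwm, threshold=-np.inf)[0][1]
        rc = scan_sequence(revcomp(seq), pwm.reverse_complement(), threshold=-np.inf)[0][1]
        assert fwd == pytest.approx(rc)

    def test_pvalue_threshold_matches_enumeration(self):
        # exhaustive enumeration over all 4^w sequences under the background
        pwm = PWM("small", np.array([[0.7, 0.1, 0.1, 0.1]] * 4),
                  {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25})
        lo = pwm.log_odds()
        import itertools as it

        scores = []
        for word in it.product(range(4), repeat=4):
            scores.append((sum(lo[j, b] for j, b in enumerate(word)), 0.25 ** 4))
        # the DP threshold is exact up to the score quantisation (1e-3 per
        # column, so w * 5e-4 cumulative)
        slack = 4 * 1e-3
        for p in (0.5, 0.1, 0.01):
            t = pwm.score_threshold(p)
            tail_above = sum(pr for s, pr in scores if s >= t + slack)
            assert tail_above <= p + 1e-9
            tail_below = sum(pr for s, pr in scores if s >= t - slack)
            assert tail_below > p or tail_below == tail_above

    def test_sequence_shorter_than_motif_yields_no_hits(self):
        pwm = seqfeat.load_core_motifs()["INR"]
        out = scan_pwm([PromoterSeq("g", "ACG", (3, 0))], pwm, score_threshold=0.0)
        assert out.empty


class TestMotifFrequencies:
    def test_fraction_arithmetic(self):
        hits = pd.DataFrame({"gene_id": ["g0", "g1", "g2"], "motif": "INR",
                             "offset": 0, "strand": "+", "score": 1.0})
        classes = pd.Series({f"g{i}": "constitutive" for i in range(10)})
        freq = motif_class_frequency(hits, classes)
        assert freq.iloc[0]["percent"] == pytest.approx(30.0)

    def test_no_hits_reports_zero_everywhere(self):
        classes = pd.Series({"g0": "brain", "g1": "neoblast"})
        freq = motif_class_frequency(pd.DataFrame(columns=["gene_id", "motif"]), classes)
        assert (freq["percent"] == 0).all()

    def test_planted_inr_frequencies_recovered(self, small_genome):
        genome, truth = small_genome
        inr = seqfeat.load_core_motifs()["INR"]
        proms = extract_promoters(genome.sequences, genome.genes,
                                  upstream=40, downstream=41)
        hits = scan_pwm(proms, inr, p_value=1e-4)
        freq = motif_class_frequency(hits, truth.gene_classes).set_index("class")
        assert freq.loc["constitutive", "percent"] == pytest.approx(100.0, abs=5.0)
        assert freq.loc["neoblast", "percent"] == pytest.approx(100.0, abs=5.0)
        tissue = freq.loc[["brain", "epidermis", "intestine"], "percent"].mean()
        assert tissue == pytest.approx(10.0, abs=8.0)


class TestMotifAccessibility:
    def test_uniform_coverage_flat(self):
        frags = pd.DataFrame([("c", s, s + 100) for s in range(0, 20000, 10)],
                             columns=["contig", "start", "end"])
        hits = pd.DataFrame([{"contig": "c", "start": 10000, "end": 10008, "strand": "+"}])
        prof = seqfeat.motif_accessibility_profile(hits, frags, library_size=len(frags))
        assert prof.values.max() / prof.values.min() < 1.05

    def test_empty_hits_flagged(self):
        frags = pd.DataFrame(columns=["contig", "start", "end"])
        with pytest.warns(UserWarning, match="no motif hits"):
            prof = seqfeat.motif_accessibility_profile(
                pd.DataFrame(columns=["contig", "start", "end", "strand"]), frags,
                library_size=1)
        assert prof.values.size == 0

    def test_planted_tf_motifs_accessible_in_matching_isolation_only(
            self, small_genome, small_atac):
        genome, truth = small_genome
        hits = truth.motifs[truth.motifs["motif"] == "TF8"].merge(
            truth.gene_classes.rename("class"), left_on="gene_id", right_index=True)
        brain_hits = hits[hits["class"] == "brain"]
        own = small_atac.for_sample("brain")
        other = small_atac.for_sample("intestine")
        prof_own = seqfeat.motif_accessibility_profile(brain_hits, own,
                                                       library_size=len(own))
        prof_other = seqfeat.motif_accessibility_profile(brain_hits, other,
                                                         library_size=len(other))
        centre = np.abs(prof_own.positions) <= 150
        flank = np.abs(prof_own.positions) >= 400
        assert prof_own.values[centre].mean() > 2 * prof_own.values[flank].mean()
        assert prof_own.values[centre].mean() > 2 * prof_other.values[centre].mean()
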