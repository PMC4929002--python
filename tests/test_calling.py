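"""Mutation-calling filter surface, classification and spectrum summaries."""

import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom, mannwhitneyu

from madrift import calling, simulate
from madrift.calling import MutationCall, PileupTable


def make_pileup(rows, parental="P0"):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "line_id", "allele", "strand", "count"])
    return PileupTable(df, parental_id=parental)


def site_rows(pos, line_alleles, chrom="A", split_strands=True):
    """line_alleles: {line: {allele: count}} -> balanced-strand pileup rows."""
    rows = []
    for line, alleles in line_alleles.items():
        for allele, n in alleles.items():
            if split_strands:
                fwd = n // 2
                if fwd:
                    rows.append((chrom, pos, line, allele, "+", fwd))
                if n - fwd:
                    rows.append((chrom, pos, line, allele, "-", n - fwd))
            else:
                rows.append((chrom, pos, line, allele, "+", n))
    return rows


def base_site(pos, mutant_line="L01", n_ma=10, mut_counts=None, depth=30):
    """An eligible site where exactly one call (G in mutant_line) passes."""
    alleles = {"P0": {"A": depth}}
    for i in range(1, n_ma + 1):
        alleles[f"L{i:02d}"] = {"A": depth}
    alleles[mutant_line] = mut_counts or {"A": 15, "G": 15}
    return site_rows(pos, alleles)


class TestEligibleSites:
    def test_toy_table_survivor_count(self):
        """Six crafted sites, one violating each eligibility clause: 3 survive."""
        ok = {f"L{i:02d}": {"A": 30} for i in range(1, 11)}
        rows = []
        rows += site_rows(1, {"P0": {"A": 30}, **ok})                      # good
        rows += site_rows(2, {"P0": {"A": 14}, **ok})                      # parental depth 14
        nine = {f"L{i:02d}": {"A": 30} for i in range(1, 10)}
        rows += site_rows(3, {"P0": {"A": 30}, **nine, "L10": {"A": 5}})   # only 9 MA lines in range
        eleven = ["A", "C", "G", "T", "AA", "AC", "AG", "AT", "CA", "CC", "CG"]
        many = {"P0": {"A": 30}}
        for i in range(1, 11):
            many[f"L{i:02d}"] = {eleven[i]: 20, "A": 10}
        rows += site_rows(4, many)                                         # 11 alleles
        rows += site_rows(5, {"P0": {"A": 15}, **ok})                      # boundary 15 inclusive
        rows += site_rows(6, {"P0": {"A": 250}, **ok})                     # boundary 250 inclusive
        sites = calling.eligible_sites(make_pileup(rows))
        assert sites == [("A", 1), ("A", 5), ("A", 6)]

    def test_parental_depth_14_excluded(self):
        ok = {f"L{i:02d}": {"A": 30} for i in range(1, 11)}
        rows = site_rows(1, {"P0": {"A": 14}, **ok})
        assert calling.eligible_sites(make_pileup(rows)) == []

    def test_missing_parental_rejected(self):
        rows = site_rows(1, {"L01": {"A": 30}, "L02": {"A": 30}})
        with pytest.raises(ValueError):
            calling.eligible_sites(make_pileup(rows, parental="P0"))


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = {x: hypergeom.pmf(x, n, r1, c1) for x in support}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_no_association(self):
        assert calling.fisher_exact_2x2(10, 10, 10, 10) == pytest.approx(1.0)

    def test_extreme_tables(self):
        assert calling.fisher_exact_2x2(0, 10, 10, 0) == pytest.approx(2 / 184756)
        assert calling.fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252)

    def test_all_zero_table(self):
        assert calling.fisher_exact_2x2(0, 0, 0, 0) == 1.0

    def test_symmetry_under_transpose(self):
        assert calling.fisher_exact_2x2(3, 7, 9, 1) == pytest.approx(
            calling.fisher_exact_2x2(3, 9, 7, 1)
        )

    def test_agrees_with_enumeration_for_small_margins(self):
        rng = random.Random(1)
        tables = [
            (a, b, c, d)
            for a, b, c, d in itertools.product(range(5), repeat=4)
        ]
        for a, b, c, d in rng.sample(tables, 80) + [(12, 0, 0, 12), (0, 12, 12, 0)]:
            if a + b + c + d == 0:
                continue
            assert calling.fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-9
            )


class TestClassify:
    @pytest.mark.parametrize(
        "anc,mut,expected",
        [
            ("A", "G", "SBS"),
            ("AC", "A", "DEL"),
            ("A", "AT", "INS"),
            ("ACG", "TG", "COMPLEX"),
            ("AC", "GT", "MBS"),
            ("ACG", "ATG", "SBS"),  # equal length, one differing base
            ("ACGT", "A", "DEL"),
            ("A", "ATTT", "INS"),
        ],
    )
    def test_examples(self, anc, mut, expected):
        assert calling.classify_mutation(anc, mut) == expected

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            calling.classify_mutation("A", "A")
        with pytest.raises(ValueError):
            calling.classify_mutation("", "A")

    @given(
        anc=st.text(alphabet="ACGT", min_size=1, max_size=6),
        mut=st.text(alphabet="ACGT", min_size=1, max_size=6),
    )
    @settings(max_examples=300, derandomize=True)
    def test_partition_property(self, anc, mut):
        """Every valid allele pair maps to exactly one of the five classes."""
        if anc == mut:
            return
        assert calling.classify_mutation(anc, mut) in calling.CLASSES


class TestCallMutations:
    def test_perfect_data_recovers_all_fixed_mutations(self):
        genome = simulate.generate_genome(50_000, seed=1)
        rng = np.random.default_rng(2)
        positions = rng.choice(50_000, size=20, replace=False)
        lines = [f"L{i:02d}" for i in range(1, 13)]
        truth = {l: [] for l in lines}
        for j, pos0 in enumerate(positions):
            line = lines[j % len(lines)]
            anc = genome.sequence[pos0]
            mut = [b for b in "ACGT" if b != anc][0]
            truth[line].append(
                simulate.TrueMutation(
                    line_id=line, position=int(pos0) + 1, chrom=genome.chrom_of(pos0),
                    ancestral=anc, mutant=mut, origin_generation=1, two_ne=23,
                    trajectory=np.array([1, 23]),  # fixed
                )
            )
        pileups = simulate.render_pileups(
            genome, truth, mean_depth=30, error_rate=0.0, seed=3, t=60, n_background=50
        )
        calls = calling.call_mutations(pileups)
        assert len(calls) == 20
        called = {(c.chrom, c.pos, c.line_id, c.mutant) for c in calls}
        for line, muts in truth.items():
            for m in muts:
                chrom, cpos = genome.chrom_pos(m.position - 1)
                assert (chrom, cpos, line, m.mutant) in called
        assert all(c.frequency == pytest.approx(1.0) for c in calls)

    def test_error_free_no_mutations_monoallelic(self):
        genome = simulate.generate_genome(1000, seed=4)
        truth = {f"L{i:02d}": [] for i in range(1, 11)}
        pileups = simulate.render_pileups(
            genome, truth, mean_depth=30, error_rate=0.0, seed=5, t=60, n_background=100
        )
        per_site = pileups.data.groupby(["chrom", "pos"])["allele"].nunique()
        assert (per_site == 1).all()
        assert calling.call_mutations(pileups) == []

    def test_each_clause_flips_the_call(self):
        """Base site yields one call; each single-clause violation removes it."""
        base = make_pileup(base_site(1))
        assert len(calling.call_mutations(base)) == 1

        # (1) one parental read supporting the mutant allele
        rows = base_site(1)
        rows.append(("A", 1, "P0", "G", "+", 1))
        assert calling.call_mutations(make_pileup(rows)) == []

        # (2) strand bias: all mutant reads on one strand
        alleles = {"P0": {"A": 30}}
        for i in range(1, 11):
            alleles[f"L{i:02d}"] = {"A": 30}
        rows = site_rows(1, {k: v for k, v in alleles.items() if k != "L01"})
        rows += [("A", 1, "L01", "A", "+", 10), ("A", 1, "L01", "A", "-", 10),
                 ("A", 1, "L01", "G", "+", 20)]
        assert calling.fisher_exact_2x2(20, 0, 10, 10) <= 0.001
        assert calling.call_mutations(make_pileup(rows)) == []

        # (3) a third allele in the mutant line
        rows = base_site(1, mut_counts={"A": 14, "G": 15, "T": 1})
        assert calling.call_mutations(make_pileup(rows)) == []

        # (4) mutant frequency exactly at the cutoff (not strictly above)
        rows = base_site(1, mut_counts={"A": 24, "G": 6})
        assert calling.call_mutations(make_pileup(rows)) == []

        # (5) another line carries the mutant allele above 5%
        rows = base_site(1)
        rows = [r for r in rows if not (r[2] == "L02")]
        rows += site_rows(1, {"L02": {"A": 27, "G": 3}})  # 10% > 5%
        assert calling.call_mutations(make_pileup(rows)) == []

        # (6) three other lines each with a single mutant read
        rows = base_site(1)
        kept = [r for r in rows if r[2] not in ("L02", "L03", "L04")]
        for line in ("L02", "L03", "L04"):
            kept += site_rows(1, {line: {"A": 29, "G": 1}})
        assert calling.call_mutations(make_pileup(kept)) == []

    def test_leaky_reads_below_thresholds_do_not_block(self):
        # two other lines with one mutant read each at freq 1/30 < 5%: still called
        rows = base_site(1)
        kept = [r for r in rows if r[2] not in ("L02", "L03")]
        for line in ("L02", "L03"):
            kept += site_rows(1, {line: {"A": 29, "G": 1}})
        assert len(calling.call_mutations(make_pileup(kept))) == 1

    @given(
        mut_reads=st.integers(5, 20),
        leak_reads=st.integers(0, 3),
        n_leak_lines=st.integers(0, 4),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_relaxing_thresholds_never_removes_calls(self, mut_reads, leak_reads, n_leak_lines):
        rows = base_site(1, mut_counts={"A": 30 - mut_reads, "G": mut_reads})
        kept = [r for r in rows if r[2] not in [f"L{i:02d}" for i in range(2, 2 + n_leak_lines)]]
        for i in range(2, 2 + n_leak_lines):
            kept += site_rows(1, {f"L{i:02d}": {"A": 30 - leak_reads, "G": leak_reads}})
        pileup = make_pileup(kept)
        strict = {
            (c.chrom, c.pos, c.line_id, c.mutant)
            for c in calling.call_mutations(pileup)
        }
        for kwargs in (
            {"freq_cutoff": 0.1},
            {"leak_freq": 0.2},
            {"strand_p": 1e-6},
            {"max_leak_lines": 5},
        ):
            relaxed = {
                (c.chrom, c.pos, c.line_id, c.mutant)
                for c in calling.call_mutations(pileup, **kwargs)
            }
            assert strict <= relaxed


class TestSpectrumSummaries:
    def make_sbs(self, anc, mut, n):
        return [
            MutationCall("L01", "A", i + 1, anc, mut, 1.0, "SBS") for i in range(n)
        ]

    def test_titv_printed_counts(self):
        calls = self.make_sbs("A", "G", 595) + self.make_sbs("A", "C", 608)
        ti, tv, ratio = calling.titv_summary(calls)
        assert (ti, tv) == (595, 608)
        assert ratio == pytest.approx(1.957, abs=5e-3)

    def test_titv_equal_counts_normalize_to_two(self):
        calls = self.make_sbs("C", "T", 50) + self.make_sbs("C", "A", 50)
        assert calling.titv_summary(calls)[2] == pytest.approx(2.0)

    def test_titv_uniform_substitutions_approach_one(self):
        rng = np.random.default_rng(8)
        calls = []
        for i in range(3000):
            anc = "ACGT"[rng.integers(4)]
            mut = [b for b in "ACGT" if b != anc][rng.integers(3)]
            calls.append(MutationCall("L01", "A", i + 1, anc, mut, 1.0, "SBS"))
        ratio = calling.titv_summary(calls)[2]
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_titv_no_transversions_flagged(self):
        assert calling.titv_summary(self.make_sbs("A", "G", 5))[2] is None

    def test_gc_fold_bias_printed_counts(self):
        assert calling.gc_fold_bias(828, 401, 0.4248) == pytest.approx(2.80, abs=5e-3)

    def test_gc_fold_bias_null(self):
        gc = 0.4248
        assert calling.gc_fold_bias(4248, 5752, gc) == pytest.approx(1.0)
        assert calling.gc_fold_bias(200, 100, 0.5) == pytest.approx(2.0)

    def test_gc_bias_from_calls(self):
        calls = self.make_sbs("G", "A", 28) + self.make_sbs("A", "G", 10)
        assert calling.gc_bias(calls, 0.5) == pytest.approx(2.8)

    def test_summarize_spectrum_counts_sum(self):
        calls = self.make_sbs("A", "G", 3) + [
            MutationCall("L01", "A", 99, "AC", "A", 1.0, "DEL"),
            MutationCall("L01", "A", 100, "A", "AT", 1.0, "INS"),
        ]
        s = calling.summarize_spectrum(calls, genome_gc=0.5)
        assert s.total == 5
        assert s.ti + s.tv == s.class_counts["SBS"] == 3


class TestDust:
    def test_homopolymer_value(self):
        s, neg = calling.dust_complexity("AAAAAAAAAA")
        assert s == pytest.approx(4.0)
        assert neg == pytest.approx(-math.log(4.0))

    def test_all_distinct_triplets_score_zero(self):
        s, neg = calling.dust_complexity("ACGTACCGGT"[:10])
        # craft a 10-bp window with 8 distinct triplets
        window = "ACGTAGCTTG"
        tris = {window[i:i+3] for i in range(8)}
        assert len(tris) == 8
        s, neg = calling.dust_complexity(window)
        assert s == 0.0 and neg == math.inf

    @pytest.mark.parametrize("w", [6, 8, 10, 12])
    def test_homopolymer_beats_shuffled(self, w):
        rng = random.Random(w)
        homo = "A" * w
        s_homo = calling.dust_complexity(homo)[0]
        base = ("ACGT" * w)[:w]
        for _ in range(20):
            shuffled = list(base)
            rng.shuffle(shuffled)
            assert s_homo > calling.dust_complexity("".join(shuffled))[0]

    def test_non_acgt_triplets_skipped(self):
        s_with_n = calling.dust_complexity("AANAA" + "A" * 5)[0]
        assert s_with_n >= 0

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            calling.dust_complexity("AC")


class TestLocalContext:
    def test_all_g_genome(self):
        g = simulate.Genome(sequence="G" * 100, x_length=0)
        ctx = calling.local_context(g, 50)
        assert ctx.gc_content == 1.0

    def test_single_c_window_counting(self):
        g = simulate.Genome(sequence="A" * 20 + "C" + "A" * 20, x_length=0)
        ctx = calling.local_context(g, 21)
        assert ctx.end - ctx.start == 41
        assert ctx.gc_content == pytest.approx(1 / 41)

    def test_indel_sites_in_homopolymers_have_lower_complexity(self):
        # genome enriched for homopolymer runs; indels planted by slippage
        rng = np.random.default_rng(11)
        parts = []
        while sum(len(p) for p in parts) < 40_000:
            if rng.random() < 0.3:
                parts.append("ACGT"[rng.integers(4)] * rng.integers(6, 15))
            else:
                parts.append("".join(rng.choice(list("ACGT"), size=20)))
        g = simulate.Genome(sequence="".join(parts), x_length=0)
        truth = simulate.simulate_ma_lines(
            g, 5, 30, 5e-6, 23, seed=12, indel_fraction=0.5, slippage_bias=1.0
        )
        indel_scores, random_scores = [], []
        for muts in truth.values():
            for m in muts:
                if len(m.ancestral) != len(m.mutant):
                    indel_scores.append(calling.local_context(g, m.position).s)
        for pos in rng.integers(21, len(g.sequence) - 21, size=1000):
            random_scores.append(calling.local_context(g, int(pos)).s)
        assert len(indel_scores) >= 10
        stat = mannwhitneyu(indel_scores, random_scores, alternative="greater")
        assert stat.pvalue < 0.01  # higher S = lower complexity at indels


class TestMutationsPerGene:
    def test_no_calls_all_zero(self):
        genes = [("g1", "A", 0, 100), ("g2", "A", 100, 300)]
        df = calling.mutations_per_gene([], genes)
        assert (df["n_mutations"] == 0).all()
        assert df["covered_bases"].tolist() == [100, 200]

    def test_whole_genome_gene_counts_everything(self):
        calls = [MutationCall("L01", "A", i + 1, "A", "G", 1.0, "SBS") for i in range(7)]
        df = calling.mutations_per_gene(calls, [("all", "A", 0, 1000)])
        assert df["n_mutations"].iloc[0] == 7

    def test_uniform_calls_proportional_to_length(self):
        rng = np.random.default_rng(13)
        calls = [
            MutationCall("L01", "A", int(p) + 1, "A", "G", 1.0, "SBS")
            for p in rng.integers(0, 30_000, size=3000)
        ]
        genes = [("short", "A", 0, 5000), ("long", "A", 5000, 30_000)]
        df = calling.mutations_per_gene(calls, genes)
        rate = df["n_mutations"] / df["covered_bases"]
        assert rate.iloc[0] == pytest.approx(rate.iloc[1], rel=0.2)

    def test_overlapping_genes_count_twice(self):
        calls = [MutationCall("L01", "A", 50, "A", "G", 1.0, "SBS")]
        genes = [("g1", "A", 0, 100), ("g2", "A", 40, 60)]
        df = calling.mutations_per_gene(calls, genes)
        assert df["n_mutations"].tolist() == [1, 1]
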