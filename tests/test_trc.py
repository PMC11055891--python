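import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rdcscan.forks import ForkSegment
from rdcscan.junctions import JunctionSet, Orientation
from rdcscan.rdc import RdcCall
from rdcscan.repliseq import CorrectedFractionTrack
from rdcscan.trc import (
    TrcCompartment,
    assign_compartments,
    dual_strand_peaks,
    group_compare,
    hybrid_counts,
    hybrid_stratify,
    peak_density_compare,
    proportions,
    relative_dsb_count,
    relative_replication_speed,
)

RDC = RdcCall("chr1", 1_000_000, 2_000_000, 0)


def _jset(records):
    rows = [(r[0], r[1], r[2], None, None, None) for r in records]
    return JunctionSet(pd.DataFrame(rows, columns=JunctionSet.COLUMNS))


def _comp(start, end, mode, fork_dir):
    matched = Orientation.DCEN if fork_dir == "rightward" else Orientation.DTEL
    tx = "-" if (mode == "head_on") == (fork_dir == "rightward") else "+"
    return TrcCompartment("chr1", start, end, mode, fork_dir, tx, matched)


class TestAssignCompartments:
    def test_rightward_fork_leftward_gene_is_head_on_dcen(self, gene_frame):
        genes = gene_frame([("chr1", 1_000_000, 2_000_000, "-", 3.0)])
        forks = [ForkSegment("chr1", 900_000, 2_100_000, "rightward")]
        comps = assign_compartments(RDC, forks, genes)
        assert len(comps) == 1
        c = comps[0]
        assert c.mode == "head_on"
        assert c.matched_orientation == Orientation.DCEN
        assert (c.start, c.end) == (1_000_000, 2_000_000)

    def test_leftward_fork_leftward_gene_is_codirectional_dtel(self, gene_frame):
        genes = gene_frame([("chr1", 1_000_000, 2_000_000, "-", 3.0)])
        forks = [ForkSegment("chr1", 900_000, 2_100_000, "leftward")]
        comps = assign_compartments(RDC, forks, genes)
        assert comps[0].mode == "co_directional"
        assert comps[0].matched_orientation == Orientation.DTEL

    def test_low_rpkm_gene_excluded(self, gene_frame):
        genes = gene_frame([("chr1", 1_000_000, 2_000_000, "-", 0.01)])
        forks = [ForkSegment("chr1", 900_000, 2_100_000, "rightward")]
        assert assign_compartments(RDC, forks, genes) == []

    def test_rpkm_threshold_inclusive(self, gene_frame):
        genes = gene_frame([("chr1", 1_000_000, 2_000_000, "-", 0.05)])
        forks = [ForkSegment("chr1", 900_000, 2_100_000, "rightward")]
        assert len(assign_compartments(RDC, forks, genes)) == 1


class TestProportions:
    def test_balanced_counts_give_fifty_fifty(self):
        comps = [_comp(1_000_000, 1_500_000, "head_on", "rightward"),
                 _comp(1_500_000, 2_000_000, "co_directional", "leftward")]
        js = _jset([("chr1", 1_200_000 + i, "Dcen") for i in range(40)]
                   + [("chr1", 1_700_000 + i, "Dtel") for i in range(40)])
        assert proportions(js, comps) == (50.0, 50.0)

    def test_all_head_on_gives_hundred(self):
        comps = [_comp(1_000_000, 1_500_000, "head_on", "rightward"),
                 _comp(1_500_000, 2_000_000, "co_directional", "leftward")]
        js = _jset([("chr1", 1_100_000, "Dcen"), ("chr1", 1_200_000, "Dcen")])
        assert proportions(js, comps) == (100.0, 0.0)

    def test_sixty_forty(self):
        comps = [_comp(1_000_000, 1_500_000, "head_on", "rightward"),
                 _comp(1_500_000, 2_000_000, "co_directional", "leftward")]
        js = _jset([("chr1", 1_000_001 + i, "Dcen") for i in range(60)]
                   + [("chr1", 1_500_001 + i, "Dtel") for i in range(40)])
        assert proportions(js, comps) == (60.0, 40.0)

    def test_unmatched_orientation_not_counted(self):
        comps = [_comp(1_000_000, 2_000_000, "head_on", "rightward")]
        js = _jset([("chr1", 1_500_000, "Dtel")])  # Dtel under rightward fork
        assert proportions(js, comps) is None

    def test_sums_to_hundred_whenever_defined(self, rng):
        comps = [_comp(1_000_000, 1_400_000, "head_on", "rightward"),
                 _comp(1_400_000, 2_000_000, "co_directional", "rightward")]
        for _ in range(20):
            pos = rng.integers(1_000_000, 2_000_000, size=30)
            ori = rng.choice(["Dcen", "Dtel"], size=30)
            js = _jset(list(zip(["chr1"] * 30, pos, ori)))
            p = proportions(js, comps)
            if p is not None:
                assert p[0] + p[1] == 100.0


class TestRelativeReplicationSpeed:
    def test_ten_bins_eight_fractions(self):
        track = CorrectedFractionTrack(
            "chr1", np.array([0] * 20 + list(range(4, 12)) + [11, 11]))
        comp = _comp(20 * 50_000, 30 * 50_000, "head_on", "rightward")
        assert relative_replication_speed(comp, track) == pytest.approx(1.25)

    def test_single_bin_single_fraction(self):
        track = CorrectedFractionTrack("chr1", np.array([7]))
        comp = _comp(0, 50_000, "head_on", "rightward")
        assert relative_replication_speed(comp, track) == 1.0

    def test_doubling_bins_at_fixed_span_doubles_rs(self):
        f = [4, 5, 6, 7]
        t1 = CorrectedFractionTrack("chr1", np.array(f))
        t2 = CorrectedFractionTrack("chr1", np.array(np.repeat(f, 2)))
        c1 = _comp(0, 4 * 50_000, "head_on", "rightward")
        c2 = _comp(0, 8 * 50_000, "head_on", "rightward")
        assert relative_replication_speed(c2, t2) == \
            2 * relative_replication_speed(c1, t1)

    def test_no_coverage_errors(self):
        track = CorrectedFractionTrack("chr1", np.zeros(10, int))
        with pytest.raises(ValueError):
            relative_replication_speed(_comp(0, 100_000, "head_on", "rightward"),
                                       track)


class TestRelativeDsbCount:
    def test_equal_counts_all_zero(self):
        out = relative_dsb_count(dict.fromkeys("abcde", 10))
        assert all(v == 0.0 for v in out.values())

    def test_dose_series_arithmetic(self):
        out = relative_dsb_count(dict(zip("abcde", [5, 10, 15, 20, 50])))
        assert out["e"] == pytest.approx(np.log2(2.5))
        assert out["a"] == pytest.approx(np.log2(0.25))

    def test_zero_count_uses_pseudocount(self):
        out = relative_dsb_count(dict(zip("abcde", [0, 10, 10, 10, 10])))
        assert out["a"] == pytest.approx(np.log2(0.5 / 8))

    def test_all_zero_excluded(self):
        assert relative_dsb_count(dict.fromkeys("abcde", 0)) is None

    def test_permutation_of_equal_counts_zero_vector(self):
        for perm in itertools.permutations([7, 7, 7]):
            out = relative_dsb_count(dict(zip("abc", perm)))
            assert all(v == 0.0 for v in out.values())


class TestHybridStratification:
    def _peaks(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_dual_strand_requires_overlap(self):
        plus = self._peaks([("chr1", 100, 200)])
        minus = self._peaks([("chr1", 300, 400)])
        assert len(dual_strand_peaks(plus, minus)) == 0
        minus2 = self._peaks([("chr1", 150, 250)])
        assert len(dual_strand_peaks(plus, minus2)) == 1

    def test_zero_hybrids_is_low(self):
        rdcs = [RdcCall("chr1", 0, 1_000_000, 0)]
        empty = self._peaks([])
        assert hybrid_stratify(rdcs, empty, empty) == {0: "low"}

    def test_tertile_rule_trace(self):
        # counts 1,2,5,8,20,30 -> low,low,mid,mid,high,high
        counts = [1, 2, 5, 8, 20, 30]
        rdcs, plus, minus = [], [], []
        for i, c in enumerate(counts):
            lo = i * 10_000_000
            rdcs.append(RdcCall("chr1", lo, lo + 1_000_000, 0))
            for k in range(c):
                s = lo + 1000 + 2000 * k
                plus.append(("chr1", s, s + 800))
                minus.append(("chr1", s + 200, s + 1000))
        labels = hybrid_stratify(rdcs, self._peaks(plus), self._peaks(minus))
        assert [labels[i] for i in range(6)] == \
            ["low", "low", "mid", "mid", "high", "high"]
        assert hybrid_counts(rdcs, self._peaks(plus), self._peaks(minus)) == \
            dict(enumerate(counts))


class TestPeakDensity:
    def test_density_per_100kb(self, gene_frame):
        genes = gene_frame([("chr1", 0, 200_000, "+", 1.0)])
        peaks = pd.DataFrame([("chr1", i * 10_000, i * 10_000 + 500)
                              for i in range(4)],
                             columns=["chrom", "start", "end"])
        a, _, _ = peak_density_compare(genes, genes, peaks)
        assert a[0] == pytest.approx(2.0)

    def test_matches_exhaustive_permutation_oracle(self, gene_frame):
        # density vectors {1,2,3} vs {4,5,6} engineered via gene lengths
        def genes_with_densities(dens, offset):
            rows = []
            for i, d in enumerate(dens):
                start = offset + i * 1_000_000
                rows.append(("chr1", start, start + 100_000, "+", 1.0))
            return gene_frame(rows), dens

        ga, da = genes_with_densities([1, 2, 3], 0)
        gb, db = genes_with_densities([4, 5, 6], 10_000_000)
        peaks = []
        for genes, dens in ((ga, da), (gb, db)):
            for g, d in zip(genes.itertuples(index=False), dens):
                for k in range(d):
                    peaks.append(("chr1", g.start + k * 2000, g.start + k * 2000 + 100))
        peaks = pd.DataFrame(peaks, columns=["chrom", "start", "end"])
        a, b, p = peak_density_compare(ga, gb, peaks)
        assert sorted(a) == [1, 2, 3] and sorted(b) == [4, 5, 6]

        # brute-force two-sided Mann-Whitney over all 6!/(3!3!) splits
        pooled = np.r_[a, b]
        u_obs = sum(1 for x in a for y in b if x > y) \
            + 0.5 * sum(1 for x in a for y in b if x == y)
        mu = len(a) * len(b) / 2
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            xs = pooled[list(combo)]
            ys = pooled[[i for i in range(6) if i not in combo]]
            u = sum(1 for x in xs for y in ys if x > y) \
                + 0.5 * sum(1 for x in xs for y in ys if x == y)
            if abs(u - mu) >= abs(u_obs - mu):
                count += 1
            total += 1
        assert p == pytest.approx(count / total)

    def test_empty_set_errors(self, gene_frame):
        genes = gene_frame([("chr1", 0, 200_000, "+", 1.0)])
        with pytest.raises(ValueError):
            peak_density_compare(genes, genes.iloc[:0],
                                 pd.DataFrame(columns=["chrom", "start", "end"]))


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        assert group_compare([1, 2, 3], [1, 2, 3], "mann_whitney") == 1.0

    def test_separated_constant_groups_tiny_p(self):
        p = group_compare([0, 0, 0], [1, 1, 1], "t_test")
        assert p < 1e-6

    def test_t_statistic_matches_hand_formula(self):
        a, b = [1, 2, 3, 4], [2, 3, 4, 5]
        res = stats.ttest_ind(a, b)
        # hand computation: pooled-variance two-sample t
        sa2 = np.var(a, ddof=1)
        sb2 = np.var(b, ddof=1)
        sp = np.sqrt(((3 * sa2) + (3 * sb2)) / 6)
        t_hand = (np.mean(a) - np.mean(b)) / (sp * np.sqrt(1 / 4 + 1 / 4))
        assert res.statistic == pytest.approx(t_hand)
        assert group_compare(a, b, "t_test") == pytest.approx(res.pvalue)

    def test_zero_variance_equal_means(self):
        assert group_compare([2, 2], [2, 2], "t_test") == 1.0

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            group_compare([1], [2, 3], "t_test")
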