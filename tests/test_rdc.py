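import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rdcscan.junctions import JunctionSet
from rdcscan.rdc import (
    NbBackground,
    PileupTrack,
    PValueTrack,
    call_rdc,
    extend_and_pileup,
    fit_background,
    pileup_pvalues,
)


def _jset(positions, chrom="chr1", orientation="Dcen"):
    rows = [(chrom, int(p), orientation, None, None, None) for p in positions]
    return JunctionSet(pd.DataFrame(rows, columns=JunctionSet.COLUMNS))


class TestExtendAndPileup:
    def test_single_junction_covers_100kb(self):
        t = extend_and_pileup(_jset([1_000_000]), "chr1", 2_000_000, bin_size=1000)
        covered = np.flatnonzero(t.values)
        assert covered[0] == 950 and covered[-1] == 1049
        assert (t.values[covered] == 1).all()

    def test_clipped_at_chromosome_start(self):
        t = extend_and_pileup(_jset([10_000]), "chr1", 1_000_000, bin_size=1000)
        covered = np.flatnonzero(t.values)
        assert covered[0] == 0 and covered[-1] == 59  # [0, 60 kb)

    def test_two_junctions_30kb_apart_overlap(self):
        t = extend_and_pileup(_jset([1_000_000, 1_030_000]), "chr1", 2_000_000,
                              bin_size=1000)
        assert (t.values[980:1030] == 2).all()  # 70-kb overlap region
        assert t.values[960] == 1 and t.values[1060] == 1

    def test_interval_mass_conserved(self, rng):
        pos = rng.integers(100_000, 9_900_000, size=300)
        t = extend_and_pileup(_jset(pos), "chr1", 10_000_000, bin_size=1000)
        # each 100-kb interval overlaps 100 bins when aligned, 101 otherwise
        expected = sum((p + 50_000 - 1) // 1000 - (p - 50_000) // 1000 + 1
                       for p in pos)
        assert t.values.sum() == expected


class TestFitBackground:
    def test_nb_parameter_recovery(self, rng):
        mean, disp = 4.0, 2.0
        v = rng.negative_binomial(disp, disp / (disp + mean), size=100_000)
        bg = fit_background(PileupTrack("chr1", 1000, v))
        assert bg.mean == pytest.approx(mean, rel=0.02)
        assert not bg.degenerate
        assert bg.dispersion == pytest.approx(disp, rel=0.10)

    def test_constant_track_poisson_fallback(self):
        bg = fit_background(PileupTrack("chr1", 1000, np.full(500, 3)))
        assert bg.degenerate and bg.mean == 3.0

    def test_poisson_data_engages_fallback_or_huge_dispersion(self, rng):
        v = rng.poisson(2.0, size=100_000)
        bg = fit_background(PileupTrack("chr1", 1000, v))
        assert bg.degenerate or bg.dispersion > 50

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            fit_background(PileupTrack("chr1", 1000, np.zeros(1000, int)))

    def test_too_few_bins_errors(self):
        with pytest.raises(ValueError):
            fit_background(PileupTrack("chr1", 1000, np.ones(10, int)))


class TestPileupPvalues:
    def test_poisson_tail_matches_pmf_summation(self):
        bg = NbBackground(mean=2.0, dispersion=None, degenerate=True)
        t = PileupTrack("chr1", 1000, np.array([7]))
        p = pileup_pvalues(t, bg).pvalues[0]
        # independent oracle: brute-force pmf summation of P(X >= 7)
        import math

        brute = 1.0 - sum(np.exp(-2) * 2**k / math.factorial(k) for k in range(7))
        assert p == pytest.approx(brute, rel=1e-9)
        assert p == pytest.approx(0.0045, abs=2e-4)

    def test_observed_zero_gives_one(self):
        bg = NbBackground(mean=5.0, dispersion=3.0)
        p = pileup_pvalues(PileupTrack("chr1", 1000, np.array([0])), bg).pvalues
        assert p[0] == 1.0

    def test_null_pvalues_uniform_after_randomization(self, rng):
        """Calibration of the fitted NB tail on data drawn from it.

        Discrete upper-tail p-values are sub-uniform by construction, so the
        proper uniformity check randomizes within pmf atoms:
        u = P(X > x) + V * P(X = x), exactly Uniform(0,1) iff the model fits.
        """
        mean, disp = 4.0, 2.0
        v = rng.negative_binomial(disp, disp / (disp + mean), size=5000)
        bg = fit_background(PileupTrack("chr1", 1000, v))
        p_ge = pileup_pvalues(PileupTrack("chr1", 1000, v), bg).pvalues
        p_gt = bg.sf_at_or_above(v + 1)
        u = p_gt + rng.random(len(v)) * (p_ge - p_gt)
        assert stats.kstest(u, "uniform").pvalue > 0.01
        # the raw tail p-values remain valid (conservative): P(p <= a) <= a
        for alpha in (0.01, 0.05, 0.1):
            assert (p_ge <= alpha).mean() <= alpha + 3 * np.sqrt(alpha / len(v))


# ---------------------------------------------------------------------------
# island calling


def _track(p, ori="both", bin_size=1000):
    return PValueTrack("chr1", bin_size, np.asarray(p, float), ori)


def _toy(extension_end_kb):
    """p<0.01 over 100-180 and 190-240 kb, p<0.1 flanks to 90..extension_end."""
    p = np.full(500, 0.5)
    p[100:180] = 0.001
    p[190:240] = 0.001
    p[90:100] = 0.05
    p[180:190] = 0.05
    p[240:extension_end_kb] = 0.05
    return p


class TestCallRdc:
    def test_island_below_min_length_rejected(self):
        calls = call_rdc({"both": _track(_toy(320))})
        assert calls == []  # extended island 90-320 kb = 230 kb < 300 kb

    def test_island_meeting_both_filters_called(self):
        calls = call_rdc({"both": _track(_toy(400))})
        assert len(calls) == 1
        c = calls[0]
        assert (c.start, c.end) == (90_000, 400_000)  # 310 kb >= 300 kb
        assert c.sig_bp == 130_000  # >= 100 kb below 0.01

    def test_uniform_track_yields_no_calls(self):
        calls = call_rdc({"both": _track(np.full(1000, 0.5))})
        assert calls == []

    def test_seed_gap_strictly_greater_breaks_seed(self):
        # 11-kb non-significant gap: two separate seeds, gap still joined at
        # island stage (<= 100 kb), so extension spans both
        p = np.full(600, 0.5)
        p[100:180] = 0.001
        p[191:420] = 0.001
        calls = call_rdc({"both": _track(p)})
        assert len(calls) == 1
        assert calls[0].start == 100_000 and calls[0].end == 420_000

    def test_orientation_islands_merge(self):
        pc = np.full(700, 0.5)
        pt = np.full(700, 0.5)
        pc[100:280] = 0.001  # Dcen island 100-280
        pt[250:430] = 0.001  # Dtel island 250-430, overlapping
        calls = call_rdc({"Dcen": _track(pc, "Dcen"), "Dtel": _track(pt, "Dtel"),
                          "both": _track(np.full(700, 0.5))})
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (100_000, 430_000)
        assert set(calls[0].orientation_islands["Dcen"]) == {(100_000, 280_000)}

    def test_mismatched_grids_error(self):
        with pytest.raises(ValueError):
            call_rdc({"Dcen": _track(np.full(100, 0.5), "Dcen"),
                      "Dtel": _track(np.full(90, 0.5), "Dtel")})

    def test_adding_junctions_never_removes_a_call(self, rng):
        pos = rng.integers(0, 30_000_000, size=3000).tolist()
        pos += rng.integers(10_000_000, 10_400_000, size=800).tolist()

        def call(ps):
            t = extend_and_pileup(_jset(ps), "chr1", 30_000_000, bin_size=1000)
            pv = pileup_pvalues(t, fit_background(t))
            return call_rdc({"both": pv})

        before = call(pos)
        assert any(c.start <= 10_200_000 <= c.end for c in before)
        more = pos + rng.integers(10_100_000, 10_300_000, size=300).tolist()
        after = call(more)
        assert any(c.start <= 10_200_000 <= c.end for c in after)

    def test_calls_do_not_overlap(self, rng):
        for trial in range(10):
            p = 10 ** -(3 * rng.random(400))
            calls = call_rdc({"both": _track(p)})
            for a, b in zip(calls, calls[1:]):
                assert a.end <= b.start


# ---------------------------------------------------------------------------
# brute-force oracle


def oracle_call_rdc(pmap, bin_size=1000, p_seed=0.01, p_extend=0.1,
                    seed_gap=10_000, island_gap=100_000,
                    min_sig=100_000, min_len=300_000):
    """Exhaustive reference implementation by transitive-closure clustering.

    Groups significant bins into seeds by pairwise distance, seeds into
    islands likewise, extends bin-by-bin, unions orientation islands on a
    boolean mask, then filters.  Quadratic and simple on purpose.
    """

    def cluster(intervals, max_gap_bins):
        # transitive closure under "gap <= max_gap_bins"
        groups = [list(iv) for iv in sorted(intervals)]
        changed = True
        while changed:
            changed = False
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    gi, gj = groups[i], groups[j]
                    gap = max(gi[0], gj[0]) - min(gi[1], gj[1])
                    if gap <= max_gap_bins:
                        groups[i] = [min(gi[0], gj[0]), max(gi[1], gj[1])]
                        del groups[j]
                        changed = True
                        break
                if changed:
                    break
        return sorted(tuple(g) for g in groups)

    n = len(next(iter(pmap.values())))
    covered = np.zeros(n, bool)
    for p in pmap.values():
        sig_bins = [(i, i + 1) for i in range(n) if p[i] < p_seed]
        seeds = cluster(sig_bins, seed_gap // bin_size)
        islands = cluster(seeds, island_gap // bin_size)
        for s, e in islands:
            while s > 0 and p[s - 1] < p_extend:
                s -= 1
            while e < n and p[e] < p_extend:
                e += 1
            covered[s:e] = True
    any_sig = np.zeros(n, bool)
    for p in pmap.values():
        any_sig |= np.asarray(p) < p_seed
    out = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            sig_bp = int(any_sig[i:j].sum()) * bin_size
            if sig_bp >= min_sig and (j - i) * bin_size >= min_len:
                out.append((i * bin_size, j * bin_size, sig_bp))
            i = j
        else:
            i += 1
    return out


def test_caller_matches_brute_force_oracle_on_random_tracks(rng):
    """100 random small multi-orientation tracks, exact agreement."""
    for trial in range(100):
        n = int(rng.integers(300, 600))
        pmap = {}
        for ori in ("Dcen", "Dtel", "both"):
            p = 10 ** -(2.5 * rng.random(n))
            # sprinkle significant blocks to create non-trivial structure
            for _ in range(int(rng.integers(0, 4))):
                s = int(rng.integers(0, n - 50))
                p[s:s + int(rng.integers(20, 120))] = 0.001
            pmap[ori] = p
        got = call_rdc({o: _track(v, o) for o, v in pmap.items()})
        want = oracle_call_rdc(pmap)
        assert [(c.start, c.end, c.sig_bp) for c in got] == want, f"trial {trial}"
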