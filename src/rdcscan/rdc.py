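"""Recurrent DNA break cluster (RDC) calling from oriented junction pileups.

The caller mirrors the orientation-aware island algorithm: junctions are
extended +/-50 kb, piled up per orientation stratum (Dcen-only, Dtel-only and
both), a negative-binomial background is fitted per chromosome/condition/
orientation, per-bin upper-tail p-values are computed, and significant bins
are grown into islands:

1. seeds: maximal runs of bins with p < p_seed (0.01), tolerating internal
   non-significant gaps of <= seed_gap (10 kb);
2. islands: seeds joined when separated by <= island_gap (100 kb);
3. extension: islands grow outward over contiguous flanking bins with
   p < p_extend (0.1);
4. orientation merge: overlapping (or touching) islands from the three
   orientation strata are unioned;
5. filters: a merged candidate is an RDC iff it contains >= min_sig
   (100 kb) of sequence below p_seed in any orientation and its extended
   length is >= min_len (300 kb).  The reported interval is the broadest
   range of the overlapping islands.

Raw p-values are thresholded (no multiple-testing correction), matching the
source procedure.  The pileup grid defaults to 1-kb bins so the 10-kb gap
rule is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .junctions import JunctionSet, Orientation

DEFAULT_PARAMS = dict(
    half_width=50_000,
    bin_size=1_000,
    p_seed=0.01,
    p_extend=0.1,
    seed_gap=10_000,
    island_gap=100_000,
    min_sig=100_000,
    min_len=300_000,
)


@dataclass
class PileupTrack:
    chrom: str
    bin_size: int
    values: np.ndarray  # int counts per bin
    orientation: str = "both"
    condition: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if (self.values < 0).any():
            raise ValueError("pileup values must be non-negative")


@dataclass
class NbBackground:
    """Negative-binomial background; variance = mean + mean^2 / dispersion.

    ``degenerate`` marks tracks whose sample variance does not exceed the
    mean, where a Poisson(mean) model is used instead.
    """

    mean: float
    dispersion: float | None
    degenerate: bool = False

    def sf_at_or_above(self, x: np.ndarray) -> np.ndarray:
        """Upper tail P(X >= x)."""
        x = np.asarray(x)
        if self.degenerate or self.dispersion is None:
            return stats.poisson.sf(x - 1, self.mean)
        n = self.dispersion
        p = n / (n + self.mean)
        return stats.nbinom.sf(x - 1, n, p)


@dataclass
class PValueTrack:
    chrom: str
    bin_size: int
    pvalues: np.ndarray
    orientation: str = "both"
    condition: str | None = None


@dataclass
class RdcCall:
    chrom: str
    start: int
    end: int
    sig_bp: int
    orientation_islands: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    p_profile: dict[str, np.ndarray] | None = None
    label: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def extend_and_pileup(
    junctions: JunctionSet,
    chrom: str,
    chrom_length: int,
    *,
    half_width: int = 50_000,
    bin_size: int = 1_000,
    orientation: Orientation | str | None = None,
    condition: str | None = None,
) -> PileupTrack:
    """Extend each junction +/- half_width and count interval-bin overlaps.

    Each junction contributes the clipped interval [pos - hw, pos + hw); a
    bin's value is the number of such intervals overlapping it.  Computed
    with a difference array over bin indices.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    sub = junctions.subset(chrom=chrom, orientation=orientation, condition=condition)
    pos = sub.df["pos"].to_numpy(dtype=np.int64)
    n_bins = int(np.ceil(chrom_length / bin_size))
    diff = np.zeros(n_bins + 1, dtype=np.int64)
    starts = np.clip(pos - half_width, 0, chrom_length)
    ends = np.clip(pos + half_width, 0, chrom_length)
    first_bin = starts // bin_size
    last_bin = np.minimum((ends - 1) // bin_size, n_bins - 1)  # inclusive
    keep = ends > starts
    np.add.at(diff, first_bin[keep], 1)
    np.add.at(diff, last_bin[keep] + 1, -1)
    values = np.cumsum(diff[:-1])
    ori = str(Orientation(orientation).value) if orientation is not None else "both"
    return PileupTrack(chrom, bin_size, values, ori, condition)


def fit_background(pileup: PileupTrack, min_bins: int = 100) -> NbBackground:
    """Method-of-moments NB fit to a pileup track (genome/chromosome-wide).

    dispersion = mean^2 / (var - mean); if var <= mean the track is under- or
    equi-dispersed and a Poisson fallback is flagged.
    """
    v = np.asarray(pileup.values, dtype=float)
    if len(v) < min_bins:
        raise ValueError(f"need >= {min_bins} bins to fit a background, got {len(v)}")
    if not v.any():
        raise ValueError("all-zero pileup track: no background estimable")
    mean = float(v.mean())
    var = float(v.var(ddof=1))
    if var <= mean:
        return NbBackground(mean=mean, dispersion=None, degenerate=True)
    return NbBackground(mean=mean, dispersion=mean**2 / (var - mean))


def pileup_pvalues(pileup: PileupTrack, bg: NbBackground) -> PValueTrack:
    """Per-bin upper-tail p-value P(X >= observed) under the background."""
    p = bg.sf_at_or_above(pileup.values)
    return PValueTrack(pileup.chrom, pileup.bin_size, p, pileup.orientation, pileup.condition)


# ---------------------------------------------------------------------------
# island construction


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as half-open bin-index intervals."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _join_within(intervals: list[tuple[int, int]], max_gap_bins: int) -> list[tuple[int, int]]:
    """Join sorted half-open intervals whose separating gap is <= max_gap_bins."""
    if not intervals:
        return []
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s - out[-1][1] <= max_gap_bins:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def _extend(interval: tuple[int, int], loose: np.ndarray) -> tuple[int, int]:
    """Grow an island outward over contiguous bins where ``loose`` is True."""
    s, e = interval
    while s > 0 and loose[s - 1]:
        s -= 1
    n = len(loose)
    while e < n and loose[e]:
        e += 1
    return s, e


def orientation_islands(pvals: PValueTrack, *, p_seed: float = 0.01,
                        p_extend: float = 0.1, seed_gap: int = 10_000,
                        island_gap: int = 100_000) -> list[tuple[int, int]]:
    """Seed/join/extend islands for one orientation track (bin indices)."""
    bs = pvals.bin_size
    sig = pvals.pvalues < p_seed
    seeds = _join_within(_runs(sig), seed_gap // bs)
    islands = _join_within(seeds, island_gap // bs)
    loose = pvals.pvalues < p_extend
    extended = [_extend(iv, loose) for iv in islands]
    # extension may create overlaps between formerly separate islands
    return _join_within(sorted(extended), 0)


def call_rdc(
    pvals: dict[str, PValueTrack],
    *,
    p_seed: float = 0.01,
    p_extend: float = 0.1,
    seed_gap: int = 10_000,
    island_gap: int = 100_000,
    min_sig: int = 100_000,
    min_len: int = 300_000,
) -> list[RdcCall]:
    """Call RDCs from per-orientation p-value tracks on a common grid.

    ``pvals`` maps orientation labels (typically "Dcen", "Dtel", "both") to
    tracks.  Returns non-overlapping calls sorted by start.
    """
    tracks = list(pvals.values())
    if not tracks:
        return []
    bs = tracks[0].bin_size
    n = len(tracks[0].pvalues)
    chrom = tracks[0].chrom
    for t in tracks:
        if t.bin_size != bs or len(t.pvalues) != n or t.chrom != chrom:
            raise ValueError("p-value tracks must share one chromosome and grid")

    per_ori = {
        name: orientation_islands(t, p_seed=p_seed, p_extend=p_extend,
                                  seed_gap=seed_gap, island_gap=island_gap)
        for name, t in pvals.items()
    }
    pooled = sorted(iv for ivs in per_ori.values() for iv in ivs)
    merged = _join_within(pooled, 0)  # overlapping or touching islands union

    any_sig = np.zeros(n, dtype=bool)
    for t in tracks:
        any_sig |= t.pvalues < p_seed

    calls: list[RdcCall] = []
    for s, e in merged:
        sig_bp = int(any_sig[s:e].sum()) * bs
        length = (e - s) * bs
        if sig_bp < min_sig or length < min_len:
            continue
        sub_islands = {
            name: [(a * bs, b * bs) for a, b in ivs if a < e and b > s]
            for name, ivs in per_ori.items()
        }
        profile = {name: t.pvalues[s:e].copy() for name, t in pvals.items()}
        calls.append(RdcCall(chrom, s * bs, e * bs, sig_bp, sub_islands, profile))
    return calls


def calls_to_frame(calls: list[RdcCall]):
    """Summary table of RDC calls (one row per call)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "length": c.length,
                "sig_bp": c.sig_bp,
                "label": c.label,
            }
            for c in calls
        ]
    )
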