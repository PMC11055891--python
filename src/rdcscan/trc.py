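"""Transcription-replication conflict (TRC) statistics at RDCs.

Within an RDC, each fork-covered interval overlapping an actively
transcribed gene is a TRC compartment: head-on (HO) when fork and
transcription directions oppose, co-directional (CD) when they agree.
Because a stalled rightward fork yields centromere-connected (Dcen) break
ends and a leftward fork telomere-connected (Dtel) ends, each compartment
counts only its matched orientation: Dcen under rightward forks, Dtel under
leftward forks.  The head-on proportion is then

    P_HO = 100 * N_HO / (N_HO + N_CD),      P_CD = 100 - P_HO,

where N_HO / N_CD are matched-orientation junction counts aggregated over
the RDC's HO / CD compartments.  Equal contributions give 50%/50%; the
aphidicolin dose series shifts P_HO toward ~60%.

Also provided: relative replication speed Rs (50-kb bins traversed per
distinct corrected S-phase fraction in a compartment), relative DSB counts
across the five-dose series (log2[P_RDC / (sum_RDC/5)]), dual-strand
DNA:RNA-hybrid stratification of RDCs, DRIPc peak-density comparisons
(two-sided Mann-Whitney) and plain two-group tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .junctions import JunctionSet, Orientation
from .rdc import RdcCall
from .forks import ForkSegment, _overlap
from .repliseq import CorrectedFractionTrack

logger = logging.getLogger(__name__)

MIN_RPKM = 0.05
CONDITIONS_5 = ("untreated", "0.2uM", "0.3uM", "0.4uM", "0.6uM")


@dataclass(frozen=True)
class TrcCompartment:
    chrom: str
    start: int
    end: int
    mode: str  # head_on | co_directional
    fork_direction: str  # rightward | leftward
    tx_direction: str  # "+" | "-"
    matched_orientation: Orientation

    @property
    def length(self) -> int:
        return self.end - self.start


def assign_compartments(
    rdc: RdcCall,
    forks: list[ForkSegment],
    genes: pd.DataFrame,
    min_rpkm: float = MIN_RPKM,
) -> list[TrcCompartment]:
    """TRC compartments of one RDC from fork segments and gene annotation.

    ``genes`` needs columns chrom/start/end/strand/rpkm.  Only genes with
    rpkm >= min_rpkm count as transcribed.  For every (fork, gene) overlap
    inside the RDC, the compartment is head-on if the fork opposes the
    gene's transcription direction ("+" = rightward transcription), and its
    matched orientation is Dcen for rightward forks, Dtel for leftward.
    """
    active = genes[(genes["chrom"] == rdc.chrom) & (genes["rpkm"] >= min_rpkm)]
    out: list[TrcCompartment] = []
    for fork in forks:
        if fork.chrom != rdc.chrom:
            continue
        f_lo = max(fork.start, rdc.start)
        f_hi = min(fork.end, rdc.end)
        if f_hi <= f_lo:
            continue
        for g in active.itertuples(index=False):
            lo = max(f_lo, g.start)
            hi = min(f_hi, g.end)
            if hi <= lo:
                continue
            tx_right = g.strand == "+"
            fork_right = fork.direction == "rightward"
            mode = "co_directional" if tx_right == fork_right else "head_on"
            matched = Orientation.DCEN if fork_right else Orientation.DTEL
            out.append(TrcCompartment(rdc.chrom, lo, hi, mode,
                                      fork.direction, g.strand, matched))
    if not out:
        logger.info("RDC %s:%d-%d overlaps no active gene; excluded from "
                    "proportions", rdc.chrom, rdc.start, rdc.end)
    return out


def _matched_count(junctions: JunctionSet, comp: TrcCompartment) -> int:
    df = junctions.df
    return int(((df["chrom"] == comp.chrom)
                & (df["pos"] >= comp.start) & (df["pos"] < comp.end)
                & (df["orientation"] == comp.matched_orientation.value)).sum())


def proportions(junctions: JunctionSet,
                compartments: list[TrcCompartment]) -> tuple[float, float] | None:
    """(P_HO, P_CD) in percent, or None when no matched junctions exist.

    Junctions are aggregated across all compartments of the RDC before
    dividing (aggregate-then-divide).  P_HO + P_CD = 100 whenever defined.
    """
    n_ho = sum(_matched_count(junctions, c) for c in compartments
               if c.mode == "head_on")
    n_cd = sum(_matched_count(junctions, c) for c in compartments
               if c.mode == "co_directional")
    total = n_ho + n_cd
    if total == 0:
        logger.info("no matched-orientation junctions in any compartment; "
                    "RDC skipped")
        return None
    p_ho = 100.0 * n_ho / total
    return p_ho, 100.0 - p_ho


def relative_replication_speed(comp: TrcCompartment,
                               fractions: CorrectedFractionTrack) -> float:
    """Rs = 50-kb bins in the compartment / distinct S-phase fractions spent.

    A geometry-only speed proxy: more bins per fraction = faster replication.
    """
    bs = fractions.bin_size
    lo = comp.start // bs
    hi = max(lo + 1, -(-comp.end // bs))
    f = fractions.fractions[lo:hi]
    f = f[f > 0]
    n_frac = len(np.unique(f))
    if n_frac == 0:
        raise ValueError("compartment has no corrected-fraction coverage")
    return (hi - lo) / n_frac


def relative_dsb_count(per_condition_counts: dict[str, float],
                       pseudocount: float = 0.5) -> dict[str, float] | None:
    """log2[P_RDC / (sum_RDC / n)] per condition across the dose series.

    Zero counts are replaced by ``pseudocount`` in the numerator.  Returns
    None (RDC excluded) when the aggregate count is zero.
    """
    vals = np.array(list(per_condition_counts.values()), dtype=float)
    total = vals.sum()
    if total == 0:
        return None
    mean = total / len(vals)
    num = np.where(vals > 0, vals, pseudocount)
    out = np.log2(num / mean)
    return dict(zip(per_condition_counts.keys(), out.tolist()))


# ---------------------------------------------------------------------------
# DNA:RNA hybrid stratification and peak densities


def dual_strand_peaks(plus_peaks: pd.DataFrame,
                      minus_peaks: pd.DataFrame) -> pd.DataFrame:
    """Positional plus/minus peak overlaps, reported as merged intervals."""
    rows = []
    for p in plus_peaks.itertuples(index=False):
        on = minus_peaks[minus_peaks["chrom"] == p.chrom]
        for m in on.itertuples(index=False):
            if _overlap(p.start, p.end, m.start, m.end) > 0:
                rows.append((p.chrom, min(p.start, m.start), max(p.end, m.end)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def hybrid_stratify(rdcs: list[RdcCall], plus_peaks: pd.DataFrame,
                    minus_peaks: pd.DataFrame) -> dict[int, str]:
    """Stratify RDCs into low/mid/high by dual-strand hybrid counts.

    Dual-strand hybrids = positionally overlapping plus- and minus-strand
    DRIPc peaks.  RDCs with 0-2 hybrids form the "low" group; the remaining
    counts split at their upper tertile into "mid" and "high".
    """
    dual = dual_strand_peaks(plus_peaks, minus_peaks)
    counts = {}
    for i, rdc in enumerate(rdcs):
        on = dual[dual["chrom"] == rdc.chrom]
        counts[i] = int(sum(1 for d in on.itertuples(index=False)
                            if _overlap(d.start, d.end, rdc.start, rdc.end) > 0))
    labels = {}
    rest = [c for c in counts.values() if c > 2]
    cut = float(np.quantile(rest, 2 / 3)) if rest else np.inf
    for i, c in counts.items():
        labels[i] = "low" if c <= 2 else ("high" if c >= cut else "mid")
    return labels


def hybrid_counts(rdcs: list[RdcCall], plus_peaks: pd.DataFrame,
                  minus_peaks: pd.DataFrame) -> dict[int, int]:
    """Dual-strand hybrid count per RDC (by list index)."""
    dual = dual_strand_peaks(plus_peaks, minus_peaks)
    return {
        i: int(sum(1 for d in dual[dual["chrom"] == rdc.chrom].itertuples(index=False)
                   if _overlap(d.start, d.end, rdc.start, rdc.end) > 0))
        for i, rdc in enumerate(rdcs)
    }


def peak_density_compare(rdc_genes: pd.DataFrame, long_nonrdc_genes: pd.DataFrame,
                         peaks: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-gene peak density (peaks per 100 kb) and two-sided Mann-Whitney p.

    Compares RDC-containing genes with transcribed non-RDC genes longer than
    100 kb.  Exact null distribution below n = 20 per group (no ties),
    mid-rank normal approximation otherwise.
    """
    if len(rdc_genes) == 0 or len(long_nonrdc_genes) == 0:
        raise ValueError("both gene sets must be non-empty")

    def dens(genes: pd.DataFrame) -> np.ndarray:
        out = []
        for g in genes.itertuples(index=False):
            on = peaks[peaks["chrom"] == g.chrom]
            n = sum(1 for p in on.itertuples(index=False)
                    if _overlap(p.start, p.end, g.start, g.end) > 0)
            out.append(n / ((g.end - g.start) / 1e5))
        return np.array(out)

    a, b = dens(rdc_genes), dens(long_nonrdc_genes)
    method = "exact" if (len(a) < 20 and len(b) < 20
                         and len(np.unique(np.r_[a, b])) == len(a) + len(b)) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return a, b, float(res.pvalue)


def group_compare(values_a, values_b, test: str = "t_test") -> float:
    """Two-sided p-value comparing two groups (unpaired t or Mann-Whitney)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if test == "t_test":
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            # degenerate pooled variance: equal means are indistinguishable,
            # unequal constant groups are perfectly separated (t -> inf)
            return 1.0 if a.mean() == b.mean() else 0.0
        return float(stats.ttest_ind(a, b).pvalue)
    if test == "mann_whitney":
        if np.array_equal(np.sort(a), np.sort(b)):
            return 1.0
        method = "exact" if (len(a) < 20 and len(b) < 20
                             and len(np.unique(np.r_[a, b])) == len(a) + len(b)) \
            else "asymptotic"
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method=method).pvalue)
    raise ValueError(f"unknown test: {test!r}")
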