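"""Directional fork segments and RDC classification by fork configuration.

Fork direction between an initiation zone (IZ) and its flanking termination
meeting points is fixed by geometry: the fork emitted from the right edge of
an IZ moves rightward until the nearest termination point on the right, and
symmetrically on the left.  Timing transition regions (TTRs) contribute
segments with their own direction (an ascending early->late run is replicated
by a rightward fork).  Segments shorter than one Repli-seq bin (50 kb) cannot
be resolved and are dropped.  Only fork directions consistent across
technical repeats are kept.

An RDC is then classified by the configuration of fork segments overlapping
it: "inward" (a rightward fork left of a leftward fork, converging),
"unidirectional" (one direction only), "outward" (diverging), "complex"
(three or more fork segments) or "undetermined" (no usable overlap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .rdc import RdcCall
from .repliseq import ReplicationFeatureSet

logger = logging.getLogger(__name__)

MIN_FORK_BP = 50_000
BROAD_CTR_BP = 500_000


@dataclass(frozen=True)
class ForkSegment:
    chrom: str
    start: int
    end: int
    direction: str  # rightward | leftward
    source: str = "iz-to-tz"  # or "ttr"
    replicate_support: frozenset = field(default_factory=frozenset)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RdcClassification:
    rdc: RdcCall
    klass: str  # inward | unidirectional | outward | complex | undetermined
    biphasic: bool = False
    contains_ttr: bool = False
    contains_broad_lateCTR: bool = False
    n_forks: int = 0


def assemble_forks(
    features: ReplicationFeatureSet,
    tz_points: np.ndarray,
    *,
    bin_size: int = 50_000,
    min_fork_bp: int = MIN_FORK_BP,
    replicate_id: str | None = None,
    include_ttr: bool = True,
) -> list[ForkSegment]:
    """Connect IZ edges to nearest termination meeting points.

    ``tz_points`` are termination anchors as bin indices on the feature
    grid.  From each IZ's right edge a rightward segment runs to the nearest
    anchor on the right; from the left edge a leftward segment runs to the
    nearest anchor on the left.  One-sided IZs (no anchor on one side) get a
    one-sided assembly with a warning.  TTR features contribute their own
    directional segments.  Segments shorter than ``min_fork_bp`` are dropped.
    """
    support = frozenset([replicate_id]) if replicate_id else frozenset()
    tz_bp = np.sort(np.asarray(tz_points, dtype=np.int64)) * bin_size + bin_size // 2
    segments: list[ForkSegment] = []
    for iz in features.of_kind("IZ"):
        right = tz_bp[tz_bp > iz.end]
        left = tz_bp[tz_bp < iz.start]
        if len(right) == 0 or len(left) == 0:
            logger.warning("IZ %s:%d-%d lacks a termination anchor on one side; "
                           "one-sided fork assembly", iz.chrom, iz.start, iz.end)
        if len(right):
            seg = ForkSegment(iz.chrom, iz.end, int(right[0]), "rightward",
                              "iz-to-tz", support)
            if seg.length >= min_fork_bp:
                segments.append(seg)
        if len(left):
            seg = ForkSegment(iz.chrom, int(left[-1]), iz.start, "leftward",
                              "iz-to-tz", support)
            if seg.length >= min_fork_bp:
                segments.append(seg)
    if include_ttr:
        for ttr in features.of_kind("TTR"):
            if ttr.length >= min_fork_bp:
                segments.append(ForkSegment(ttr.chrom, ttr.start, ttr.end,
                                            ttr.direction, "ttr", support))
    return sorted(segments, key=lambda s: (s.start, s.end))


def _direction_profile(segments: list[ForkSegment], breakpoints: np.ndarray
                       ) -> list[set]:
    """Per elementary interval, the set of directions covering it."""
    out = [set() for _ in range(len(breakpoints) - 1)]
    for seg in segments:
        lo = np.searchsorted(breakpoints, seg.start, side="left")
        hi = np.searchsorted(breakpoints, seg.end, side="left")
        for i in range(lo, hi):
            out[i].add(seg.direction)
    return out


def consensus_forks(rep1: list[ForkSegment], rep2: list[ForkSegment],
                    *, min_fork_bp: int = MIN_FORK_BP) -> list[ForkSegment]:
    """Base-pair-wise intersection of two replicate fork-direction maps.

    A position keeps a direction only where both replicates assign exactly
    that single direction; consistent runs are re-segmented and runs shorter
    than ``min_fork_bp`` are dropped.  Commutative in its arguments.
    """
    if not rep1 or not rep2:
        return []
    chrom = rep1[0].chrom
    bp = np.unique(np.concatenate(
        [[s.start, s.end] for s in rep1] + [[s.start, s.end] for s in rep2], axis=0
    ))
    d1 = _direction_profile(rep1, bp)
    d2 = _direction_profile(rep2, bp)
    support = frozenset().union(*(s.replicate_support for s in rep1 + rep2))
    out: list[ForkSegment] = []
    cur: list | None = None  # [start, end, direction]
    for i in range(len(bp) - 1):
        direction = None
        if len(d1[i]) == 1 and d1[i] == d2[i]:
            direction = next(iter(d1[i]))
        if direction is not None and cur is not None and \
                cur[2] == direction and cur[1] == bp[i]:
            cur[1] = bp[i + 1]
        else:
            if cur is not None and cur[1] - cur[0] >= min_fork_bp:
                out.append(ForkSegment(chrom, cur[0], cur[1], cur[2], "iz-to-tz", support))
            cur = [int(bp[i]), int(bp[i + 1]), direction] if direction else None
    if cur is not None and cur[1] - cur[0] >= min_fork_bp:
        out.append(ForkSegment(chrom, cur[0], cur[1], cur[2], "iz-to-tz", support))
    return out


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def classify_rdc(
    rdc: RdcCall,
    forks: list[ForkSegment],
    features: ReplicationFeatureSet | None = None,
    *,
    min_overlap_bp: int = 50_000,
    broad_ctr_bp: int = BROAD_CTR_BP,
) -> RdcClassification:
    """Classify an RDC by the fork segments overlapping it.

    A fork overlaps when the shared span is >= one bin (50 kb).
    Overlapping or touching same-direction segments (e.g. a TTR and the
    IZ-to-TZ fork covering it) are merged into one directional stretch
    first.  Three or more stretches make the RDC "complex"; a single
    direction makes it "unidirectional"; two opposing stretches are
    "inward" when converging (rightward fork left of the leftward fork) and
    "outward" when diverging; no overlapping stretch leaves it
    "undetermined".
    """
    clipped = [
        (max(s.start, rdc.start), min(s.end, rdc.end), s.direction)
        for s in forks
        if s.chrom == rdc.chrom
        and _overlap(s.start, s.end, rdc.start, rdc.end) >= min_overlap_bp
    ]
    over: list[ForkSegment] = []
    for direction in ("rightward", "leftward"):
        ivs = sorted((a, b) for a, b, d in clipped if d == direction)
        merged: list[list[int]] = []
        for a, b in ivs:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        over.extend(ForkSegment(rdc.chrom, a, b, direction) for a, b in merged)
    contains_ttr = False
    contains_broad = False
    if features is not None:
        for f in features.features:
            if _overlap(f.start, f.end, rdc.start, rdc.end) > 0:
                if f.kind == "TTR":
                    contains_ttr = True
                if f.kind == "lateCTR" and f.length > broad_ctr_bp:
                    contains_broad = True

    if not over:
        klass = "undetermined"
    elif len(over) >= 3:
        klass = "complex"
    else:
        dirs = {s.direction for s in over}
        if len(dirs) == 1:
            klass = "unidirectional"
        else:
            right = next(s for s in over if s.direction == "rightward")
            left = next(s for s in over if s.direction == "leftward")
            mid_r = (right.start + right.end) / 2
            mid_l = (left.start + left.end) / 2
            klass = "inward" if mid_r <= mid_l else "outward"
    return RdcClassification(rdc, klass, contains_ttr=contains_ttr,
                             contains_broad_lateCTR=contains_broad,
                             n_forks=len(over))


def detect_biphasic(matrix_values: np.ndarray, rdc_cols: slice,
                    *, min_sep_fractions: int = 4, min_frac_bins: float = 0.2
                    ) -> bool:
    """Heuristic flag: two disjoint S-phase signal bands within the RDC.

    True when >= ``min_frac_bins`` of the RDC's bins have two local maxima
    in their 16-fraction profile separated by >= ``min_sep_fractions``.
    Off by default in classification; exposed for exploratory use.
    """
    sub = matrix_values[:, rdc_cols]
    n_biphasic = 0
    for col in sub.T:
        if col.sum() == 0:
            continue
        peaks = [i for i in range(1, 15)
                 if col[i] > col[i - 1] and col[i] >= col[i + 1] and col[i] > 0]
        if len(peaks) >= 2 and (max(peaks) - min(peaks)) >= min_sep_fractions:
            n_biphasic += 1
    n_cov = int((sub.sum(axis=0) > 0).sum())
    return n_cov > 0 and n_biphasic / n_cov >= min_frac_bins
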