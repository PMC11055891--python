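"""16-fraction Repli-seq normalization, corrected fractions and feature calls.

High-resolution Repli-seq sorts S-phase cells into 16 fractions (S1 earliest
... S16 latest) and sequences newly replicated DNA per fraction, yielding a
16 x N matrix of replication signal over 50-kb genomic bins.  A bin's signal
profile across the 16 fractions encodes when it replicates.

Processing steps:

* depth normalization per fraction, Gaussian smoothing along the genome,
  and per-bin column scaling to unit sum;
* BIRCH clustering of the per-bin 16-vectors into 80 clusters; each cluster's
  "corrected fraction" is the argmax fraction of its centroid, inherited by
  its member bins — a denoised per-bin replication-timing call in 1..16;
* feature calling on the corrected-fraction sequence: initiation zones (IZ,
  local timing minima), small termination zones (TZ, local maxima <= 100 kb),
  timing transition regions (TTR, monotone early->late runs tolerating
  plateaus of up to three equal-fraction bins) and late constant timing
  regions (late CTR, constant runs of more than three bins at fraction >= 12).

The 50-kb bin is motivated by fork kinetics: at ~1.8 kb/min a fork lays down
at least 54 kb of labeled DNA during a 30-min BrdU pulse, so one bin is the
smallest unit a single fork can fully traverse within the labeling window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.cluster import Birch

N_FRACTIONS = 16
BIN_SIZE = 50_000

#: Fork speed assumed when choosing the genomic bin, kb per minute.
FORK_SPEED_KB_PER_MIN = 1.8
#: BrdU labeling pulse for untreated cells, minutes.
BRDU_LABELING_MIN = 30


def min_labeled_kb_per_fork(speed_kb_per_min: float = FORK_SPEED_KB_PER_MIN,
                            labeling_min: float = BRDU_LABELING_MIN) -> float:
    """Minimum kb of BrdU-labeled DNA a single fork produces per pulse."""
    return speed_kb_per_min * labeling_min


@dataclass
class RepliseqMatrix:
    """16 x N replication signal for one chromosome at fixed bin size."""

    chrom: str
    values: np.ndarray  # shape (16, n_bins)
    bin_size: int = BIN_SIZE
    replicate_id: str | None = None
    condition: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != N_FRACTIONS:
            raise ValueError(f"expected a {N_FRACTIONS} x N matrix, got {self.values.shape}")
        if (self.values < 0).any():
            raise ValueError("negative Repli-seq signal")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def covered(self) -> np.ndarray:
        """Bins with any signal (unmappable bins are all-zero columns)."""
        return self.values.sum(axis=0) > 0


@dataclass
class CorrectedFractionTrack:
    """Per-bin corrected S-phase fraction in 1..16 (0 where missing)."""

    chrom: str
    fractions: np.ndarray  # int, 0 = missing
    cluster_ids: np.ndarray | None = None
    bin_size: int = BIN_SIZE


@dataclass(frozen=True)
class ReplicationFeature:
    kind: str  # IZ | TTR | lateCTR | smallTZ
    chrom: str
    start: int
    end: int
    direction: str = "none"  # rightward | leftward | none (TTR only)
    fraction_span: tuple[int, int] | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReplicationFeatureSet:
    chrom: str
    features: list[ReplicationFeature] = field(default_factory=list)
    covered_bp: int = 0

    def of_kind(self, kind: str) -> list[ReplicationFeature]:
        return [f for f in self.features if f.kind == kind]


def normalize_and_smooth(raw: RepliseqMatrix, sigma_bins: float = 1.0,
                         target_depth: float = 50e6) -> RepliseqMatrix:
    """Depth-normalize, Gaussian-smooth along the genome, column-scale.

    Each fraction row is scaled to ``target_depth`` total signal (a
    reads-per-50-million equivalent), smoothed along the genomic axis with
    s.d. ``sigma_bins`` (0 = no smoothing), then each bin column is scaled to
    unit sum so a column is the distribution of that bin's replication over
    the 16 fractions.  All-zero columns stay zero.
    """
    v = raw.values.copy()
    if not v.any():
        raise ValueError("all-zero Repli-seq matrix")
    row_sums = v.sum(axis=1, keepdims=True)
    nz = row_sums[:, 0] > 0
    v[nz] *= target_depth / row_sums[nz]
    if sigma_bins > 0:
        v = gaussian_filter1d(v, sigma=sigma_bins, axis=1, mode="constant")
    col = v.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(col > 0, v / np.where(col > 0, col, 1.0), 0.0)
    return RepliseqMatrix(raw.chrom, v, raw.bin_size, raw.replicate_id, raw.condition)


def birch_fractions(matrix: RepliseqMatrix, n_clusters: int = 80,
                    threshold: float = 0.02) -> CorrectedFractionTrack:
    """Cluster per-bin 16-vectors with BIRCH; assign corrected fractions.

    Each cluster's corrected fraction is argmax over its centroid's 16
    components (earliest fraction on ties), inherited by member bins.  Bins
    without signal get fraction 0 (missing).  Input order is genomic order,
    keeping BIRCH deterministic.
    """
    cov = matrix.covered()
    x = matrix.values.T[cov]
    fractions = np.zeros(matrix.n_bins, dtype=int)
    cluster_ids = np.full(matrix.n_bins, -1, dtype=int)
    if len(x) == 0:
        return CorrectedFractionTrack(matrix.chrom, fractions, cluster_ids, matrix.bin_size)
    k = n_clusters
    if len(x) < k:
        warnings.warn(f"only {len(x)} usable bins; reducing BIRCH clusters from {k}")
        k = max(1, len(x))
    # agglomeration cannot produce more clusters than distinct points
    k = min(k, len(np.unique(x, axis=0)))
    if k <= 1 or len(x) < 2:
        labels = np.zeros(len(x), dtype=int)
    else:
        model = Birch(n_clusters=k, threshold=threshold)
        labels = model.fit_predict(x)
    corrected = np.zeros(labels.max() + 1, dtype=int)
    for c in range(labels.max() + 1):
        members = x[labels == c]
        if len(members) == 0:
            continue
        centroid = members.mean(axis=0)
        corrected[c] = int(np.argmax(centroid)) + 1  # argmax takes earliest on ties
    fractions[cov] = corrected[labels]
    cluster_ids[cov] = labels
    return CorrectedFractionTrack(matrix.chrom, fractions, cluster_ids, matrix.bin_size)


# ---------------------------------------------------------------------------
# feature calling on the corrected-fraction sequence


def _segments(fractions: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of defined (non-missing) bins, half-open indices."""
    mask = fractions > 0
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _plateau_runs(f: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode: (start, end, value) for equal-fraction runs."""
    runs = []
    s = 0
    for i in range(1, len(f) + 1):
        if i == len(f) or f[i] != f[s]:
            runs.append((s, i, int(f[s])))
            s = i
    return runs


def _call_segment(f: np.ndarray, offset: int, chrom: str, bin_size: int,
                  plateau_tol: int, late_fraction: int,
                  tz_max_bins: int) -> list[ReplicationFeature]:
    """Feature-call one gap-free corrected-fraction run.

    Works on the run-length encoding.  A TTR is a maximal monotone chain of
    runs in which internal plateaus of <= plateau_tol bins are tolerated;
    longer plateaus become constant-timing runs that break the chain and are
    reported as late CTR when late enough.  Local minima flanked by ascent
    become IZs; local maxima spanning <= tz_max_bins become small TZs.
    """
    runs = _plateau_runs(f)
    n = len(runs)
    feats: list[ReplicationFeature] = []

    def emit(kind, s, e, direction="none", span=None):
        feats.append(ReplicationFeature(kind, chrom, (offset + s) * bin_size,
                                        (offset + e) * bin_size, direction, span))

    long_plateau = [(e - s) > plateau_tol for s, e, _ in runs]

    # --- TTRs: maximal chains of runs with all steps strict in one direction
    # and every run short (a >plateau_tol equal-fraction run breaks the chain
    # and is excluded entirely).  In the run-length encoding every adjacent
    # step is strict, so tolerated plateaus are simply short internal runs.
    prev_end = -1  # run index consumed as the end of the previous chain
    i = 0
    while i < n - 1:
        if long_plateau[i] or long_plateau[i + 1]:
            i += 1
            continue
        direction = int(np.sign(runs[i + 1][2] - runs[i][2]))
        j = i + 1
        while (j < n - 1 and not long_plateau[j + 1]
               and int(np.sign(runs[j + 1][2] - runs[j][2])) == direction):
            j += 1
        # a run shared with the previous chain's end (a local extremum)
        # stays with that chain to keep TTRs disjoint
        first = i + 1 if i == prev_end else i
        if j > first and runs[j][2] != runs[first][2]:
            emit("TTR", runs[first][0], runs[j][1],
                 "rightward" if direction > 0 else "leftward",
                 (runs[first][2], runs[j][2]))
            prev_end = j
        i = j

    # --- constant runs: late CTR when long and late
    for (s, e, val), lp in zip(runs, long_plateau):
        if lp and val >= late_fraction:
            emit("lateCTR", s, e, span=(val, val))

    # --- local extrema: IZ (minima) and small TZ (maxima <= tz_max_bins)
    for idx, (s, e, val) in enumerate(runs):
        left = runs[idx - 1][2] if idx > 0 else None
        right = runs[idx + 1][2] if idx < n - 1 else None
        if left is not None and right is not None:
            if val < left and val < right:
                emit("IZ", s, e, span=(val, val))
            elif val > left and val > right and (e - s) <= tz_max_bins:
                emit("smallTZ", s, e, span=(val, val))
    return feats


def call_features(track: CorrectedFractionTrack, *, plateau_tol: int = 3,
                  late_fraction: int = 12, tz_max_bp: int = 100_000
                  ) -> ReplicationFeatureSet:
    """Call IZ/TTR/lateCTR/smallTZ features from corrected fractions.

    Missing (fraction 0) bins break all features.  Features of one kind are
    disjoint and sorted; TTRs carry a direction (rightward = ascending
    early->late leftward->rightward, i.e. a rightward-moving fork).
    """
    feats: list[ReplicationFeature] = []
    tz_max_bins = max(1, tz_max_bp // track.bin_size)
    for s, e in _segments(track.fractions):
        feats.extend(
            _call_segment(track.fractions[s:e], s, track.chrom, track.bin_size,
                          plateau_tol, late_fraction, tz_max_bins)
        )
    feats.sort(key=lambda f: (f.start, f.kind))
    covered = int((track.fractions > 0).sum()) * track.bin_size
    return ReplicationFeatureSet(track.chrom, feats, covered)


def genome_feature_fractions(features: ReplicationFeatureSet) -> dict[str, float]:
    """Fraction of the covered genome occupied by each feature kind."""
    if features.covered_bp == 0:
        return {}
    out: dict[str, float] = {}
    for f in features.features:
        out[f.kind] = out.get(f.kind, 0) + f.length
    return {k: v / features.covered_bp for k, v in out.items()}


# ---------------------------------------------------------------------------
# I/O


def read_matrix_tsv(path: str | Path, chrom: str | None = None) -> RepliseqMatrix:
    """Read a 16-row TSV matrix (rows S1..S16, columns = genomic bins)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RepliseqMatrix(chrom or "chr1", df.to_numpy(dtype=float))


def write_matrix_tsv(matrix: RepliseqMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values,
                      index=[f"S{i}" for i in range(1, N_FRACTIONS + 1)])
    df.to_csv(path, sep="\t")


def read_fraction_bedgraphs(paths: list[str | Path], chrom: str,
                            chrom_length: int, bin_size: int = BIN_SIZE) -> RepliseqMatrix:
    """Assemble a RepliseqMatrix from 16 per-fraction bedGraph files."""
    if len(paths) != N_FRACTIONS:
        raise ValueError(f"expected {N_FRACTIONS} bedGraph files, got {len(paths)}")
    n_bins = int(np.ceil(chrom_length / bin_size))
    values = np.zeros((N_FRACTIONS, n_bins))
    for i, p in enumerate(paths):
        bg = pd.read_csv(p, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"])
        bg = bg[bg["chrom"] == chrom]
        values[i, bg["start"].to_numpy() // bin_size] = bg["value"].to_numpy()
    return RepliseqMatrix(chrom, values, bin_size)


def features_to_bed(features: ReplicationFeatureSet, path: str | Path) -> None:
    strand = {"rightward": "+", "leftward": "-", "none": "."}
    rows = [
        (f.chrom, f.start, f.end, f.kind, 0, strand[f.direction])
        for f in features.features
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
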