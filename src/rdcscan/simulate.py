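"""Synthetic genomes with a planted replication program and break clusters.

The generator emits every input the pipeline consumes — a 16-fraction
Repli-seq matrix, OK-seq strand counts, LAM-HTGTS junction libraries across
an aphidicolin dose series, gene annotation with expression, and
strand-specific DRIPc peaks — together with a machine-readable truth bundle
(origins, fork segments, features, planted RDC intervals and biases) for
parameter-recovery tests.

Replication model: each origin i fires at S-phase fraction f_i and sends two
forks outward at constant speed v (kb per fraction).  A locus x replicates at

    t(x) = min_i [ f_i + |x - o_i| / v ],  capped at fraction 16.

Two adjacent origins meet at the timing maximum between them,

    x* = (o_i + o_{i+1}) / 2 + v (f_{i+1} - f_i) / 2,

which is the planted termination meeting point.  The Repli-seq signal for a
bin is a Gaussian band (s.d. 1.5 fractions) around t(x), Poisson-sampled at
the configured depth.  OK-seq strand counts follow local fork directionality
(rightward forks give reverse-strand Okazaki excess under the package's RFD
sign convention).  Junctions are background negative-binomial noise plus
planted RDC enrichment whose orientation follows the local fork direction
(Dcen under rightward, Dtel under leftward forks) and whose head-on :
co-directional placement follows the planted bias theta.

Defaults describe one 100-Mb chromosome at 50-kb bins with origins every
~3 Mb — desk-scale but structurally faithful to mammalian replication
programs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .junctions import JunctionSet, Library, Orientation
from .repliseq import N_FRACTIONS, RepliseqMatrix
from .forks import ForkSegment

DEFAULT_CONDITIONS = ("untreated", "0.2uM", "0.3uM", "0.4uM", "0.6uM")
DEFAULT_FOLDS = {"untreated": 1.0, "0.2uM": 2.0, "0.3uM": 3.0,
                 "0.4uM": 4.0, "0.6uM": 6.0}


@dataclass
class PlantedRdc:
    start: int
    end: int
    klass: str = "inward"  # descriptive; geometry comes from fork placement
    folds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FOLDS))
    theta: float = 0.6  # head-on bias
    n_dual_hybrids: int = 0

    def __post_init__(self):
        if self.end - self.start < 300_000:
            raise ValueError("planted RDC intervals must be >= 300 kb")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")


@dataclass
class SimConfig:
    seed: int = 0
    chrom: str = "chr1"
    chrom_length: int = 100_000_000
    bait_chrom: str = "chr9"
    bait_chrom_length: int = 10_000_000
    bin_size: int = 50_000
    # replication program
    origins: list[tuple[int, int]] | None = None  # (pos_bp, firing_fraction)
    fork_speed_kb_per_fraction: float = 150.0
    fraction_sigma: float = 1.5
    repliseq_depth: float = 100.0  # expected reads per bin column
    okseq_depth: float = 100.0  # expected Okazaki reads per bin
    rfd_amplitude: float = 0.8  # |RFD| expectation inside a pure fork
    # junction model
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    background_nb_mean: float = 10.0  # junctions per 50-kb bin
    background_nb_dispersion: float = 10.0
    planted_rdcs: list[PlantedRdc] = field(default_factory=list)
    offtarget_interval: tuple[int, int] = (90_000_000, 90_005_000)
    offtarget_mean: float = 200.0
    bait_junction_mean: float = 500.0
    # annotation
    genes: list[tuple[int, int, str, float]] | None = None  # start,end,strand,rpkm

    def origin_list(self) -> list[tuple[int, int]]:
        if self.origins is not None:
            return list(self.origins)
        spacing = 2_000_000
        firing = [1, 4, 2, 6, 3, 5]
        out = []
        pos = 1_000_000
        i = 0
        while pos < self.chrom_length - 500_000:
            out.append((pos, firing[i % len(firing)]))
            pos += spacing
            i += 1
        return out

    def validate(self) -> None:
        o = sorted(p for p, _ in self.origin_list())
        if any(b - a < 2 * self.bin_size for a, b in zip(o, o[1:])):
            raise ValueError("origins denser than one per two bins are unresolvable")
        if self.repliseq_depth <= 0 or self.okseq_depth <= 0:
            raise ValueError("sequencing depth must be positive")


# ---------------------------------------------------------------------------
# replication


def true_timing(config: SimConfig) -> np.ndarray:
    """Per-bin replication fraction t(x) in [1, 16] (continuous)."""
    v_bp = config.fork_speed_kb_per_fraction * 1_000
    n_bins = config.chrom_length // config.bin_size
    centers = (np.arange(n_bins) + 0.5) * config.bin_size
    t = np.full(n_bins, np.inf)
    for pos, frac in config.origin_list():
        t = np.minimum(t, frac + np.abs(centers - pos) / v_bp)
    return np.clip(t, 1, N_FRACTIONS)


def true_forks(config: SimConfig) -> tuple[list[ForkSegment], list[int]]:
    """Planted fork segments (bp coordinates) and meeting points (bp)."""
    v_bp = config.fork_speed_kb_per_fraction * 1_000
    origins = sorted(config.origin_list())
    segments: list[ForkSegment] = []
    meetings: list[int] = []
    first, last = origins[0][0], origins[-1][0]
    segments.append(ForkSegment(config.chrom, 0, first, "leftward", "iz-to-tz"))
    for (o1, f1), (o2, f2) in zip(origins, origins[1:]):
        x_star = (o1 + o2) / 2 + v_bp * (f2 - f1) / 2
        x_star = int(np.clip(x_star, o1 + 1, o2 - 1))
        meetings.append(x_star)
        segments.append(ForkSegment(config.chrom, o1, x_star, "rightward", "iz-to-tz"))
        segments.append(ForkSegment(config.chrom, x_star, o2, "leftward", "iz-to-tz"))
    segments.append(ForkSegment(config.chrom, last, config.chrom_length,
                                "rightward", "iz-to-tz"))
    return segments, meetings


def direction_at(forks: list[ForkSegment], pos: np.ndarray) -> np.ndarray:
    """+1 rightward, -1 leftward, 0 uncovered, for bp positions."""
    out = np.zeros(len(pos), dtype=int)
    for seg in forks:
        sign = 1 if seg.direction == "rightward" else -1
        out[(pos >= seg.start) & (pos < seg.end)] = sign
    return out


def simulate_replication(config: SimConfig, rng: np.random.Generator | None = None
                         ) -> tuple[RepliseqMatrix, dict]:
    """Simulate a raw (count-level) Repli-seq matrix plus the planted truth."""
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    t = true_timing(config)
    frac_axis = np.arange(1, N_FRACTIONS + 1, dtype=float)[:, None]
    weights = np.exp(-0.5 * ((frac_axis - t[None, :]) / config.fraction_sigma) ** 2)
    weights /= weights.sum(axis=0, keepdims=True)
    expected = weights * config.repliseq_depth
    matrix = RepliseqMatrix(config.chrom, rng.poisson(expected).astype(float),
                            config.bin_size)
    forks, meetings = true_forks(config)
    truth = {
        "chrom": config.chrom,
        "chrom_length": config.chrom_length,
        "bin_size": config.bin_size,
        "origins": config.origin_list(),
        "fork_speed_kb_per_fraction": config.fork_speed_kb_per_fraction,
        "true_fraction": np.clip(np.round(t), 1, N_FRACTIONS).astype(int).tolist(),
        "iz_bp": [int(p) for p, _ in sorted(config.origin_list())],
        "tz_bp": meetings,
        "iz_bins": [int(p // config.bin_size) for p, _ in sorted(config.origin_list())],
        "tz_bins": [int(m // config.bin_size) for m in meetings],
        "forks": [{"start": s.start, "end": s.end, "direction": s.direction}
                  for s in forks],
    }
    return matrix, truth


def simulate_okseq(config: SimConfig, forks: list[ForkSegment],
                   rng: np.random.Generator | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Strand-specific Okazaki counts (F, R) per bin following fork direction."""
    rng = rng or np.random.default_rng(config.seed + 1)
    n_bins = config.chrom_length // config.bin_size
    centers = (np.arange(n_bins) + 0.5) * config.bin_size
    rfd = direction_at(forks, centers).astype(float) * config.rfd_amplitude
    depth = config.okseq_depth
    R = rng.poisson(depth * (1 + rfd) / 2)
    F = rng.poisson(depth * (1 - rfd) / 2)
    return F.astype(float), R.astype(float)


# ---------------------------------------------------------------------------
# annotation


def default_genes(config: SimConfig) -> list[tuple[int, int, str, float]]:
    """One long active minus-strand gene spanning each planted RDC.

    Over an inward fork pair a leftward-transcribed gene makes the
    rightward-fork side head-on and the leftward-fork side co-directional.
    """
    genes = []
    for rdc in config.planted_rdcs:
        genes.append((max(0, rdc.start - 50_000),
                      min(config.chrom_length, rdc.end + 50_000), "-", 5.0))
    return genes


def simulate_annotation(config: SimConfig, rng: np.random.Generator | None = None
                        ) -> dict[str, pd.DataFrame]:
    """Gene table (chrom/start/end/strand/rpkm) and DRIPc peak BED frames."""
    rng = rng or np.random.default_rng(config.seed + 2)
    gene_list = config.genes if config.genes is not None else default_genes(config)
    genes = pd.DataFrame(
        [(config.chrom, s, e, strand, rpkm) for s, e, strand, rpkm in gene_list],
        columns=["chrom", "start", "end", "strand", "rpkm"],
    )
    by_strand = genes.groupby("strand")["start"].count() if len(genes) else None
    for strand in ("+", "-"):
        sub = genes[genes["strand"] == strand].sort_values("start")
        prev_end = -1
        for g in sub.itertuples(index=False):
            if g.start < prev_end:
                import warnings

                warnings.warn("overlapping genes on the same strand")
            prev_end = g.end

    plus_rows, minus_rows = [], []
    for rdc in config.planted_rdcs:
        width = 2_000
        span = rdc.end - rdc.start
        for k in range(rdc.n_dual_hybrids):
            center = rdc.start + int((k + 1) * span / (rdc.n_dual_hybrids + 1))
            plus_rows.append((config.chrom, center - width, center + width))
            minus_rows.append((config.chrom, center - width // 2,
                               center + width + width // 2))
    cols = ["chrom", "start", "end"]
    return {
        "genes": genes,
        "dripc_plus": pd.DataFrame(plus_rows, columns=cols),
        "dripc_minus": pd.DataFrame(minus_rows, columns=cols),
    }


# ---------------------------------------------------------------------------
# junctions


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float,
               size: int) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _compartment_bp(rdc: PlantedRdc, forks: list[ForkSegment],
                    genes: pd.DataFrame, chrom: str) -> dict[str, list[tuple[int, int]]]:
    """Head-on / co-directional bp intervals inside one planted RDC."""
    out = {"head_on": [], "co_directional": []}
    active = genes[(genes["chrom"] == chrom) & (genes["rpkm"] >= 0.05)]
    for fork in forks:
        lo = max(fork.start, rdc.start)
        hi = min(fork.end, rdc.end)
        if hi <= lo:
            continue
        for g in active.itertuples(index=False):
            a, b = max(lo, g.start), min(hi, g.end)
            if b <= a:
                continue
            co = (g.strand == "+") == (fork.direction == "rightward")
            out["co_directional" if co else "head_on"].append((a, b))
    return out


def simulate_junctions(config: SimConfig, forks: list[ForkSegment],
                       genes: pd.DataFrame | None = None,
                       rng: np.random.Generator | None = None
                       ) -> dict[str, Library]:
    """One junction library per aphidicolin condition.

    Background: per-bin counts ~ NB(mean, dispersion), positions uniform in
    the bin, orientation Bernoulli(1/2).  Planted RDCs add
    ``background_mean * (fold - 1)`` junctions per bin on average, each
    placed in a head-on compartment with probability theta (else
    co-directional) and oriented by the local fork direction.  The off-target
    interval receives a condition-invariant Poisson count; the bait
    chromosome receives filler junctions removed by the viewpoint filter.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    if genes is None:
        genes = simulate_annotation(config)["genes"]
    n_bins = config.chrom_length // config.bin_size
    dcen, dtel = Orientation.DCEN.value, Orientation.DTEL.value

    # sorted fork-boundary arrays for vectorized direction lookup
    fsorted = sorted(forks, key=lambda s: s.start)
    f_starts = np.array([s.start for s in fsorted], dtype=np.int64)
    f_ends = np.array([s.end for s in fsorted], dtype=np.int64)
    f_sign = np.array([1 if s.direction == "rightward" else -1 for s in fsorted])

    def dir_sign(pos: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(f_starts, pos, side="right") - 1, 0, None)
        ok = (pos >= f_starts[idx]) & (pos < f_ends[idx])
        return np.where(ok, f_sign[idx], 0)

    def _sample_in(ivs: list[tuple[int, int]], n: int) -> np.ndarray:
        lens = np.array([b - a for a, b in ivs], dtype=np.int64)
        starts = np.array([a for a, _ in ivs], dtype=np.int64)
        cum = np.concatenate(([0], np.cumsum(lens)))
        u = rng.integers(0, cum[-1], size=n)
        which = np.searchsorted(cum, u, side="right") - 1
        return starts[which] + (u - cum[which])

    libraries: dict[str, Library] = {}
    for cond in config.conditions:
        pos_parts, ori_parts, chrom_parts = [], [], []

        bg = _nb_counts(rng, config.background_nb_mean,
                        config.background_nb_dispersion, n_bins)
        total_bg = int(bg.sum())
        bg_pos = (np.repeat(np.arange(n_bins), bg) * config.bin_size
                  + rng.integers(0, config.bin_size, size=total_bg))
        pos_parts.append(bg_pos)
        ori_parts.append(rng.choice([dcen, dtel], size=total_bg))
        chrom_parts.append(np.full(total_bg, config.chrom, dtype=object))

        for rdc in config.planted_rdcs:
            fold = rdc.folds.get(cond, 1.0)
            if fold <= 1.0:
                continue
            comp = _compartment_bp(rdc, forks, genes, config.chrom)
            lam = config.background_nb_mean * (fold - 1.0) \
                * (rdc.end - rdc.start) / config.bin_size
            n_extra = int(rng.poisson(lam))
            if n_extra == 0:
                continue
            is_ho = rng.random(n_extra) < rdc.theta
            pos = np.empty(n_extra, dtype=np.int64)
            for mode, sel in (("head_on", is_ho), ("co_directional", ~is_ho)):
                k = int(sel.sum())
                if k == 0:
                    continue
                other = "co_directional" if mode == "head_on" else "head_on"
                ivs = comp[mode] or comp[other]
                pos[sel] = (_sample_in(ivs, k) if ivs
                            else rng.integers(rdc.start, rdc.end, size=k))
            d = dir_sign(pos)
            pos_parts.append(pos)
            ori_parts.append(np.where(d >= 0, dcen, dtel))
            chrom_parts.append(np.full(n_extra, config.chrom, dtype=object))

        ot_lo, ot_hi = config.offtarget_interval
        n_ot = int(rng.poisson(config.offtarget_mean))
        pos_parts.append(rng.integers(ot_lo, ot_hi, size=n_ot))
        ori_parts.append(rng.choice([dcen, dtel], size=n_ot))
        chrom_parts.append(np.full(n_ot, config.chrom, dtype=object))

        n_bait = int(rng.poisson(config.bait_junction_mean))
        pos_parts.append(rng.integers(0, config.bait_chrom_length, size=n_bait))
        ori_parts.append(rng.choice([dcen, dtel], size=n_bait))
        chrom_parts.append(np.full(n_bait, config.bait_chrom, dtype=object))

        df = pd.DataFrame({
            "chrom": np.concatenate(chrom_parts),
            "pos": np.concatenate(pos_parts).astype(np.int64),
            "orientation": np.concatenate(ori_parts),
        })
        df["bait_chrom"] = config.bait_chrom
        df["library_id"] = f"lib_{cond}"
        df["condition"] = cond
        libraries[cond] = Library(f"lib_{cond}", config.bait_chrom, cond,
                                  JunctionSet(df), offtarget_count=int(n_ot))
    return libraries


# ---------------------------------------------------------------------------
# bundle


def default_planted_rdcs(config: SimConfig) -> list[PlantedRdc]:
    """Plant one inward and one unidirectional RDC on the default program."""
    forks, meetings = true_forks(config)
    rdcs = [
        PlantedRdc(meetings[0] - 250_000, meetings[0] + 250_000, "inward",
                   n_dual_hybrids=4),
    ]
    right = next(s for s in forks if s.direction == "rightward"
                 and s.length >= 800_000)
    mid = (right.start + right.end) // 2
    rdcs.append(PlantedRdc(mid - 200_000, mid + 200_000, "unidirectional",
                           n_dual_hybrids=1))
    return rdcs


def simulate_all(config: SimConfig) -> dict:
    """Run every generator stage under one seed; return data + truth."""
    if not config.planted_rdcs:
        config.planted_rdcs = default_planted_rdcs(config)
    rng = np.random.default_rng(config.seed)
    matrix, truth = simulate_replication(config, rng)
    forks = [ForkSegment(config.chrom, f["start"], f["end"], f["direction"])
             for f in truth["forks"]]
    F, R = simulate_okseq(config, forks, rng)
    annotation = simulate_annotation(config, rng)
    libraries = simulate_junctions(config, forks, annotation["genes"], rng)
    truth["rdcs"] = [
        {"start": r.start, "end": r.end, "class": r.klass, "theta": r.theta,
         "folds": r.folds, "n_dual_hybrids": r.n_dual_hybrids}
        for r in config.planted_rdcs
    ]
    truth["genes"] = annotation["genes"].to_dict(orient="records")
    return {
        "config": config,
        "matrix": matrix,
        "okseq_F": F,
        "okseq_R": R,
        "annotation": annotation,
        "libraries": libraries,
        "truth": truth,
    }


def emit(config: SimConfig, outdir: str | Path) -> dict:
    """Write all synthetic inputs plus truth.json to ``outdir``; return bundle."""
    from .junctions import write_junctions_bed6
    from .repliseq import write_matrix_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_all(config)
    write_matrix_tsv(bundle["matrix"], outdir / "repliseq_matrix.tsv")
    bins = np.arange(len(bundle["okseq_F"]))
    for name, vals in (("okseq_F", bundle["okseq_F"]), ("okseq_R", bundle["okseq_R"])):
        pd.DataFrame({
            "chrom": config.chrom,
            "start": bins * config.bin_size,
            "end": (bins + 1) * config.bin_size,
            "value": vals,
        }).to_csv(outdir / f"{name}.bedGraph", sep="\t", header=False, index=False)
    for cond, lib in bundle["libraries"].items():
        write_junctions_bed6(lib.junctions, outdir / f"junctions_{cond}.bed")
    ann = bundle["annotation"]
    ann["genes"].to_csv(outdir / "genes.tsv", sep="\t", index=False)
    ann["dripc_plus"].to_csv(outdir / "dripc_plus.bed", sep="\t", header=False,
                             index=False)
    ann["dripc_minus"].to_csv(outdir / "dripc_minus.bed", sep="\t", header=False,
                              index=False)
    ot_lo, ot_hi = config.offtarget_interval
    pd.DataFrame([(config.chrom, ot_lo, ot_hi)]).to_csv(
        outdir / "offtargets.bed", sep="\t", header=False, index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(bundle["truth"], fh, indent=1)
    return bundle
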