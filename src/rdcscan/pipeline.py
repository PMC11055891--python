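"""End-to-end pipeline: simulate or load inputs, call RDCs, reconstruct the
replication program, classify RDCs and compute TRC statistics.

Stages run in dependency order:

    junctions -> pileup/p-values -> RDC calls
    repliseq  -> corrected fractions -> features
    OK-seq    -> reference IZ/TZ -> CNN training -> termination points
    features + termination points -> fork segments -> RDC classification
    RDCs + forks + genes + junctions -> P_HO/P_CD, Rs, relative DSB, hybrids

Every stage logs its parameters; stage outputs are cached in the working
directory keyed by a checksum of the stage inputs and parameters, so partial
reruns reuse results and a rerun with an identical config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import forks as forks_mod
from . import junctions as jmod
from . import rdc as rdc_mod
from . import repliseq as rmod
from . import simulate as sim
from . import trc as trc_mod
from . import tznet

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds with their canonical defaults, plus the seed."""

    seed: int = 0
    workdir: str = "rdcscan_out"
    # RDC caller
    half_width: int = 50_000
    pileup_bin: int = 1_000
    p_seed: float = 0.01
    p_extend: float = 0.1
    seed_gap: int = 10_000
    island_gap: int = 100_000
    min_sig: int = 100_000
    min_len: int = 300_000
    # Repli-seq
    bin_size: int = 50_000
    smoothing_sigma: float = 1.0
    n_clusters: int = 80
    late_fraction: int = 12
    plateau_tol: int = 3
    # transcription / TRC
    rpkm_min: float = 0.05
    # CNN
    tz_epochs: int = 40
    tz_lr: float = 1e-3
    tz_dropout: float = 0.9
    tz_batch: int = 32
    tz_folds: int = 10
    tz_threshold: float = 0.5
    tz_min_windows: int = 100
    # synthetic input scale (when simulating)
    chrom_length: int = 100_000_000

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _to_py(obj):
    """Recursively convert numpy scalars for JSON serialization."""
    if isinstance(obj, dict):
        return {k: _to_py(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_py(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


def _key(payload) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


class _Cache:
    def __init__(self, root: Path):
        self.root = root / "cache"
        self.root.mkdir(parents=True, exist_ok=True)

    def get(self, stage: str, key: str):
        f = self.root / f"{stage}.json"
        if f.exists():
            data = json.loads(f.read_text())
            if data.get("key") == key:
                logger.info("stage %s: cache hit", stage)
                return data["value"]
        return None

    def put(self, stage: str, key: str, value) -> None:
        (self.root / f"{stage}.json").write_text(
            json.dumps({"key": key, "value": value}, sort_keys=True)
        )


def run_pipeline(config: PipelineConfig, sim_config: sim.SimConfig | None = None
                 ) -> dict:
    """Run all stages on a synthetic genome; return the consolidated report.

    ``sim_config`` defaults to the generator's study conditions at
    ``config.chrom_length`` with the pipeline seed.
    """
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    cache = _Cache(workdir)
    if sim_config is None:
        sim_config = sim.SimConfig(seed=config.seed,
                                   chrom_length=config.chrom_length)
    logger.info("pipeline seed=%d workdir=%s", config.seed, workdir)

    bundle = sim.emit(sim_config, workdir / "inputs")
    truth = bundle["truth"]
    chrom = sim_config.chrom
    chrom_len = sim_config.chrom_length

    # --- stage: RDC calling per condition ---------------------------------
    rdc_key = _key([dataclasses.asdict(config), sim_config.seed, "rdc"])
    cached = cache.get("rdc_calls", rdc_key)
    calls_by_cond: dict[str, list[rdc_mod.RdcCall]] = {}
    if cached is None:
        serial = {}
        for cond, lib in bundle["libraries"].items():
            inter = jmod.filter_viewpoint(lib)
            pvals = {}
            for ori in ("Dcen", "Dtel", None):
                track = rdc_mod.extend_and_pileup(
                    inter, chrom, chrom_len, half_width=config.half_width,
                    bin_size=config.pileup_bin, orientation=ori)
                bg = rdc_mod.fit_background(track)
                pvals[ori or "both"] = rdc_mod.pileup_pvalues(track, bg)
            calls = rdc_mod.call_rdc(
                pvals, p_seed=config.p_seed, p_extend=config.p_extend,
                seed_gap=config.seed_gap, island_gap=config.island_gap,
                min_sig=config.min_sig, min_len=config.min_len)
            calls_by_cond[cond] = calls
            serial[cond] = [[c.chrom, int(c.start), int(c.end), int(c.sig_bp)]
                            for c in calls]
        cache.put("rdc_calls", rdc_key, serial)
    else:
        calls_by_cond = {
            cond: [rdc_mod.RdcCall(c[0], c[1], c[2], c[3]) for c in rows]
            for cond, rows in cached.items()
        }

    # union RDC list across conditions (combined datasets)
    pooled = sorted((c.start // config.pileup_bin, c.end // config.pileup_bin)
                    for cs in calls_by_cond.values() for c in cs)
    merged = rdc_mod._join_within(pooled, 0)
    rdcs = [rdc_mod.RdcCall(chrom, s * config.pileup_bin, e * config.pileup_bin, 0)
            for s, e in merged]

    # --- stage: replication features --------------------------------------
    norm = rmod.normalize_and_smooth(bundle["matrix"], config.smoothing_sigma)
    track = rmod.birch_fractions(norm, config.n_clusters)
    features = rmod.call_features(track, plateau_tol=config.plateau_tol,
                                  late_fraction=config.late_fraction)

    # --- stage: termination prediction ------------------------------------
    rfd = tznet.compute_rfd(bundle["okseq_F"], bundle["okseq_R"], chrom,
                            config.bin_size)
    iz_bins, tz_bins = tznet.reference_iz_tz(rfd)
    windows = tznet.make_training_windows(norm, iz_bins, tz_bins)
    model, cv = tznet.train_tz_model(
        windows, seed=config.seed, epochs=config.tz_epochs, lr=config.tz_lr,
        dropout=config.tz_dropout, batch_size=config.tz_batch,
        n_folds=config.tz_folds, min_windows=config.tz_min_windows,
        threshold=config.tz_threshold)
    tz_points = tznet.predict_tz(model, norm, config.tz_threshold)

    # --- stage: forks and classification ----------------------------------
    raw_segments = forks_mod.assemble_forks(features, tz_points,
                                            bin_size=config.bin_size)
    # self-consensus drops positions where TTR- and IZ-derived segments
    # disagree in direction, keeping a single-direction map
    fork_segments = forks_mod.consensus_forks(raw_segments, raw_segments)
    classifications = [forks_mod.classify_rdc(r, fork_segments, features)
                       for r in rdcs]

    # --- stage: TRC statistics --------------------------------------------
    genes = bundle["annotation"]["genes"]
    per_rdc = []
    for r, cls in zip(rdcs, classifications):
        comps = trc_mod.assign_compartments(r, fork_segments, genes,
                                            config.rpkm_min)
        row = {"chrom": r.chrom, "start": r.start, "end": r.end,
               "class": cls.klass, "P_HO": None, "P_CD": None}
        counts = {}
        for cond, lib in bundle["libraries"].items():
            inter = jmod.filter_viewpoint(lib)
            counts[cond] = int(((inter.df["pos"] >= r.start)
                                & (inter.df["pos"] < r.end)).sum())
            if cond == "0.6uM" and comps:
                props = trc_mod.proportions(inter, comps)
                if props:
                    row["P_HO"], row["P_CD"] = props
        rel = trc_mod.relative_dsb_count(counts)
        row["relative_dsb"] = rel
        per_rdc.append(row)

    strata = trc_mod.hybrid_stratify(rdcs, bundle["annotation"]["dripc_plus"],
                                     bundle["annotation"]["dripc_minus"])

    # --- planted vs called agreement ---------------------------------------
    agreement = []
    for planted in truth["rdcs"]:
        hit = next((r for r in rdcs
                    if min(r.end, planted["end"]) - max(r.start, planted["start"]) > 0),
                   None)
        agreement.append({
            "planted": [planted["start"], planted["end"], planted["class"]],
            "called": [hit.start, hit.end] if hit else None,
        })

    report = _to_py({
        "seed": config.seed,
        "n_rdcs": len(rdcs),
        "rdcs": per_rdc,
        "hybrid_groups": {str(k): v for k, v in strata.items()},
        "cv_recall": cv.recall,
        "cv_precision": cv.precision,
        "n_fork_segments": len(fork_segments),
        "feature_fractions": rmod.genome_feature_fractions(features),
        "planted_vs_called": agreement,
    })
    (workdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    return report
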