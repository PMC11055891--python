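"""Train the termination-zone predictor and locate fork meeting points.

Reference labels come from OK-seq replication fork directionality (RFD):
LOESS-smoothed RFD crosses zero upward at initiation zones and downward at
termination zones.  30-bin Repli-seq windows around labeled regions (at both
50-kb and 100-kb scales) train a small fully-convolutional network that
scores each bin for being a termination meeting point.
"""

import numpy as np

import rdcscan as rs
from rdcscan.forks import ForkSegment
from rdcscan.simulate import SimConfig, simulate_okseq, simulate_replication

cfg = SimConfig(seed=3, chrom_length=100_000_000)
matrix, truth = simulate_replication(cfg)
forks = [ForkSegment(cfg.chrom, f["start"], f["end"], f["direction"])
         for f in truth["forks"]]
F, R = simulate_okseq(cfg, forks)

rfd = rs.compute_rfd(F, R)
iz_bins, tz_bins = rs.reference_iz_tz(rfd)
print(f"reference labels: {len(iz_bins)} IZs, {len(tz_bins)} TZs "
      f"({len(truth['iz_bins'])} planted origins)")

norm = rs.normalize_and_smooth(matrix, 1.0)
windows = rs.make_training_windows(norm, iz_bins, tz_bins)
print(f"{len(windows)} training windows (50-kb + 100-kb scales pooled)")

model, cv = rs.train_tz_model(windows, seed=3, epochs=30, n_folds=5,
                              min_windows=50)
print(f"cross-validation at 1-bin tolerance: "
      f"recall {cv.recall:.2f}, precision {cv.precision:.2f}")

points = rs.predict_tz(model, norm, threshold=0.5)
true_tz = np.array(truth["tz_bins"])
hits = sum(1 for p in points if np.abs(true_tz - p).min() <= 1)
print(f"{len(points)} predicted meeting points, {hits} within 1 bin of a "
      f"planted termination ({len(true_tz)} planted)")
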