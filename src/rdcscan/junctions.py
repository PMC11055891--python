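"""Reading, filtering and binning of LAM-HTGTS translocation junctions.

LAM-HTGTS recovers prey double-strand-break (DSB) ends joined to an induced
bait DSB.  Linear amplification preserves which side of the prey break was
captured, so every junction carries an orientation: centromere-connected
(``Dcen``, the break end pointing toward the centromere, recovered from
rightward-moving forks) or telomere-connected (``Dtel``, from leftward-moving
forks).  This module ingests junction tables, applies the viewpoint-chromosome
filter, computes off-target library-size weights across drug conditions, and
bins junctions into density tracks.

Coordinates are 0-based half-open internally.  BED input is taken as-is;
TLX-style 1-based positions are shifted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default off-target normalization regions (mm10), one per bait chromosome.
DEFAULT_OFFTARGETS = pd.DataFrame(
    [
        ("chr2", 165364620, 165369885),
        ("chr4", 141559295, 141560757),
        ("chr14", 22764896, 22769859),
        ("chr12", 111040435, 111040503),
    ],
    columns=["chrom", "start", "end"],
)


class Orientation(str, Enum):
    """Prey DSB end orientation."""

    DCEN = "Dcen"
    DTEL = "Dtel"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Strand-to-orientation convention: "+" prey junctions are centromere-connected.
#: The mapping is a file-format convention, not biology, and may be overridden.
STRAND_TO_ORIENTATION = {"+": Orientation.DCEN, "-": Orientation.DTEL}


@dataclass(frozen=True)
class Junction:
    chrom: str
    pos: int
    orientation: Orientation
    bait_chrom: str | None = None
    library_id: str | None = None
    condition: str | None = None

    @property
    def interchromosomal(self) -> bool:
        return self.bait_chrom is not None and self.chrom != self.bait_chrom


class JunctionSet:
    """A collection of junctions stored columnar in a DataFrame.

    Columns: chrom, pos, orientation, bait_chrom, library_id, condition.
    """

    COLUMNS = ["chrom", "pos", "orientation", "bait_chrom", "library_id", "condition"]

    def __init__(self, df: pd.DataFrame | None = None, n_rejected: int = 0):
        if df is None:
            df = pd.DataFrame(columns=self.COLUMNS)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"junction frame missing columns: {sorted(missing)}")
        self.df = df.reset_index(drop=True)
        self.n_rejected = n_rejected

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield Junction(
                row.chrom, int(row.pos), Orientation(row.orientation),
                row.bait_chrom, row.library_id, row.condition,
            )

    @classmethod
    def from_junctions(cls, junctions: Iterable[Junction]) -> "JunctionSet":
        rows = [
            (j.chrom, j.pos, j.orientation.value, j.bait_chrom, j.library_id, j.condition)
            for j in junctions
        ]
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))

    def subset(self, *, chrom: str | None = None,
               orientation: Orientation | str | None = None,
               condition: str | None = None) -> "JunctionSet":
        mask = pd.Series(True, index=self.df.index)
        if chrom is not None:
            mask &= self.df["chrom"] == chrom
        if orientation is not None:
            mask &= self.df["orientation"] == str(Orientation(orientation).value)
        if condition is not None:
            mask &= self.df["condition"] == condition
        return JunctionSet(self.df[mask])

    def positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy(dtype=np.int64)


@dataclass
class Library:
    """One LAM-HTGTS library: bait location, drug condition and junctions."""

    library_id: str
    bait_chrom: str
    condition: str
    junctions: JunctionSet
    offtarget_count: int = 0

    @property
    def interchromosomal_total(self) -> int:
        return int((self.junctions.df["chrom"] != self.bait_chrom).sum())


def read_junctions(
    path: str | Path,
    dialect: str = "bed6",
    *,
    bait_chrom: str | None = None,
    library_id: str | None = None,
    condition: str | None = None,
    strand_to_orientation: dict[str, Orientation] | None = None,
) -> JunctionSet:
    """Read a junction table in BED6 or TLX-like TSV dialect.

    BED6: ``chrom start end name score strand``; the junction position is the
    interval start (0-based).  TLX: tab-separated with a header containing at
    least ``Rname``, ``Junction`` (1-based) and ``Strand`` (+/-/1/-1).
    Records lacking an orientation are rejected and counted, with the line
    number logged.
    """
    conv = strand_to_orientation or STRAND_TO_ORIENTATION
    path = Path(path)
    if dialect not in ("bed6", "tlx"):
        raise ValueError(f"unknown junction dialect: {dialect!r}")
    rows: list[tuple] = []
    n_rejected = 0

    def reject(lineno: int, why: str) -> None:
        nonlocal n_rejected
        n_rejected += 1
        logger.warning("%s:%d rejected junction record (%s)", path, lineno, why)

    if dialect == "bed6":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 6 or parts[5] not in conv:
                    reject(lineno, "missing or invalid strand")
                    continue
                rows.append((parts[0], int(parts[1]), conv[parts[5]].value))
    else:  # tlx
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"Rname", "Junction", "Strand"}
        if not required.issubset(df.columns):
            raise ValueError(f"TLX file lacks columns {sorted(required - set(df.columns))}")
        strand_alias = {"1": "+", "-1": "-", "+": "+", "-": "-"}
        for lineno, row in enumerate(df.itertuples(index=False), 2):
            strand = strand_alias.get(str(row.Strand))
            if strand is None or strand not in conv:
                reject(lineno, "missing or invalid strand")
                continue
            try:
                pos = int(row.Junction) - 1  # TLX is 1-based
            except (TypeError, ValueError):
                reject(lineno, "non-integer junction position")
                continue
            rows.append((str(row.Rname), pos, conv[strand].value))

    df = pd.DataFrame(rows, columns=["chrom", "pos", "orientation"])
    df["bait_chrom"] = bait_chrom
    df["library_id"] = library_id
    df["condition"] = condition
    return JunctionSet(df, n_rejected=n_rejected)


def write_junctions_bed6(junctions: JunctionSet, path: str | Path) -> None:
    """Dump a JunctionSet as BED6 (1-bp intervals, strand from orientation)."""
    inv = {v.value: k for k, v in STRAND_TO_ORIENTATION.items()}
    df = junctions.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"] + 1,
            "name": [f"j{i}" for i in range(len(df))],
            "score": 0,
            "strand": df["orientation"].map(inv),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def filter_viewpoint(library: Library) -> JunctionSet:
    """Drop junctions on the bait (viewpoint) chromosome.

    Dcen/Dtel recovery is unbalanced on the viewpoint chromosome (the bait
    preferentially recovers downstream prey ends), so all statistics use
    interchromosomal junctions only.
    """
    df = library.junctions.df
    return JunctionSet(df[df["chrom"] != library.bait_chrom])


def count_in_intervals(junctions: JunctionSet, intervals: pd.DataFrame) -> int:
    """Count junctions falling in any of the given half-open intervals."""
    n = 0
    df = junctions.df
    for iv in intervals.itertuples(index=False):
        on = df["chrom"] == iv.chrom
        n += int(((df["pos"] >= iv.start) & (df["pos"] < iv.end) & on).sum())
    return n


def offtarget_weights(
    libraries: Sequence[Library],
    offtargets: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Per-condition library-size weights from off-target junction counts.

    Off-target sites are CRISPR by-product cut sites whose DSB frequency does
    not respond to aphidicolin, so their junction counts act as a library-size
    anchor.  weight(c) = mean off-target count across conditions / off-target
    count of condition c; applying it equalizes off-target counts.
    """
    if offtargets is None:
        offtargets = DEFAULT_OFFTARGETS
    counts: dict[str, int] = {}
    for lib in libraries:
        n = lib.offtarget_count or count_in_intervals(lib.junctions, offtargets)
        if n == 0:
            raise ValueError(
                f"library {lib.library_id!r} has zero off-target junctions; "
                "off-target normalization impossible"
            )
        counts[lib.condition] = counts.get(lib.condition, 0) + n
    mean = float(np.mean(list(counts.values())))
    return {cond: mean / n for cond, n in counts.items()}


def density_track(
    junctions: JunctionSet,
    chrom: str,
    chrom_length: int,
    bin_size: int,
    *,
    orientation: Orientation | str | None = None,
    per: str = "count",
    interchromosomal_total: int | None = None,
) -> np.ndarray:
    """Binned junction density for one chromosome.

    ``per="count"`` returns raw counts; ``per="per-10k-interchromosomal"``
    scales by 1e4 / interchromosomal_total, the paper-style display unit.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    sub = junctions.subset(chrom=chrom, orientation=orientation)
    n_bins = int(np.ceil(chrom_length / bin_size))
    counts = np.bincount(sub.df["pos"].to_numpy() // bin_size, minlength=n_bins).astype(float)
    if per == "count":
        return counts
    if per == "per-10k-interchromosomal":
        if not interchromosomal_total:
            raise ValueError("per-10k scaling requires a positive interchromosomal_total")
        return counts * 1e4 / interchromosomal_total
    raise ValueError(f"unknown density basis: {per!r}")


def write_bedgraph(values: np.ndarray, chrom: str, bin_size: int, path: str | Path,
                   chrom_length: int | None = None) -> None:
    starts = np.arange(len(values)) * bin_size
    ends = starts + bin_size
    if chrom_length is not None:
        ends = np.minimum(ends, chrom_length)
    pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": values}).to_csv(
        path, sep="\t", header=False, index=False
    )
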