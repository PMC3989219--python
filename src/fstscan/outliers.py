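"""Empirical-tail thresholds over window means and extreme-window flagging.

Thresholds are computed separately per chromosome partition.  The sex
chromosome Z carries systematically higher differentiation than the
autosomes (smaller effective population size), so by default it forms its
own partition ("sexchrom") while the autosomes and the two linkage groups
pool into "autosome".

The tail rule is a rank rule, not an interpolated quantile: with n
non-NaN windows and tail fraction alpha, k = ceil(alpha * n); the upper
threshold is the k-th largest window mean and the lower threshold the
k-th smallest.  Comparison is inclusive (>= / <=) so the threshold value
itself is extreme; ties can flag more than k windows and are logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger("fstscan")

AUTOSOME_PARTITION = "autosome"
SEXCHROM_PARTITION = "sexchrom"


@dataclass(frozen=True)
class ThresholdSpec:
    """Tail fraction and chromosome partitioning for empirical thresholds."""

    tail_fraction: float = 0.01
    partitions: dict = field(default_factory=lambda: {"Z": SEXCHROM_PARTITION})

    def __post_init__(self) -> None:
        if not 0.0 < self.tail_fraction < 0.5:
            raise ConfigurationError(
                f"tail_fraction must be in (0, 0.5), got {self.tail_fraction}"
            )

    def partition_of(self, chrom: str) -> str:
        return self.partitions.get(str(chrom), AUTOSOME_PARTITION)


@dataclass(frozen=True)
class PartitionThresholds:
    """Order-statistic thresholds for one chromosome partition."""

    partition: str
    n_windows: int
    k: int
    lower: float
    upper: float


@dataclass
class OutlierSet:
    """Per-partition thresholds plus the flagged extreme windows.

    ``flagged`` carries the window-track columns plus ``window_idx``
    (row index into the input track), ``direction`` ("upper"/"lower"),
    ``partition`` and ``threshold``.  A window tied at both thresholds in
    a degenerate distribution appears once per direction.
    """

    thresholds: dict[str, PartitionThresholds]
    flagged: pd.DataFrame


_FLAG_COLUMNS = [
    "window_idx",
    "chrom",
    "start_idx",
    "stop_idx",
    "bp_start",
    "bp_end",
    "n_snps",
    "mean_fst",
    "direction",
    "partition",
    "threshold",
]


def tail_thresholds(
    track: pd.DataFrame, spec: ThresholdSpec | None = None
) -> OutlierSet:
    """Flag windows in the empirical upper and lower tails per partition.

    Windows with NaN mean are excluded from both the count n and the
    flagging.  Partitions with fewer than ceil(1/alpha) usable windows are
    skipped with a warning (no thresholds can put ~alpha mass in a tail).
    """
    spec = spec or ThresholdSpec()
    alpha = spec.tail_fraction
    part = np.array(
        [spec.partition_of(c) for c in track["chrom"]], dtype=object
    )
    means = track["mean_fst"].to_numpy(dtype=float)
    usable = ~np.isnan(means)

    thresholds: dict[str, PartitionThresholds] = {}
    flag_frames: list[pd.DataFrame] = []
    min_windows = math.ceil(1.0 / alpha)
    for p in dict.fromkeys(part):
        in_p = usable & (part == p)
        n = int(in_p.sum())
        if n < min_windows:
            logger.warning(
                "partition %s has %d usable window(s) (< %d); skipped",
                p,
                n,
                min_windows,
            )
            continue
        vals = means[in_p]
        k = math.ceil(alpha * n)
        srt = np.sort(vals)
        lower = float(srt[k - 1])
        upper = float(srt[n - k])
        thresholds[p] = PartitionThresholds(p, n, k, lower, upper)
        if lower == upper:
            logger.warning(
                "partition %s: degenerate F_ST distribution (lower == upper "
                "threshold); all windows flagged in both tails",
                p,
            )
        for direction, sel, thr in (
            ("upper", in_p & (means >= upper), upper),
            ("lower", in_p & (means <= lower), lower),
        ):
            idx = np.flatnonzero(sel)
            if len(idx) > k:
                logger.info(
                    "partition %s %s tail: ties flag %d windows (k = %d)",
                    p,
                    direction,
                    len(idx),
                    k,
                )
            sub = track.iloc[idx].copy()
            sub.insert(0, "window_idx", idx)
            sub["direction"] = direction
            sub["partition"] = p
            sub["threshold"] = thr
            flag_frames.append(sub)

    if flag_frames:
        flagged = pd.concat(flag_frames, ignore_index=True)[_FLAG_COLUMNS]
    else:
        flagged = pd.DataFrame(columns=_FLAG_COLUMNS)
    return OutlierSet(thresholds, flagged)


def write_outlier_tsv(o: OutlierSet, path) -> None:
    """Outlier TSV: chrom, bp_start, bp_end, mean_fst, direction, partition, threshold."""
    o.flagged[
        ["chrom", "bp_start", "bp_end", "mean_fst", "direction", "partition", "threshold"]
    ].to_csv(path, sep="\t", index=False, float_format="%.6g")
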