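"""Joining extreme windows into candidate sweep regions; interval export.

Outlier windows of the same tail on the same chromosome that lie within
``max_gap`` base pairs of each other (default 500 kb, gap measured
edge-to-edge and inclusive at exactly the gap) are merged into a single
candidate region.  Upper- and lower-tail windows are never merged with
each other: elevated and depressed differentiation are distinct signals.

BED export is the annotation hand-off point; gene and pathway annotation
is outside this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import chrom_sort_rank
from .outliers import OutlierSet

DEFAULT_MAX_GAP = 500_000


@dataclass
class SweepRegion:
    """A merged run of same-tail outlier windows on one chromosome."""

    chrom: str
    bp_start: int
    bp_end: int
    direction: str
    n_windows: int
    peak_fst: float
    members: list[int] = field(default_factory=list)


def join_outlier_windows(
    outliers: OutlierSet | pd.DataFrame, max_gap: int = DEFAULT_MAX_GAP
) -> list[SweepRegion]:
    """Merge flagged windows within ``max_gap`` bp into sweep regions.

    Windows are first canonically sorted, so the result is independent of
    input order; re-joining a region's member windows reproduces it.
    """
    flagged = outliers.flagged if isinstance(outliers, OutlierSet) else outliers
    if len(flagged) == 0:
        return []
    df = flagged.copy()
    if "window_idx" not in df.columns:
        df["window_idx"] = np.arange(len(df))
    df = df.iloc[
        np.lexsort(
            (
                df["bp_end"].to_numpy(),
                df["bp_start"].to_numpy(),
                chrom_sort_rank(df["chrom"].to_numpy(dtype=object)),
            )
        )
    ]

    regions: list[SweepRegion] = []
    for (chrom, direction), sub in df.groupby(["chrom", "direction"], sort=False):
        current: SweepRegion | None = None
        for row in sub.itertuples(index=False):
            if current is not None and row.bp_start - current.bp_end <= max_gap:
                current.bp_end = max(current.bp_end, int(row.bp_end))
                current.n_windows += 1
                current.peak_fst = max(current.peak_fst, float(row.mean_fst))
                current.members.append(int(row.window_idx))
            else:
                current = SweepRegion(
                    chrom=str(chrom),
                    bp_start=int(row.bp_start),
                    bp_end=int(row.bp_end),
                    direction=str(direction),
                    n_windows=1,
                    peak_fst=float(row.mean_fst),
                    members=[int(row.window_idx)],
                )
                regions.append(current)
    regions.sort(
        key=lambda r: (
            int(chrom_sort_rank([r.chrom])[0]),
            r.chrom,
            r.bp_start,
            r.direction,
        )
    )
    return regions


def export_bed(regions: list[SweepRegion], path) -> None:
    """Write regions as BED (0-based half-open; score = 1000 * peak F_ST)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            score = int(round(1000.0 * r.peak_fst))
            score = min(max(score, 0), 1000)
            fh.write(
                f"{r.chrom}\t{r.bp_start - 1}\t{r.bp_end}\t"
                f"{r.direction}{i}\t{score}\n"
            )


def regions_to_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "bp_start": [r.bp_start for r in regions],
            "bp_end": [r.bp_end for r in regions],
            "direction": [r.direction for r in regions],
            "n_windows": [r.n_windows for r in regions],
            "peak_fst": [r.peak_fst for r in regions],
        }
    )


def export_region_tsv(regions: list[SweepRegion], path) -> None:
    """Region TSV: chrom, bp_start, bp_end, direction, n_windows, peak_fst."""
    regions_to_frame(regions).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
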