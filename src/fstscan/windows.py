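"""Overlapping SNP-count windows and within-window averaging.

Windows are defined in marker rank, not base pairs: each window holds a
fixed number of consecutive SNPs (default 40) and starts ``step`` SNPs
(default 20) after the previous one, so consecutive windows share
``size - step`` members.  Windows never span chromosome or linkage-group
boundaries.  At a chromosome end the trailing window may hold fewer SNPs;
it is kept when it has at least two members (configurable via
``drop_partial``) so telomeric signal is not discarded.

Base-pair spans (last member position minus first, plus one) are reported
for QC only; detection operates purely on SNP rank.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StructuralError

logger = logging.getLogger("fstscan")

#: columns of a window track frame
TRACK_COLUMNS = (
    "chrom",
    "start_idx",
    "stop_idx",
    "bp_start",
    "bp_end",
    "n_snps",
    "mean_fst",
)


@dataclass(frozen=True)
class WindowSpec:
    """Overlapping-window geometry: SNPs per window and start-to-start step."""

    size: int = 40
    step: int = 20
    drop_partial: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.step <= self.size):
            raise ConfigurationError(
                f"require 1 <= step <= size, got step={self.step}, size={self.size}"
            )


def build_windows(variants: pd.DataFrame, spec: WindowSpec | None = None) -> pd.DataFrame:
    """Window geometry over a (chrom, pos)-sorted variant table.

    Returns a DataFrame with one row per window (``TRACK_COLUMNS``);
    ``start_idx``/``stop_idx`` are half-open global SNP indices into the
    variant table and ``mean_fst`` is NaN until filled by
    :func:`window_mean`.  Chromosomes with fewer than two SNPs yield no
    windows (warning logged).
    """
    spec = spec or WindowSpec()
    chroms = variants["chrom"].to_numpy(dtype=object)
    pos = variants["pos"].to_numpy()
    rows: list[tuple] = []
    start = 0
    n = len(variants)
    while start < n:
        chrom = chroms[start]
        stop = start
        while stop < n and chroms[stop] == chrom:
            stop += 1
        m = stop - start
        if m < 2:
            logger.warning(
                "chromosome %s has %d SNP(s); no windows emitted", chrom, m
            )
        else:
            for s in range(0, m, spec.step):
                e = min(s + spec.size, m)
                nw = e - s
                if nw < spec.size and (spec.drop_partial or nw < 2):
                    continue
                lo, hi = start + s, start + e
                rows.append(
                    (
                        chrom,
                        lo,
                        hi,
                        int(pos[lo]),
                        int(pos[hi - 1]),
                        nw,
                        np.nan,
                    )
                )
        start = stop
    track = pd.DataFrame(rows, columns=list(TRACK_COLUMNS))
    if len(track) == 0:
        track = pd.DataFrame(
            {
                "chrom": pd.Series(dtype=object),
                "start_idx": pd.Series(dtype=np.int64),
                "stop_idx": pd.Series(dtype=np.int64),
                "bp_start": pd.Series(dtype=np.int64),
                "bp_end": pd.Series(dtype=np.int64),
                "n_snps": pd.Series(dtype=np.int64),
                "mean_fst": pd.Series(dtype=float),
            }
        )
    track.attrs["n_variants"] = n
    track.attrs["size"] = spec.size
    track.attrs["step"] = spec.step
    return track


def window_mean(per_snp_fst: np.ndarray, track: pd.DataFrame) -> pd.DataFrame:
    """Fill ``mean_fst`` with the mean of non-NaN member SNP values.

    A window whose members are all NaN gets mean NaN (excluded downstream).
    """
    per_snp_fst = np.asarray(per_snp_fst, dtype=float)
    n_expected = track.attrs.get("n_variants")
    if n_expected is not None and len(per_snp_fst) != n_expected:
        raise StructuralError(
            f"per-SNP vector has {len(per_snp_fst)} entries; track was built "
            f"over {n_expected} variants"
        )
    if len(track) and int(track["stop_idx"].max()) > len(per_snp_fst):
        raise StructuralError("per-SNP vector shorter than window span")

    finite = ~np.isnan(per_snp_fst)
    csum = np.concatenate([[0.0], np.cumsum(np.where(finite, per_snp_fst, 0.0))])
    ccnt = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])
    lo = track["start_idx"].to_numpy(dtype=np.int64)
    hi = track["stop_idx"].to_numpy(dtype=np.int64)
    cnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(cnt > 0, (csum[hi] - csum[lo]) / np.maximum(cnt, 1), np.nan)
    out = track.copy()
    out["mean_fst"] = means
    out.attrs.update(track.attrs)
    return out


def bp_span_stats(track: pd.DataFrame) -> dict:
    """QC summary of window base-pair spans (mean, min, max)."""
    if len(track) == 0:
        return {"mean_bp": float("nan"), "min_bp": 0, "max_bp": 0, "n_windows": 0}
    span = track["bp_end"].to_numpy() - track["bp_start"].to_numpy() + 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return {
            "mean_bp": float(span.mean()),
            "min_bp": int(span.min()),
            "max_bp": int(span.max()),
            "n_windows": int(len(track)),
        }


def write_window_tsv(track: pd.DataFrame, path) -> None:
    """Window track TSV: chrom, bp_start, bp_end, n_snps, mean_fst."""
    track[["chrom", "bp_start", "bp_end", "n_snps", "mean_fst"]].to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
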