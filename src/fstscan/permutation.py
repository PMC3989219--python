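"""Randomisation reference distribution for window-averaged F_ST.

Each replicate reassigns individuals uniformly at random (without
replacement) to two groups of fixed sizes, recomputes per-SNP F_ST
between the random groups, averages it over the same window geometry as
the observed scan, and records the genome-wide maximum and minimum window
mean.  The envelope of these extremes describes what window-level
differentiation label shuffling alone can produce.

The permuted extremes are diagnostics, not detection thresholds:
empirical-tail flagging lives in :mod:`fstscan.outliers`.

Replicate r draws its random state from a child seed derived
deterministically from (root seed, r), so any replicate is reproducible
independently of execution order or the total replicate count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .fst import (
    FstEstimatorConfig,
    _stats_from_calls,
    pair_fst_weir_cockerham,
    pair_fst_wright_nei,
)
from .genotype_io import GenotypeMatrix
from .windows import WindowSpec, build_windows, window_mean

logger = logging.getLogger("fstscan")


@dataclass(frozen=True)
class PermutationResult:
    """Per-replicate genome-wide extremes of permuted window means."""

    n_reps: int
    seed: int
    max_fst: np.ndarray
    min_fst: np.ndarray

    def __post_init__(self) -> None:
        if len(self.max_fst) != self.n_reps or len(self.min_fst) != self.n_reps:
            raise ConfigurationError("extreme lists must have n_reps entries")

    def envelope(self) -> tuple[float, float]:
        """(min over replicates of the minima, max over replicates of the maxima)."""
        if self.n_reps == 0:
            return (float("nan"), float("nan"))
        return (float(np.nanmin(self.min_fst)), float(np.nanmax(self.max_fst)))


def _two_group_fst(
    calls: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    cfg: FstEstimatorConfig,
) -> np.ndarray:
    pa, na, ha = _stats_from_calls(calls[idx_a])
    pb, nb, hb = _stats_from_calls(calls[idx_b])
    if cfg.estimator == "wright_nei":
        return pair_fst_wright_nei(pa, pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop_a = np.where(na > 0, ha / np.maximum(na, 1), np.nan)
        prop_b = np.where(nb > 0, hb / np.maximum(nb, 1), np.nan)
    return pair_fst_weir_cockerham(pa, pb, na, nb, prop_a, prop_b)


def permutation_null(
    g: GenotypeMatrix,
    group_sizes: tuple[int, int],
    wspec: WindowSpec | None = None,
    cfg: FstEstimatorConfig | None = None,
    n_reps: int = 100,
    seed: int = 0,
    track: pd.DataFrame | None = None,
) -> PermutationResult:
    """Permute samples into two groups and record window-mean extremes.

    ``track`` may supply a pre-built window geometry (it must match the
    variant table of ``g``); otherwise windows are rebuilt from ``wspec``.
    """
    n_a, n_b = group_sizes
    if n_a < 1 or n_b < 1:
        raise ConfigurationError("both permutation group sizes must be >= 1")
    if n_a + n_b > g.n_samples:
        raise ConfigurationError(
            f"group sizes {n_a}+{n_b} exceed {g.n_samples} samples"
        )
    if n_reps < 0:
        raise ConfigurationError("n_reps must be >= 0")
    cfg = cfg or FstEstimatorConfig()
    if track is None:
        track = build_windows(g.variants, wspec or WindowSpec())

    maxima = np.empty(n_reps)
    minima = np.empty(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        perm = rng.permutation(g.n_samples)
        idx_a = perm[:n_a]
        idx_b = perm[n_a : n_a + n_b]
        fst = _two_group_fst(g.calls, idx_a, idx_b, cfg)
        means = window_mean(fst, track)["mean_fst"].to_numpy()
        finite = means[~np.isnan(means)]
        if len(finite):
            maxima[r] = finite.max()
            minima[r] = finite.min()
        else:
            maxima[r] = np.nan
            minima[r] = np.nan
    return PermutationResult(n_reps, int(seed), maxima, minima)


def write_permutation_tsv(res: PermutationResult, path) -> None:
    """Permutation summary TSV: rep, min_fst, max_fst."""
    pd.DataFrame(
        {
            "rep": np.arange(res.n_reps),
            "min_fst": res.min_fst,
            "max_fst": res.max_fst,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
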