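"""Per-SNP allele frequencies, pairwise F_ST, and multi-pair averaging.

The default estimator is the classic Wright/Nei frequency form,

    F_ST = (H_T - H_S) / H_T,

with H_T = 2 p̄ q̄ the expected heterozygosity of the pooled (equal-weight)
frequencies and H_S = p1 q1 + p2 q2 the mean within-group heterozygosity.
Algebraically this equals (p1 - p2)^2 / (4 p̄ q̄), is symmetric, and is
bounded in [0, 1] with 0 at equal frequencies and 1 at a fixed difference.
SNPs monomorphic for the same allele in both groups (H_T = 0) have no
defined differentiation and propagate NaN.

A Weir–Cockerham two-population theta with sample-size and
observed-heterozygosity corrections is available as an option; unlike the
Wright/Nei form it can be negative, and negative values are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, StructuralError
from .genotype_io import MISSING, GenotypeMatrix, SampleGroups

logger = logging.getLogger("fstscan")

ESTIMATORS = ("wright_nei", "weir_cockerham")


@dataclass(frozen=True)
class FstEstimatorConfig:
    """Choice of per-SNP F_ST estimator; undefined SNPs always propagate NaN."""

    estimator: str = "wright_nei"

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATORS:
            raise ConfigurationError(
                f"estimator must be one of {ESTIMATORS}, got {self.estimator!r}"
            )


@dataclass(frozen=True)
class ComparisonSpec:
    """A named set of group pairs whose per-SNP F_ST values are averaged."""

    name: str
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        pairs = tuple((str(a), str(b)) for a, b in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        if not pairs:
            raise ConfigurationError(f"comparison {self.name!r} has no pairs")
        if len(set(pairs)) != len(pairs):
            raise ConfigurationError(f"comparison {self.name!r} repeats a pair")

    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b in self.pairs:
            seen.setdefault(a, None)
            seen.setdefault(b, None)
        return list(seen)


@dataclass
class GroupFrequencies:
    """Per-group per-SNP alternate-allele frequencies with call bookkeeping.

    ``freq`` is NaN where a group has no called genotypes at a SNP.
    Heterozygote counts are carried so that the Weir–Cockerham option can
    be computed without revisiting the genotype matrix.
    """

    groups: list[str]
    freq: np.ndarray        # (n_groups, n_snps), NaN where no calls
    n_samples: np.ndarray   # (n_groups, n_snps) called diploid individuals
    n_het: np.ndarray       # (n_groups, n_snps) called heterozygotes

    def index_of(self, group: str) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise StructuralError(f"group {group!r} absent from frequencies")


def _stats_from_calls(calls: np.ndarray):
    """Alt-allele frequency, called-sample count and het count per SNP."""
    called = calls != MISSING
    n = called.sum(axis=0).astype(np.float64)
    alt = np.where(called, calls, 0).sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(2.0 * n, 1.0), np.nan)
    het = (calls == 1).sum(axis=0).astype(np.float64)
    return p, n, het


def group_allele_frequencies(
    g: GenotypeMatrix, s: SampleGroups
) -> GroupFrequencies:
    """Compute per-group alternate-allele frequencies over non-missing calls."""
    s.validate_against(g)
    groups = s.groups()
    freq = np.empty((len(groups), g.n_snps))
    n_samp = np.empty((len(groups), g.n_snps))
    n_het = np.empty((len(groups), g.n_snps))
    for k, grp in enumerate(groups):
        idx = s.indices(g.samples, grp)
        if len(idx) == 0:
            raise StructuralError(f"group {grp!r} has no samples in the matrix")
        freq[k], n_samp[k], n_het[k] = _stats_from_calls(g.calls[idx])
    return GroupFrequencies(groups, freq, n_samp, n_het)


def _check_freq_domain(*ps) -> None:
    for p in ps:
        arr = np.asarray(p, dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            raise DomainError("allele frequencies must lie in [0, 1]")


def pair_fst_wright_nei(p1, p2):
    """Vectorised Wright/Nei F_ST = (p1-p2)^2 / (4 p̄ q̄); NaN where H_T = 0."""
    _check_freq_domain(p1, p2)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    pbar = 0.5 * (p1 + p2)
    ht = 4.0 * pbar * (1.0 - pbar)  # = 2 * H_T
    num = (p1 - p2) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(ht > 0, num / np.where(ht > 0, ht, 1.0), np.nan)
    out = np.where(np.isnan(p1) | np.isnan(p2), np.nan, out)
    return out


def pair_fst_weir_cockerham(p1, p2, n1, n2, h1, h2):
    """Two-population Weir–Cockerham theta from group summary statistics.

    ``n`` are called diploid sample counts and ``h`` observed heterozygote
    *proportions* per group.  NaN where undefined (no calls, n̄ <= 1, or
    zero total variance).
    """
    _check_freq_domain(p1, p2)
    p1, p2, n1, n2, h1, h2 = (
        np.asarray(x, dtype=float) for x in (p1, p2, n1, n2, h1, h2)
    )
    r = 2.0
    nsum = n1 + n2
    nbar = nsum / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n1**2 + n2**2) / np.maximum(nsum, 1e-300)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / np.maximum(nsum, 1e-300)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (
            (r - 1.0) * np.maximum(nbar, 1e-300)
        )
        hbar = (n1 * h1 + n2 * h2) / np.maximum(nsum, 1e-300)
        inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0
        a = nbar / np.maximum(nc, 1e-300) * (
            s2 - inner / np.maximum(nbar - 1.0, 1e-300)
        )
        b = nbar / np.maximum(nbar - 1.0, 1e-300) * (
            pbar * (1.0 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    invalid = (
        np.isnan(p1) | np.isnan(p2) | (n1 < 1) | (n2 < 1) | (nbar <= 1.0)
    )
    return np.where(invalid, np.nan, theta)


def snp_fst(p1: float, p2: float, cfg: FstEstimatorConfig | None = None) -> float:
    """Single-SNP F_ST between two groups given their allele frequencies.

    The Weir–Cockerham option needs per-group sample sizes and is only
    available through :func:`comparison_fst`; this scalar convenience
    always uses the Wright/Nei form.
    """
    if cfg is not None and cfg.estimator != "wright_nei":
        raise ConfigurationError(
            "snp_fst from frequencies alone supports only wright_nei; use "
            "comparison_fst for weir_cockerham"
        )
    return float(pair_fst_wright_nei(p1, p2))


def _pair_vector(
    f: GroupFrequencies, a: str, b: str, cfg: FstEstimatorConfig
) -> np.ndarray:
    i, j = f.index_of(a), f.index_of(b)
    if cfg.estimator == "wright_nei":
        return pair_fst_wright_nei(f.freq[i], f.freq[j])
    with np.errstate(invalid="ignore", divide="ignore"):
        h1 = np.where(f.n_samples[i] > 0, f.n_het[i] / np.maximum(f.n_samples[i], 1), np.nan)
        h2 = np.where(f.n_samples[j] > 0, f.n_het[j] / np.maximum(f.n_samples[j], 1), np.nan)
    return pair_fst_weir_cockerham(
        f.freq[i], f.freq[j], f.n_samples[i], f.n_samples[j], h1, h2
    )


def comparison_fst(
    f: GroupFrequencies,
    spec: ComparisonSpec,
    cfg: FstEstimatorConfig | None = None,
) -> np.ndarray:
    """Per-SNP F_ST averaged over the comparison's group pairs.

    Pairs are averaged within each SNP first; NaN pairs are excluded from
    the mean, and a SNP is NaN only when every pair is NaN.
    """
    cfg = cfg or FstEstimatorConfig()
    stack = np.vstack([_pair_vector(f, a, b, cfg) for a, b in spec.pairs])
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(stack, axis=0)


def write_snp_fst_tsv(variants: pd.DataFrame, fst: np.ndarray, path) -> None:
    """Dump per-SNP F_ST as TSV: chrom, pos, snp_id, fst."""
    if len(fst) != len(variants):
        raise StructuralError("fst vector length does not match variant table")
    out = variants[["chrom", "pos", "snp_id"]].copy()
    out["fst"] = fst
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
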