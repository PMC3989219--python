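"""End-to-end selection-signature scan orchestration.

read -> deduplicate -> QC filter -> per-group frequencies -> per-SNP
(multi-pair) F_ST -> overlapping-window means -> empirical tail thresholds
(autosomes and Z separately) -> 500 kb joining into candidate regions,
with an optional permutation reference distribution per comparison.
Every stage's output can be written as TSV/BED with a JSON manifest, and
the whole run is deterministic given config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FstscanError
from .fst import (
    ComparisonSpec,
    FstEstimatorConfig,
    GroupFrequencies,
    comparison_fst,
    group_allele_frequencies,
    write_snp_fst_tsv,
)
from .genotype_io import (
    FilterReport,
    GenotypeMatrix,
    SampleGroups,
    apply_qc_filters,
    deduplicate_variants,
    read_genotypes,
    read_group_map,
)
from .outliers import OutlierSet, ThresholdSpec, tail_thresholds, write_outlier_tsv
from .permutation import PermutationResult, permutation_null, write_permutation_tsv
from .regions import (
    DEFAULT_MAX_GAP,
    SweepRegion,
    export_bed,
    export_region_tsv,
    join_outlier_windows,
)
from .study import COMPARISON_TEMPLATES
from .windows import WindowSpec, bp_span_stats, build_windows, window_mean, write_window_tsv

logger = logging.getLogger("fstscan")


@dataclass
class ScanConfig:
    """Declarative configuration of a full scan."""

    genotypes: str
    group_map: str
    format: str = "ped_map"
    comparisons: list = field(default_factory=lambda: ["commercial_vs_outgroup"])
    window: WindowSpec = field(default_factory=WindowSpec)
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    estimator: str = "wright_nei"
    max_missing_calls: int = 0
    maf_floor: float = 0.05
    max_gap: int = DEFAULT_MAX_GAP
    permutation_reps: int = 0
    outdir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "window" in raw:
            raw["window"] = WindowSpec(**raw["window"])
        if "threshold" in raw:
            raw["threshold"] = ThresholdSpec(**raw["threshold"])
        comps = []
        for c in raw.get("comparisons", []):
            if isinstance(c, str):
                comps.append(c)
            else:
                comps.append(
                    ComparisonSpec(c["name"], tuple(tuple(p) for p in c["pairs"]))
                )
        if comps:
            raw["comparisons"] = comps
        return cls(**raw)


@dataclass
class ComparisonResult:
    """All per-comparison scan outputs."""

    spec: ComparisonSpec
    per_snp_fst: np.ndarray
    track: pd.DataFrame
    outliers: OutlierSet
    regions: list[SweepRegion]
    permutation: PermutationResult | None = None


@dataclass
class ScanResult:
    """Bundle returned by :func:`run_scan` / :func:`scan_genotypes`."""

    genotypes: GenotypeMatrix
    groups: SampleGroups
    filter_report: FilterReport | None
    frequencies: GroupFrequencies
    comparisons: dict[str, ComparisonResult]
    manifest: dict


def resolve_comparisons(comparisons, available_groups) -> list[ComparisonSpec]:
    """Expand template names into ComparisonSpecs and validate group labels."""
    specs: list[ComparisonSpec] = []
    for c in comparisons:
        if isinstance(c, str):
            if c not in COMPARISON_TEMPLATES:
                raise ConfigurationError(
                    f"unknown comparison template {c!r}; "
                    f"templates: {sorted(COMPARISON_TEMPLATES)}"
                )
            spec = COMPARISON_TEMPLATES[c]()
        else:
            spec = c
        missing = [g for g in spec.group_labels() if g not in available_groups]
        if missing:
            raise ConfigurationError(
                f"comparison {spec.name!r} references unknown group(s) {missing}"
            )
        specs.append(spec)
    return specs


def _permutation_sizes(spec: ComparisonSpec, groups: SampleGroups) -> tuple[int, int]:
    """Pooled two-group sizes for the permutation null of a comparison.

    Side A pools the groups appearing first in the pairs, side B the rest;
    multi-pair comparisons are thereby approximated by a single pooled
    two-group label permutation.
    """
    side_a = {a for a, _ in spec.pairs}
    side_b = {b for _, b in spec.pairs} - side_a
    n_a = sum(len(groups.members(g)) for g in side_a)
    n_b = sum(len(groups.members(g)) for g in side_b)
    return n_a, n_b


def _comparison_samples(spec: ComparisonSpec, g: GenotypeMatrix, groups: SampleGroups):
    involved = set(spec.group_labels())
    idx = np.array(
        [i for i, s in enumerate(g.samples) if groups.group_of.get(s) in involved],
        dtype=np.intp,
    )
    return idx


def scan_genotypes(
    g: GenotypeMatrix,
    groups: SampleGroups,
    comparisons,
    window: WindowSpec | None = None,
    threshold: ThresholdSpec | None = None,
    estimator: str = "wright_nei",
    max_gap: int = DEFAULT_MAX_GAP,
    permutation_reps: int = 0,
    seed: int = 0,
    outdir=None,
    filter_report: FilterReport | None = None,
) -> ScanResult:
    """Run the scan stages on an in-memory, already QC'd genotype matrix."""
    window = window or WindowSpec()
    threshold = threshold or ThresholdSpec()
    est_cfg = FstEstimatorConfig(estimator)
    groups.validate_against(g)
    specs = resolve_comparisons(comparisons, set(groups.groups()))

    freqs = group_allele_frequencies(g, groups)
    track0 = build_windows(g.variants, window)

    outdir_path = Path(outdir) if outdir is not None else None
    if outdir_path is not None:
        outdir_path.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "seed": seed,
        "n_samples": g.n_samples,
        "n_snps": g.n_snps,
        "estimator": estimator,
        "window": {"size": window.size, "step": window.step},
        "tail_fraction": threshold.tail_fraction,
        "max_gap": max_gap,
        "window_bp_span": bp_span_stats(track0),
        "comparisons": {},
        "complete": False,
    }
    if filter_report is not None:
        manifest["filter_report"] = {
            "n_input": filter_report.n_input,
            "n_removed_missing": filter_report.n_removed_missing,
            "n_removed_maf": filter_report.n_removed_maf,
            "n_remaining": filter_report.n_remaining,
        }

    results: dict[str, ComparisonResult] = {}
    for spec in specs:
        stage = f"comparison {spec.name}"
        try:
            fst_vec = comparison_fst(freqs, spec, est_cfg)
            track = window_mean(fst_vec, track0)
            outliers = tail_thresholds(track, threshold)
            swept = join_outlier_windows(outliers, max_gap)
            perm = None
            if permutation_reps > 0:
                sizes = _permutation_sizes(spec, groups)
                idx = _comparison_samples(spec, g, groups)
                sub = GenotypeMatrix(
                    g.calls[idx], g.variants, [g.samples[i] for i in idx]
                )
                perm = permutation_null(
                    sub,
                    sizes,
                    wspec=window,
                    cfg=FstEstimatorConfig("wright_nei"),
                    n_reps=permutation_reps,
                    seed=seed,
                    track=track0,
                )
        except FstscanError as exc:
            raise FstscanError(f"stage {stage!r} failed: {exc}") from exc

        results[spec.name] = ComparisonResult(
            spec, fst_vec, track, outliers, swept, perm
        )
        flagged = outliers.flagged
        comp_entry = {
            "pairs": list(map(list, spec.pairs)),
            "n_windows": int(len(track)),
            "mean_fst": float(np.nanmean(fst_vec)) if len(fst_vec) else float("nan"),
            "flagged_upper": int((flagged["direction"] == "upper").sum()),
            "flagged_lower": int((flagged["direction"] == "lower").sum()),
            "regions_upper": sum(r.direction == "upper" for r in swept),
            "regions_lower": sum(r.direction == "lower" for r in swept),
            "thresholds": {
                p: {"lower": t.lower, "upper": t.upper, "n": t.n_windows, "k": t.k}
                for p, t in outliers.thresholds.items()
            },
        }
        if perm is not None:
            lo, hi = perm.envelope()
            comp_entry["permutation"] = {
                "n_reps": perm.n_reps,
                "envelope_min": lo,
                "envelope_max": hi,
            }
        manifest["comparisons"][spec.name] = comp_entry

        if outdir_path is not None:
            base = outdir_path / spec.name.replace("/", "_")
            write_snp_fst_tsv(g.variants, fst_vec, f"{base}.snp_fst.tsv")
            write_window_tsv(track, f"{base}.windows.tsv")
            write_outlier_tsv(outliers, f"{base}.outliers.tsv")
            export_region_tsv(swept, f"{base}.regions.tsv")
            export_bed(swept, f"{base}.regions.bed")
            if perm is not None:
                write_permutation_tsv(perm, f"{base}.permutation.tsv")

    manifest["complete"] = True
    if outdir_path is not None:
        with open(outdir_path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return ScanResult(g, groups, filter_report, freqs, results, manifest)


def run_scan(cfg: ScanConfig) -> ScanResult:
    """Run the full scan from files per a :class:`ScanConfig`."""
    g = read_genotypes(cfg.genotypes, cfg.format)
    groups = read_group_map(cfg.group_map)
    g = deduplicate_variants(g)
    g, report = apply_qc_filters(
        g, max_missing_calls=cfg.max_missing_calls, maf_floor=cfg.maf_floor
    )
    return scan_genotypes(
        g,
        groups,
        cfg.comparisons,
        window=cfg.window,
        threshold=cfg.threshold,
        estimator=cfg.estimator,
        max_gap=cfg.max_gap,
        permutation_reps=cfg.permutation_reps,
        seed=cfg.seed,
        outdir=cfg.outdir,
        filter_report=report,
    )


def plot_fst_track(track: pd.DataFrame, outliers: OutlierSet, path) -> None:
    """Simple genome-wide window F_ST track with tail thresholds."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    chroms = list(dict.fromkeys(track["chrom"]))
    offset = 0
    ticks, labels = [], []
    for i, chrom in enumerate(chroms):
        sub = track[track["chrom"] == chrom]
        x = offset + np.arange(len(sub))
        ax.scatter(x, sub["mean_fst"], s=3, color=f"C{i % 2}", rasterized=True)
        ticks.append(offset + len(sub) / 2)
        labels.append(str(chrom))
        offset += len(sub)
    for t in outliers.thresholds.values():
        ax.axhline(t.upper, color="red", lw=0.8)
        ax.axhline(t.lower, color="blue", lw=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_ylabel("window mean $F_{ST}$")
    ax.set_xlabel("chromosome")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
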