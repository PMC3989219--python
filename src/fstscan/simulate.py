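"""Synthetic multi-population SNP panels with known truth.

The generator follows the Balding–Nichols drift model: each SNP has an
ancestral alternate-allele frequency p0 drawn from a configurable site
frequency spectrum (uniform, or U-shaped via a Beta), and each population
draws its own frequency from

    Beta( p0 (1 - F) / F,  (1 - p0)(1 - F) / F ),

whose mean is p0 and whose dispersion parameter F is interpretable as the
expected F_ST between the population and the ancestor.  F = 0 means the
population frequency equals p0 exactly.  Genotypes are Binomial(2, p_pop)
per diploid individual (Hardy–Weinberg within populations, no linkage
disequilibrium).  A two-level hierarchy (lines nested within breeds) is
available: the breed frequency drifts from the ancestor with the breed's
F, and each line drifts from its breed frequency with its own F.

Ancestral frequencies are truncated to [0.05, 0.95] so a 5% MAF filter
does not annihilate the panel.  Sweep loci override the drawn population
frequencies over a block of consecutive SNPs with configured targets, and
every drawn quantity is recorded in a truth table.

Marker maps emulate arrays equilibrated in genetic distance: base-pair
gaps are log-normal, so spacing is even in rank but highly variable in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .genotype_io import (
    GenotypeMatrix,
    SampleGroups,
    chrom_sort_rank,
    make_variant_table,
    write_group_map,
    write_ped_map,
    write_vcf,
)

DEFAULT_FREQ_BOUNDS = (0.05, 0.95)

#: reduced default genome: three large autosomes plus Z, chicken-scale lengths
DEFAULT_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("1", 196_000_000),
    ("2", 150_000_000),
    ("3", 111_000_000),
    ("Z", 82_000_000),
)


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population (line): size, drift F, optional breed."""

    name: str
    n_diploids: int
    fst: float
    breed: str | None = None

    def __post_init__(self) -> None:
        if self.n_diploids < 1:
            raise ConfigurationError(f"population {self.name}: size must be >= 1")
        if not 0.0 <= self.fst < 1.0:
            raise ConfigurationError(f"population {self.name}: F must be in [0, 1)")


@dataclass(frozen=True)
class SweepSpec:
    """A planted high-differentiation locus.

    Overrides the drawn frequencies of ``width_snps`` consecutive SNPs
    centred on the SNP nearest ``pos`` with per-population targets; the
    default width of one window (40 SNPs) makes a planted fixed difference
    dominate at least one whole window.
    """

    chrom: str
    pos: int
    freqs: dict[str, float]
    width_snps: int = 40


@dataclass
class SimulationConfig:
    """Full recipe for a synthetic panel; every draw is seed-reproducible."""

    populations: list[PopulationSpec]
    n_snps: int = 20_000
    chromosomes: tuple[tuple[str, int], ...] = DEFAULT_CHROMOSOMES
    ancestral_sfs: str = "uniform"  # "uniform" | "u_shaped"
    beta_a: float = 0.3
    beta_b: float = 0.3
    freq_bounds: tuple[float, float] = DEFAULT_FREQ_BOUNDS
    gap_sigma: float = 1.0  # log-normal sigma of inter-marker bp gaps
    breed_fst: dict[str, float] = field(default_factory=dict)
    sweeps: list[SweepSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ConfigurationError("at least one population is required")
        if self.ancestral_sfs not in ("uniform", "u_shaped"):
            raise ConfigurationError(
                f"ancestral_sfs must be 'uniform' or 'u_shaped', got "
                f"{self.ancestral_sfs!r}"
            )
        lo, hi = self.freq_bounds
        if not 0.0 <= lo < hi <= 1.0:
            raise ConfigurationError("freq_bounds must satisfy 0 <= lo < hi <= 1")
        lengths = dict(self.chromosomes)
        for sw in self.sweeps:
            if sw.chrom not in lengths:
                raise ConfigurationError(
                    f"sweep chromosome {sw.chrom!r} not in the simulated genome"
                )
            if not 1 <= sw.pos <= lengths[sw.chrom]:
                raise ConfigurationError(
                    f"sweep position {sw.pos} outside chromosome {sw.chrom} "
                    f"(length {lengths[sw.chrom]})"
                )
            names = {p.name for p in self.populations}
            unknown = set(sw.freqs) - names
            if unknown:
                raise ConfigurationError(
                    f"sweep targets reference unknown population(s) {unknown}"
                )


def _allocate_snps(cfg: SimulationConfig) -> list[int]:
    """Largest-remainder allocation of n_snps proportional to chrom length."""
    lengths = np.array([length for _, length in cfg.chromosomes], dtype=float)
    raw = cfg.n_snps * lengths / lengths.sum()
    counts = np.floor(raw).astype(int)
    rem = cfg.n_snps - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts.tolist()


def _positions(rng: np.random.Generator, m: int, length: int, sigma: float) -> np.ndarray:
    """Strictly increasing 1-based positions with log-normal gap structure."""
    if m == 0:
        return np.zeros(0, dtype=np.int64)
    gaps = rng.lognormal(mean=0.0, sigma=sigma, size=m)
    cum = np.cumsum(gaps)
    cum = cum / cum[-1]  # (0, 1]
    usable = max(length - m, 1)
    pos = np.floor(cum * usable).astype(np.int64) + np.arange(m) + 1
    return pos


def _draw_ancestral(rng: np.random.Generator, cfg: SimulationConfig, m: int) -> np.ndarray:
    lo, hi = cfg.freq_bounds
    if cfg.ancestral_sfs == "uniform":
        return rng.uniform(lo, hi, size=m)
    dist = stats.beta(cfg.beta_a, cfg.beta_b)
    u = rng.uniform(dist.cdf(lo), dist.cdf(hi), size=m)
    return dist.ppf(u)


def _drift(rng: np.random.Generator, p_anc: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols draw of descendant frequencies around p_anc."""
    if f == 0.0:
        return p_anc.copy()
    scale = (1.0 - f) / f
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale)


def simulate_panel(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, SampleGroups, pd.DataFrame]:
    """Generate a panel; returns (genotypes, groups, truth table).

    The truth table records, per SNP, the ancestral frequency, every
    population's realised frequency, and the sweep flag.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    counts = _allocate_snps(cfg)
    chroms: list[str] = []
    poss: list[np.ndarray] = []
    for (label, length), m in zip(cfg.chromosomes, counts):
        chroms.extend([label] * m)
        poss.append(_positions(rng, m, length, cfg.gap_sigma))
    pos = np.concatenate(poss) if poss else np.zeros(0, dtype=np.int64)
    m_total = len(pos)
    snp_ids = [f"snp{k:06d}" for k in range(m_total)]
    variants = make_variant_table(chroms, pos, snp_ids)

    p0 = _draw_ancestral(rng, cfg, m_total)

    breed_freq: dict[str, np.ndarray] = {}
    for breed, f_breed in cfg.breed_fst.items():
        breed_freq[breed] = _drift(rng, p0, f_breed)

    pop_freq: dict[str, np.ndarray] = {}
    for popn in cfg.populations:
        base = breed_freq[popn.breed] if popn.breed in breed_freq else p0
        pop_freq[popn.name] = _drift(rng, base, popn.fst)

    # plant sweeps: override a block of consecutive SNPs around the target
    chrom_arr = np.array(chroms, dtype=object)
    is_sweep = np.zeros(m_total, dtype=bool)
    for sw in cfg.sweeps:
        on_chrom = np.flatnonzero(chrom_arr == sw.chrom)
        if len(on_chrom) == 0:
            raise ConfigurationError(
                f"no SNPs were simulated on sweep chromosome {sw.chrom!r}"
            )
        centre = on_chrom[np.argmin(np.abs(pos[on_chrom] - sw.pos))]
        rank = int(np.flatnonzero(on_chrom == centre)[0])
        half = sw.width_snps // 2
        lo = max(0, rank - half)
        hi = min(len(on_chrom), lo + sw.width_snps)
        block = on_chrom[lo:hi]
        is_sweep[block] = True
        for name, target in sw.freqs.items():
            pop_freq[name][block] = target

    samples: list[str] = []
    group_of: dict[str, str] = {}
    breed_of: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    for popn in cfg.populations:
        p = pop_freq[popn.name]
        geno = rng.binomial(2, p, size=(popn.n_diploids, m_total)).astype(np.int8)
        blocks.append(geno)
        for i in range(popn.n_diploids):
            sid = f"{popn.name}_{i:03d}"
            samples.append(sid)
            group_of[sid] = popn.name
            if popn.breed is not None:
                breed_of[sid] = popn.breed
    calls = (
        np.vstack(blocks) if blocks else np.zeros((0, m_total), dtype=np.int8)
    )

    g = GenotypeMatrix(calls, variants, samples).sorted_by_position()
    order = np.lexsort(
        (pos, pd.factorize(chrom_arr, sort=True)[0], chrom_sort_rank(chrom_arr))
    )
    truth = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom_arr,
            "pos": pos,
            "p0": p0,
            "is_sweep": is_sweep,
        }
    )
    for popn in cfg.populations:
        truth[f"p_{popn.name}"] = pop_freq[popn.name]
    truth = truth.iloc[order].reset_index(drop=True)

    groups = SampleGroups(group_of, breed_of)
    return g, groups, truth


def two_population_config(
    f: float = 0.1,
    n_diploids: int = 50,
    n_snps: int = 20_000,
    seed: int = 0,
    sweeps: list[SweepSpec] | None = None,
) -> SimulationConfig:
    """Two symmetric populations, each drifting from the ancestor with F=f."""
    return SimulationConfig(
        populations=[
            PopulationSpec("A", n_diploids, f),
            PopulationSpec("B", n_diploids, f),
        ],
        n_snps=n_snps,
        sweeps=sweeps or [],
        seed=seed,
    )


def study_panel_config(n_snps: int = 20_000, seed: int = 0) -> SimulationConfig:
    """A panel shaped like the 96-bird layer study.

    Six groups with the study's sample sizes; commercial lines carry heavy
    breed-level drift (U-shaped spectra), the out-group drifts little from
    a uniform ancestral spectrum.  Drift values are fixed design choices
    chosen to put between-group differentiation in the 0.1-0.3 range
    typical of layer breed comparisons.
    """
    return SimulationConfig(
        populations=[
            PopulationSpec("WL1", 10, 0.05, breed="WL"),
            PopulationSpec("WL2&3", 20, 0.05, breed="WL"),
            PopulationSpec("RIR1", 10, 0.05, breed="RIR"),
            PopulationSpec("RIR2", 10, 0.05, breed="RIR"),
            PopulationSpec("WR", 20, 0.05, breed="WR"),
            PopulationSpec("OG", 26, 0.03),
        ],
        breed_fst={"WL": 0.20, "RIR": 0.15, "WR": 0.15},
        n_snps=n_snps,
        seed=seed,
    )


def write_panel(
    g: GenotypeMatrix,
    s: SampleGroups,
    path,
    format: str = "ped_map",
) -> None:
    """Write a panel (and its group map) to disk; inverse of the readers.

    ``path`` is the PED/MAP prefix or the ``.vcf`` path; the group map is
    written next to it as ``<path>.groups.tsv``.
    """
    if format == "ped_map":
        write_ped_map(g, path)
        write_group_map(s, f"{path}.groups.tsv")
    elif format == "vcf":
        write_vcf(g, path)
        base = str(path)
        if base.endswith(".vcf"):
            base = base[: -len(".vcf")]
        write_group_map(s, f"{base}.groups.tsv")
    else:
        raise ConfigurationError(f"unknown panel format {format!r}")


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.6g")
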