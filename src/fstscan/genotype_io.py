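"""Genotype input/output, chromosome recoding, and QC filtering.

Genotypes are held as an ``n_samples x n_snps`` matrix of alternate-allele
dosages (0/1/2) with -1 marking missing calls.  Variant metadata lives in a
pandas DataFrame with columns ``chrom, pos, snp_id, ref, alt``.  Chromosome
labels follow the chicken assembly convention: autosomes "1".."28", the sex
chromosome "Z", and the linkage groups LGE22C19W28_E50C23 and LGE64, which
are recoded to "40" and "41".  Positions are 1-based throughout (the MAP/VCF
convention); only BED export converts to 0-based half-open coordinates.

Sex-chromosome genotypes are taken at face value as diploid calls, the way
array genotyping platforms deliver them; no hemizygosity model is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, StructuralError

logger = logging.getLogger("fstscan")

MISSING: int = -1

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 29))
SEX_CHROM: str = "Z"
LINKAGE_GROUPS: tuple[str, ...] = ("40", "41")
CHROM_ORDER: tuple[str, ...] = AUTOSOMES + (SEX_CHROM,) + LINKAGE_GROUPS
_CHROM_RANK = {c: i for i, c in enumerate(CHROM_ORDER)}

#: raw linkage-group names seen on the arrays -> canonical labels
LINKAGE_GROUP_RECODE = {"LGE22C19W28_E50C23": "40", "LGE64": "41"}

VARIANT_COLUMNS = ("chrom", "pos", "snp_id", "ref", "alt")


def recode_chrom(label: str) -> str:
    """Map a raw chromosome label to the canonical universe."""
    label = str(label)
    if label.lower().startswith("chr"):
        label = label[3:]
    return LINKAGE_GROUP_RECODE.get(label, label)


def chrom_sort_rank(labels) -> np.ndarray:
    """Integer rank of each chromosome label in the canonical genome order.

    Unknown labels sort after the declared universe, alphabetically.
    """
    labels = np.asarray(labels, dtype=object)
    known = np.array([_CHROM_RANK.get(c, len(CHROM_ORDER)) for c in labels])
    return known


def variant_sort_order(variants: pd.DataFrame) -> np.ndarray:
    """Stable argsort of a variant table by (chromosome rank, label, pos)."""
    rank = chrom_sort_rank(variants["chrom"].to_numpy())
    label_codes = pd.factorize(variants["chrom"], sort=True)[0]
    return np.lexsort((variants["pos"].to_numpy(), label_codes, rank))


def make_variant_table(chrom, pos, snp_id, ref=None, alt=None) -> pd.DataFrame:
    """Assemble a variant table with canonical dtypes (no sorting)."""
    n = len(pos)
    return pd.DataFrame(
        {
            "chrom": np.array([recode_chrom(c) for c in chrom], dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "snp_id": np.array(list(snp_id), dtype=object),
            "ref": np.array(list(ref) if ref is not None else ["A"] * n, dtype=object),
            "alt": np.array(list(alt) if alt is not None else ["B"] * n, dtype=object),
        }
    )


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes bound to variant and sample metadata.

    calls[i, j] counts copies of ``variants.alt[j]`` carried by sample i,
    with :data:`MISSING` (-1) for no-calls.
    """

    calls: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise StructuralError("calls must be a 2-D samples x snps array")
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise StructuralError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise StructuralError("genotype codes must be in {0, 1, 2, -1}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = variant_sort_order(self.variants)
        if np.array_equal(order, np.arange(len(order))):
            return self
        return GenotypeMatrix(
            self.calls[:, order],
            self.variants.iloc[order].reset_index(drop=True),
            list(self.samples),
        )

    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.calls[:, idx],
            self.variants.iloc[idx].reset_index(drop=True),
            list(self.samples),
        )


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for the two-stage SNP filter cascade.

    Satisfies ``n_input = n_removed_missing + n_removed_maf + n_remaining``
    by construction; violating counts raise :class:`StructuralError`.
    """

    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_remaining: int

    def __post_init__(self) -> None:
        if self.n_input != (
            self.n_removed_missing + self.n_removed_maf + self.n_remaining
        ):
            raise StructuralError(
                "filter counts do not sum: "
                f"{self.n_input} != {self.n_removed_missing} + "
                f"{self.n_removed_maf} + {self.n_remaining}"
            )

    @classmethod
    def from_stage_counts(
        cls, n_input: int, n_removed_missing: int, n_removed_maf: int
    ) -> "FilterReport":
        """Derive the remaining count from the cascade identity."""
        return cls(
            n_input,
            n_removed_missing,
            n_removed_maf,
            n_input - n_removed_missing - n_removed_maf,
        )


@dataclass
class SampleGroups:
    """Assignment of every sample to exactly one analysis group.

    Optional breed and line labels record the two-level population
    hierarchy (lines nested within breeds) when known.
    """

    group_of: dict[str, str]
    breed_of: dict[str, str] = field(default_factory=dict)
    line_of: dict[str, str] = field(default_factory=dict)

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group_of.values():
            seen.setdefault(g, None)
        return list(seen)

    def members(self, group: str) -> list[str]:
        return [s for s, g in self.group_of.items() if g == group]

    def indices(self, samples: list[str], group: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(samples) if self.group_of.get(s) == group],
            dtype=np.intp,
        )

    def validate_against(self, g: GenotypeMatrix) -> None:
        missing = [s for s in g.samples if s not in self.group_of]
        if missing:
            raise StructuralError(
                f"{len(missing)} samples lack a group label, e.g. {missing[0]!r}"
            )
        for grp in self.groups():
            if not self.members(grp):
                raise StructuralError(f"group {grp!r} has no samples")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_genotypes(path, format: str = "ped_map") -> GenotypeMatrix:
    """Read genotypes from PED/MAP or VCF into a :class:`GenotypeMatrix`.

    Variants are returned sorted by (chromosome, position).  For VCF,
    multi-allelic sites are skipped with a logged count.  ``path`` for
    PED/MAP may be the ``.ped`` file or the common prefix.
    """
    if format == "ped_map":
        g = _read_ped_map(Path(path))
    elif format == "vcf":
        g = _read_vcf(Path(path))
    else:
        raise ConfigurationError(f"unknown genotype format {format!r}")
    return g.sorted_by_position()


def _ped_map_paths(path: Path) -> tuple[Path, Path, Path]:
    if path.suffix == ".ped":
        base = str(path)[: -len(".ped")]
    else:
        base = str(path)
    return Path(base + ".ped"), Path(base + ".map"), Path(base + ".ref")


def _read_map(map_path: Path) -> pd.DataFrame:
    chroms, ids, poss = [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ParseError(
                    f"{map_path}:{lineno}: expected 4 fields, got {len(parts)}"
                )
            try:
                pos = int(parts[3])
            except ValueError as exc:
                raise ParseError(
                    f"{map_path}:{lineno}: position {parts[3]!r} is not an integer"
                ) from exc
            if pos <= 0:
                raise ParseError(f"{map_path}:{lineno}: position must be positive")
            chroms.append(parts[0])
            ids.append(parts[1])
            poss.append(pos)
    return make_variant_table(chroms, poss, ids)


def _read_ped_map(path: Path) -> GenotypeMatrix:
    ped_path, map_path, ref_path = _ped_map_paths(path)
    variants = _read_map(map_path)
    m = len(variants)
    expected = 6 + 2 * m

    samples: list[str] = []
    rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != expected:
                raise StructuralError(
                    f"{ped_path}:{lineno}: expected {expected} fields for "
                    f"{m} SNPs, got {len(parts)}"
                )
            samples.append(parts[1])
            rows.append(parts[6:])

    if m == 0:
        return GenotypeMatrix(
            np.zeros((len(samples), 0), dtype=np.int8), variants, samples
        )

    tokens = np.array(rows, dtype="U16") if rows else np.empty((0, 2 * m), dtype="U16")
    left = tokens[:, 0::2]
    right = tokens[:, 1::2]

    known_alleles: dict[str, tuple[str, str]] = {}
    if ref_path.exists():
        with open(ref_path) as fh:
            for lineno, line in enumerate(fh, 1):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) != 3:
                    raise ParseError(
                        f"{ref_path}:{lineno}: expected 'snp_id ref alt'"
                    )
                known_alleles[parts[0]] = (parts[1], parts[2])

    calls = np.full((len(samples), m), MISSING, dtype=np.int8)
    refs, alts = [], []
    for j in range(m):
        lj, rj = left[:, j], right[:, j]
        called = (lj != "0") & (rj != "0")
        snp_id = variants["snp_id"].iloc[j]
        if snp_id in known_alleles:
            ref, alt = known_alleles[snp_id]
        else:
            obs = np.unique(np.concatenate([lj[called], rj[called]]))
            if len(obs) > 2:
                raise ParseError(
                    f"{ped_path}: SNP {snp_id} has {len(obs)} alleles; "
                    "only biallelic sites are supported"
                )
            ref = obs[0] if len(obs) >= 1 else "A"
            alt = obs[1] if len(obs) == 2 else "."
        calls[called, j] = (lj[called] == alt).astype(np.int8) + (
            rj[called] == alt
        ).astype(np.int8)
        refs.append(ref)
        alts.append(alt)

    variants["ref"] = np.array(refs, dtype=object)
    variants["alt"] = np.array(alts, dtype=object)
    return GenotypeMatrix(calls, variants, samples)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, ids, refs, alts, cols = [], [], [], [], [], []
    n_multiallelic = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multiallelic += 1
            continue
        chrom = recode_chrom(var.CHROM)
        chroms.append(chrom)
        poss.append(var.POS)
        ids.append(var.ID if var.ID not in (None, ".") else f"{chrom}_{var.POS}")
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0/1/2, 3 = missing
        gt[gt == 3] = MISSING
        cols.append(gt)
    if n_multiallelic:
        logger.info("skipped %d multi-allelic site(s) in %s", n_multiallelic, path)
    calls = (
        np.column_stack(cols)
        if cols
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    variants = make_variant_table(chroms, poss, ids, refs, alts)
    return GenotypeMatrix(calls, variants, samples)


def read_group_map(path) -> SampleGroups:
    """Read the TSV sample-to-group map (header: sample_id<TAB>group[...])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ParseError(f"{path}: group map lacks required column {col!r}")
    group_of = dict(zip(df["sample_id"], df["group"]))
    if len(group_of) != len(df):
        raise StructuralError(f"{path}: duplicate sample ids in group map")
    breed_of = (
        dict(zip(df["sample_id"], df["breed"])) if "breed" in df.columns else {}
    )
    line_of = dict(zip(df["sample_id"], df["line"])) if "line" in df.columns else {}
    return SampleGroups(group_of, breed_of, line_of)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_ped_map(g: GenotypeMatrix, prefix, write_ref: bool = True) -> None:
    """Write PED/MAP text files (plus a ``.ref`` allele-order sidecar).

    The sidecar pins which allele is counted as alternate so that a
    write-read round trip reproduces the dosage codes exactly even at
    sites where only one allele is observed.
    """
    ped_path, map_path, ref_path = _ped_map_paths(Path(prefix))
    v = g.variants
    with open(map_path, "w") as fh:
        for chrom, snp_id, pos in zip(v["chrom"], v["snp_id"], v["pos"]):
            fh.write(f"{chrom}\t{snp_id}\t0\t{pos}\n")

    ref = v["ref"].to_numpy(dtype=object)
    alt = v["alt"].to_numpy(dtype=object)
    # token lookup per SNP for codes 0,1,2 and missing
    lut = np.empty((4, g.n_snps), dtype=object)
    lut[0] = [f"{r} {r}" for r in ref]
    lut[1] = [f"{r} {a}" for r, a in zip(ref, alt)]
    lut[2] = [f"{a} {a}" for a in alt]
    lut[3] = "0 0"
    code_idx = np.where(g.calls < 0, 3, g.calls)
    cols = np.arange(g.n_snps)
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(g.samples):
            tokens = lut[code_idx[i], cols]
            geno = " ".join(tokens) if g.n_snps else ""
            sep = " " if geno else ""
            fh.write(f"{sample} {sample} 0 0 0 -9{sep}{geno}\n")

    if write_ref:
        with open(ref_path, "w") as fh:
            for snp_id, r, a in zip(v["snp_id"], ref, alt):
                fh.write(f"{snp_id}\t{r}\t{a}\n")


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 text file with GT-only genotype fields."""
    v = g.variants
    gt_lut = np.array(["0/0", "0/1", "1/1", "./."])
    code_idx = np.where(g.calls < 0, 3, g.calls)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen = {}
        for chrom in v["chrom"]:
            seen.setdefault(chrom, None)
        for chrom in seen:
            block = v.loc[v["chrom"] == chrom, "pos"]
            length = int(block.max()) + 1000 if len(block) else 1000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                  "FORMAT"] + list(g.samples)
        fh.write("\t".join(header) + "\n")
        for j in range(g.n_snps):
            ref = v["ref"].iloc[j]
            alt = v["alt"].iloc[j]
            ref = ref if ref not in (".", "") else "N"
            alt = alt if alt not in (".", "") else "N"
            row = [
                str(v["chrom"].iloc[j]),
                str(int(v["pos"].iloc[j])),
                str(v["snp_id"].iloc[j]),
                ref,
                alt,
                ".",
                "PASS",
                ".",
                "GT",
            ] + list(gt_lut[code_idx[:, j]])
            fh.write("\t".join(row) + "\n")


def write_group_map(s: SampleGroups, path) -> None:
    cols = {"sample_id": list(s.group_of), "group": list(s.group_of.values())}
    if s.breed_of:
        cols["breed"] = [s.breed_of.get(x, "") for x in s.group_of]
    if s.line_of:
        cols["line"] = [s.line_of.get(x, "") for x in s.group_of]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------


def deduplicate_variants(g: GenotypeMatrix) -> GenotypeMatrix:
    """Drop repeated (chrom, pos) keys, keeping the first sorted occurrence.

    Array panels that share loci produce duplicate positions with distinct
    id strings; the locus, not the id, defines identity here.  Conflicting
    genotypes between duplicate copies are resolved kept-first with a
    warning.
    """
    g = g.sorted_by_position()
    key = pd.MultiIndex.from_arrays([g.variants["chrom"], g.variants["pos"]])
    keep = ~key.duplicated(keep="first")
    n_removed = int((~keep).sum())
    if n_removed:
        dup_idx = np.flatnonzero(~keep)
        first_idx = np.searchsorted(
            np.flatnonzero(keep), dup_idx, side="right"
        ) - 1
        kept_cols = g.calls[:, np.flatnonzero(keep)[first_idx]]
        n_conflicts = int(
            np.any(kept_cols != g.calls[:, dup_idx], axis=0).sum()
        )
        logger.info("removed %d duplicate-position SNP(s)", n_removed)
        if n_conflicts:
            logger.warning(
                "%d duplicate SNP(s) had conflicting genotypes; kept first copy",
                n_conflicts,
            )
    return g.take_variants(np.flatnonzero(keep))


def apply_qc_filters(
    g: GenotypeMatrix,
    max_missing_calls: int = 0,
    maf_floor: float = 0.05,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Two-stage SNP filter: missingness first, then minor allele frequency.

    Stage 1 removes SNPs with more than ``max_missing_calls`` missing
    genotypes (default 0: any missing value removes the SNP).  Stage 2
    removes SNPs whose MAF over the remaining non-missing calls is
    strictly below ``maf_floor`` (MAF exactly at the floor is kept).
    """
    if not 0.0 <= maf_floor <= 0.5:
        raise ConfigurationError(f"maf_floor must be in [0, 0.5], got {maf_floor}")
    if max_missing_calls < 0:
        raise ConfigurationError("max_missing_calls must be >= 0")

    n_input = g.n_snps
    n_missing = (g.calls == MISSING).sum(axis=0)
    pass_missing = n_missing <= max_missing_calls
    n_removed_missing = int((~pass_missing).sum())
    g1 = g.take_variants(np.flatnonzero(pass_missing))

    called = g1.calls != MISSING
    alt = np.where(called, g1.calls, 0).sum(axis=0).astype(float)
    denom = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(denom > 0, alt / np.where(denom > 0, denom, 1.0), np.nan)
    maf = np.fmin(p, 1.0 - p)
    pass_maf = ~(maf < maf_floor)  # NaN MAF (no calls) passes stage 2
    n_removed_maf = int((~pass_maf).sum())
    g2 = g1.take_variants(np.flatnonzero(pass_maf))

    report = FilterReport(n_input, n_removed_missing, n_removed_maf, g2.n_snps)
    logger.info(
        "QC filter: %d in, %d removed (missing), %d removed (MAF<%.3g), %d remain",
        report.n_input,
        report.n_removed_missing,
        report.n_removed_maf,
        maf_floor,
        report.n_remaining,
    )
    return g2, report
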