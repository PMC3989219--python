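import numpy as np
import pandas as pd
import pytest

from fstscan.genotype_io import GenotypeMatrix, SampleGroups, make_variant_table


@pytest.fixture
def toy_ped_map(tmp_path):
    """Hand-encoded 2-sample, 3-SNP PED/MAP fixture with known codes.

    snp1 (chr1:100): s1 = A/A, s2 = A/G  -> alt G, codes 0, 1
    snp2 (chr1:200): s1 = A/G, s2 = ./.  -> alt G, codes 1, missing
    snp3 (chr2:50):  s1 = G/G, s2 = G/T  -> alt T, codes 0, 1
    """
    (tmp_path / "toy.map").write_text(
        "1\tsnp1\t0\t100\n1\tsnp2\t0\t200\n2\tsnp3\t0\t50\n"
    )
    (tmp_path / "toy.ped").write_text(
        "fam1 s1 0 0 1 -9 A A A G G G\n"
        "fam1 s2 0 0 2 -9 A G 0 0 G T\n"
    )
    return tmp_path / "toy"


def random_matrix(rng, n_samples=6, n_snps=20, missing_rate=0.1):
    """A random valid GenotypeMatrix with A/B alleles and missing calls."""
    calls = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    calls[rng.random((n_samples, n_snps)) < missing_rate] = -1
    chrom_pool = ["1", "2", "Z"]
    chroms = [chrom_pool[int(c)] for c in rng.integers(0, 3, n_snps)]
    pos = rng.integers(1, 10_000_000, n_snps)
    variants = make_variant_table(
        chroms, pos, [f"rs{i}" for i in range(n_snps)],
        ["A"] * n_snps, ["B"] * n_snps,
    )
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(calls, variants, samples).sorted_by_position()


@pytest.fixture
def two_group_matrix():
    """10 + 10 samples, 60 SNPs on two chromosomes, no missing calls."""
    rng = np.random.default_rng(42)
    g = random_matrix(rng, n_samples=20, n_snps=60, missing_rate=0.0)
    groups = SampleGroups({s: ("A" if i < 10 else "B") for i, s in enumerate(g.samples)})
    return g, groups


def variant_table_for(chrom_counts: dict[str, int]) -> pd.DataFrame:
    """Sorted variant table with the given SNPs per chromosome."""
    chroms, pos, ids = [], [], []
    for chrom, m in chrom_counts.items():
        chroms.extend([chrom] * m)
        pos.extend(range(1000, 1000 + 1000 * m, 1000))
        ids.extend(f"{chrom}_{i}" for i in range(m))
    return make_variant_table(chroms, pos, ids)
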