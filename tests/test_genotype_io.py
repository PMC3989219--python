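import numpy as np
import pytest

from fstscan.errors import ConfigurationError, FstscanError, StructuralError
from fstscan.genotype_io import (
    FilterReport,
    GenotypeMatrix,
    SampleGroups,
    apply_qc_filters,
    deduplicate_variants,
    make_variant_table,
    read_genotypes,
    read_group_map,
    recode_chrom,
    write_ped_map,
    write_vcf,
)

from conftest import random_matrix


class TestReadPedMap:
    def test_toy_fixture_codes(self, toy_ped_map):
        g = read_genotypes(toy_ped_map, "ped_map")
        assert g.samples == ["s1", "s2"]
        assert list(g.variants["snp_id"]) == ["snp1", "snp2", "snp3"]
        assert list(g.variants["pos"]) == [100, 200, 50]
        np.testing.assert_array_equal(
            g.calls, np.array([[0, 1, 0], [1, -1, 1]], dtype=np.int8)
        )

    def test_empty_variant_list_is_valid(self, tmp_path):
        (tmp_path / "e.map").write_text("")
        (tmp_path / "e.ped").write_text("f s1 0 0 0 -9\nf s2 0 0 0 -9\n")
        g = read_genotypes(tmp_path / "e", "ped_map")
        assert g.n_snps == 0 and g.n_samples == 2

    def test_inconsistent_row_raises_with_line_number(self, tmp_path):
        (tmp_path / "b.map").write_text("1\tsnp1\t0\t100\n")
        (tmp_path / "b.ped").write_text(
            "f s1 0 0 0 -9 A A\nf s2 0 0 0 -9 A\n"
        )
        with pytest.raises(FstscanError, match="b.ped:2"):
            read_genotypes(tmp_path / "b", "ped_map")

    def test_bad_map_position(self, tmp_path):
        (tmp_path / "c.map").write_text("1\tsnp1\t0\tx\n")
        (tmp_path / "c.ped").write_text("f s1 0 0 0 -9 A A\n")
        with pytest.raises(FstscanError, match="c.map:1"):
            read_genotypes(tmp_path / "c", "ped_map")

    def test_unknown_format(self, toy_ped_map):
        with pytest.raises(ConfigurationError):
            read_genotypes(toy_ped_map, "bed")


class TestReadVcf:
    def test_multiallelic_sites_skipped(self, tmp_path, caplog):
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "##contig=<ID=1,length=100000>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2",
        ]
        for i in range(5):
            alt = "G,T" if i == 2 else "G"
            lines.append(
                f"1\t{100 * (i + 1)}\tv{i}\tA\t{alt}\t.\tPASS\t.\tGT\t0/1\t1/1"
            )
        vcf = tmp_path / "x.vcf"
        vcf.write_text("\n".join(lines) + "\n")
        with caplog.at_level("INFO", logger="fstscan"):
            g = read_genotypes(vcf, "vcf")
        assert g.n_snps == 4
        assert "1 multi-allelic" in caplog.text
        np.testing.assert_array_equal(g.calls[:, 0], [1, 2])

    def test_linkage_groups_recode(self, tmp_path):
        assert recode_chrom("LGE22C19W28_E50C23") == "40"
        assert recode_chrom("LGE64") == "41"
        assert recode_chrom("chrZ") == "Z"


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ped_map_round_trip(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        g = random_matrix(rng, n_samples=5, n_snps=15)
        write_ped_map(g, tmp_path / "rt")
        g2 = read_genotypes(tmp_path / "rt", "ped_map")
        np.testing.assert_array_equal(g.calls, g2.calls)
        assert list(g.variants["pos"]) == list(g2.variants["pos"])
        assert list(g.variants["chrom"]) == list(g2.variants["chrom"])
        assert g.samples == g2.samples

    def test_vcf_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        g = random_matrix(rng, n_samples=4, n_snps=12)
        write_vcf(g, tmp_path / "rt.vcf")
        g2 = read_genotypes(tmp_path / "rt.vcf", "vcf")
        np.testing.assert_array_equal(g.calls, g2.calls)
        assert list(g.variants["pos"]) == list(g2.variants["pos"])


def _matrix_at_positions(pairs, calls):
    variants = make_variant_table(
        [c for c, _ in pairs],
        [p for _, p in pairs],
        [f"id{i}" for i in range(len(pairs))],
    )
    return GenotypeMatrix(
        np.asarray(calls, dtype=np.int8), variants,
        [f"s{i}" for i in range(np.asarray(calls).shape[0])],
    ).sorted_by_position()


class TestDeduplicate:
    def test_two_sharing_a_position(self):
        g = _matrix_at_positions(
            [("1", 100), ("1", 200), ("1", 200), ("1", 300), ("2", 100)],
            [[0, 1, 2, 1, 0]],
        )
        out = deduplicate_variants(g)
        assert out.n_snps == 4
        assert list(out.variants["pos"]) == [100, 200, 300, 100]

    def test_all_three_at_one_position(self):
        g = _matrix_at_positions(
            [("1", 100)] * 3, [[0, 1, 2], [2, 2, 2]]
        )
        out = deduplicate_variants(g)
        assert out.n_snps == 1
        np.testing.assert_array_equal(out.calls[:, 0], [0, 2])  # first kept

    def test_no_duplicates_is_identity(self):
        g = _matrix_at_positions(
            [("1", 100), ("1", 200), ("2", 100)], [[0, 1, 2]]
        )
        out = deduplicate_variants(g)
        np.testing.assert_array_equal(out.calls, g.calls)

    def test_conflicting_duplicates_warn(self, caplog):
        g = _matrix_at_positions(
            [("1", 100), ("1", 100)], [[0, 2], [1, 1]]
        )
        with caplog.at_level("WARNING", logger="fstscan"):
            out = deduplicate_variants(g)
        assert out.n_snps == 1
        assert "conflicting genotypes" in caplog.text


class TestQcFilters:
    def _toy(self):
        # 25 samples, 4 SNPs: snp2 has one missing call; snp3 has MAF 0.02
        calls = np.zeros((25, 4), dtype=np.int8)
        calls[:12, 0] = 2           # snp1: p = 0.48
        calls[0, 1] = -1            # snp2: one missing value
        calls[:13, 1] = np.where(calls[:13, 1] == -1, -1, 1)
        calls[0, 2] = 1             # snp3: MAF = 1/50 = 0.02
        calls[:5, 3] = 2            # snp4: MAF = 0.2
        g = _matrix_at_positions(
            [("1", p) for p in (100, 200, 300, 400)], calls
        )
        return g

    def test_two_stage_counts(self):
        g2, report = apply_qc_filters(self._toy())
        assert report == FilterReport(4, 1, 1, 2)
        assert g2.n_snps == 2
        assert list(g2.variants["pos"]) == [100, 400]
        assert not (g2.calls == -1).any()

    def test_identity_when_clean(self):
        g = _matrix_at_positions(
            [("1", 100), ("1", 200)],
            np.array([[0, 1], [2, 1], [1, 0], [1, 2]], dtype=np.int8),
        )
        g2, report = apply_qc_filters(g)
        np.testing.assert_array_equal(g2.calls, g.calls)
        assert report == FilterReport(2, 0, 0, 2)

    def test_idempotent(self):
        g = self._toy()
        once, r1 = apply_qc_filters(g)
        twice, r2 = apply_qc_filters(once)
        np.testing.assert_array_equal(once.calls, twice.calls)
        assert r2.n_removed_missing == 0 and r2.n_removed_maf == 0

    def test_maf_exactly_at_floor_is_kept(self):
        # 10 samples, one SNP with exactly MAF 0.05 = 1/20
        calls = np.zeros((10, 1), dtype=np.int8)
        calls[0, 0] = 1
        g = _matrix_at_positions([("1", 100)], calls)
        g2, report = apply_qc_filters(g, maf_floor=0.05)
        assert g2.n_snps == 1 and report.n_removed_maf == 0

    def test_maf_floor_out_of_range(self):
        with pytest.raises(ConfigurationError):
            apply_qc_filters(self._toy(), maf_floor=0.6)


class TestFilterReport:
    def test_identity_enforced(self):
        with pytest.raises(StructuralError):
            FilterReport(10, 5, 4, 2)

    def test_from_stage_counts(self):
        r = FilterReport.from_stage_counts(100, 30, 20)
        assert r.n_remaining == 50


class TestSampleGroups:
    def test_read_group_map(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("sample_id\tgroup\ns1\tA\ns2\tB\n")
        s = read_group_map(p)
        assert s.group_of == {"s1": "A", "s2": "B"}

    def test_missing_label_raises(self, two_group_matrix):
        g, _ = two_group_matrix
        s = SampleGroups({g.samples[0]: "A"})
        with pytest.raises(StructuralError, match="lack a group"):
            s.validate_against(g)
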