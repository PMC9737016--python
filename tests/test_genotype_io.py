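import numpy as np
import pytest

from conftest import make_panel
from rohscan.genotype_io import (
    FilterConfig,
    apply_site_filters,
    default_autosomes,
    read_vcf,
    write_vcf,
)
from rohscan.panel import VariantSite
from rohscan.simulate import SimConfig, simulate_panel


class TestReadVcf:
    def test_direct_ingestion(self, tiny_vcf):
        panel = read_vcf(tiny_vcf)
        assert panel.individuals == ["s1", "s2", "s3"]
        assert panel.n_sites == 5
        assert panel.sites["pos"].tolist() == [100, 200, 300, 400, 500]

    def test_genotype_coding_and_phasing(self, tiny_vcf):
        panel = read_vcf(tiny_vcf)
        # phased 0|1 and unphased 1/0 both code as heterozygous; ./. as -1
        assert panel.genotypes[:, 1].tolist() == [1, 1, 0]
        assert panel.genotypes[0, 2] == -1
        assert panel.genotypes[:, 3].tolist() == [2, 2, 2]

    def test_multiallelic_record_excluded(self, tmp_path, tiny_vcf):
        text = tiny_vcf.read_text().replace(
            "1\t300\t.\tA\tG\t60", "1\t300\t.\tA\tG,T\t60"
        ).replace("\t./.\t0/0\t1/1", "\t./.\t0/0\t1/2")
        path = tmp_path / "multi.vcf"
        path.write_text(text)
        panel = read_vcf(path)
        assert panel.n_sites == 4
        assert 300 not in panel.sites["pos"].tolist()

    def test_autosome_restriction_and_chr_prefix(self, tmp_path, tiny_vcf):
        text = tiny_vcf.read_text().replace("1\t500", "chrX\t500")
        path = tmp_path / "x.vcf"
        path.write_text(text)
        panel = read_vcf(path, autosomes=default_autosomes())
        assert panel.n_sites == 4

    def test_duplicate_position_rejected(self, tmp_path, tiny_vcf):
        text = tiny_vcf.read_text().replace("1\t500", "1\t400")
        path = tmp_path / "dup.vcf"
        path.write_text(text)
        with pytest.raises(ValueError, match="duplicate"):
            read_vcf(path)

    def test_no_samples_rejected(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        with pytest.raises(ValueError, match="no samples"):
            read_vcf(path)


class TestRoundTrip:
    def test_tiny_roundtrip(self, tmp_path):
        panel = make_panel([[0, 1], [2, -1]], positions=[100, 200])
        path = tmp_path / "rt.vcf"
        write_vcf(panel, path)
        back = read_vcf(path)
        assert np.array_equal(back.genotypes, panel.genotypes)
        assert back.sites[["chrom", "pos", "ref", "alt"]].equals(
            panel.sites[["chrom", "pos", "ref", "alt"]]
        )
        # missing code written as ./.
        assert "./." in path.read_text()

    def test_synthetic_panel_roundtrip(self, tmp_path):
        cfg = SimConfig(
            seed=11, n_individuals=30, chromosomes=(("1", 2_000_000, 1000),),
            missing_rate=0.03,
        )
        panel, _ = simulate_panel(cfg)
        path = tmp_path / "sim.vcf.gz"
        write_vcf(panel, path)
        back = read_vcf(path)
        assert back.individuals == panel.individuals
        assert np.array_equal(back.genotypes, panel.genotypes)
        assert back.sites["pos"].equals(panel.sites["pos"])


class TestSiteFilters:
    def test_maf_threshold_is_strict(self):
        # 10 individuals, 1 alt copy in 20 -> MAF 0.05 exactly -> removed
        geno = np.zeros((10, 2), dtype=np.int8)
        geno[0, 0] = 1  # site 0: MAF 0.05
        geno[:3, 1] = 1  # site 1: MAF 0.15
        panel = make_panel(geno)
        cfg = FilterConfig(hwe_p_min=0.0)
        filtered, report = apply_site_filters(panel, cfg)
        assert filtered.sites["pos"].tolist() == [2000]
        assert report.n_removed["maf"] == 1

    def test_clean_site_retained(self):
        geno = np.array([[0, 1, 2, 1, 0, 0, 1, 0, 2, 0]]).T.reshape(10, 1)
        panel = make_panel(geno)
        filtered, report = apply_site_filters(panel, FilterConfig())
        assert filtered.n_sites == 1
        assert report.n_retained == 1

    def test_first_failure_attribution_and_reconciliation(self):
        rng = np.random.default_rng(3)
        geno = rng.choice([0, 1, 2], size=(20, 10)).astype(np.int8)
        # 3 sites fail MAF only (monomorphic), the rest pass everything
        geno[:, [2, 5, 7]] = 0
        panel = make_panel(geno)
        cfg = FilterConfig(hwe_p_min=0.0, max_missing_rate=1.0)
        filtered, report = apply_site_filters(panel, cfg)
        assert report.n_removed["maf"] == 3
        assert report.n_retained == 7
        assert report.n_input_sites == report.n_retained + sum(report.n_removed.values())

    def test_missingness_strict_and_counted_once(self):
        geno = np.zeros((10, 1), dtype=np.int8)
        geno[:5, 0] = 1
        geno[0, 0] = -1  # 10% missing exactly -> fails strict <
        panel = make_panel(geno)
        _, report = apply_site_filters(panel, FilterConfig())
        assert report.n_removed["missingness"] == 1
        assert report.n_removed["maf"] == 0

    def test_quality_filter_applies_only_when_present(self):
        geno = np.tile([0, 1, 2, 1, 0], (2, 1)).T.reshape(5, 2)
        panel = make_panel(geno, qual=[10.0, None])
        _, report = apply_site_filters(panel, FilterConfig(maf_min=0.0, max_missing_rate=1.0, hwe_p_min=0.0))
        assert report.n_removed["quality"] == 1
        assert report.n_retained == 1

    def test_filter_idempotence(self):
        cfg_sim = SimConfig(
            seed=5, n_individuals=20, chromosomes=(("1", 1_000_000, 500),),
            maf_lo=0.01, missing_rate=0.05,
        )
        panel, _ = simulate_panel(cfg_sim)
        cfg = FilterConfig()
        once, _ = apply_site_filters(panel, cfg)
        twice, report = apply_site_filters(once, cfg)
        assert np.array_equal(once.genotypes, twice.genotypes)
        assert report.n_retained == once.n_sites
        assert sum(report.n_removed.values()) == 0

    def test_all_sites_removed_warns_not_raises(self):
        geno = np.zeros((5, 2), dtype=np.int8)  # monomorphic: MAF 0
        panel = make_panel(geno)
        with pytest.warns(UserWarning, match="all sites removed"):
            filtered, _ = apply_site_filters(panel, FilterConfig())
        assert filtered.n_sites == 0


class TestVariantSite:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="1", pos=0, ref="A", alt="C"),
            dict(chrom="1", pos=5, ref="A", alt="A"),
            dict(chrom="1", pos=5, ref="AT", alt="C"),
        ],
    )
    def test_invalid_sites_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VariantSite(**kwargs)
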