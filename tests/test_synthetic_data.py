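"""Simulator: spectrum fidelity, purity scaling, thinning laws, serialization."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import beta as beta_dist
from scipy.stats import chisquare, kstest

from tmbbias.spectrum_model import BetaSpectrum
from tmbbias.synthetic_data import (
    DepthModel,
    SimulatedSite,
    SimulationConfig,
    TumourSample,
    downsample_sample,
    read_sample_tsv,
    simulate_cohort,
    simulate_sample,
    write_sample_tsv,
    write_sample_vcf,
)

STEEP = BetaSpectrum(0.1, 100.0)


def subclonal_config(**kw):
    defaults = dict(
        n_clonal=0,
        n_subclonal=200,
        subclonal_spectrum=STEEP,
        depth_model=DepthModel.fixed(100),
        seed=11,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestDepthModel:
    def test_fixed(self, rng):
        assert np.all(DepthModel.fixed(100).sample(rng, 50) == 100)

    def test_poisson_mean_and_floor(self, rng):
        d = DepthModel.poisson(30.0).sample(rng, 20_000)
        assert d.min() >= 1
        assert abs(d.mean() - 30.0) < 3 * math.sqrt(30 / 20_000)

    def test_negative_binomial_overdispersion(self, rng):
        d = DepthModel.negative_binomial(100.0, 5.0).sample(rng, 20_000)
        assert d.min() >= 1
        # var = mean + mean^2/dispersion = 2100
        assert 1500 < d.var() < 2800

    def test_validation(self):
        with pytest.raises(ValueError):
            DepthModel("uniform", 10)
        with pytest.raises(ValueError):
            DepthModel.negative_binomial(100, -1)


class TestSimulateSample:
    def test_fixed_depth_site_count(self):
        sample = simulate_sample(subclonal_config())
        assert len(sample) == 200
        assert np.all(sample.depths() == 100)
        assert not any(s.is_clonal for s in sample.sites)

    def test_clonal_sites_scaled_by_purity(self):
        cfg = subclonal_config(n_clonal=50, n_subclonal=0, purity=0.5)
        sample = simulate_sample(cfg)
        assert np.allclose(sample.true_vafs(), 0.25)
        assert all(s.is_clonal for s in sample.sites)

    def test_subclonal_mean_matches_beta_mean(self):
        cfg = subclonal_config(n_subclonal=10_000)
        vafs = simulate_sample(cfg).true_vafs()
        target = 0.1 / 100.1
        se = vafs.std(ddof=1) / math.sqrt(vafs.size)
        assert abs(vafs.mean() - target) < 3 * se

    def test_spectrum_fidelity_ks(self):
        cfg = subclonal_config(n_subclonal=10_000)
        vafs = simulate_sample(cfg).true_vafs()
        stat = kstest(vafs, lambda x: beta_dist.cdf(x, 0.1, 100.0)).statistic
        assert stat < 0.02

    def test_alt_fraction_concentrates_on_scaled_vaf(self):
        # depth 10,000: observed proportion ~ purity * f with binomial SE
        cfg = subclonal_config(
            n_clonal=100,
            n_subclonal=0,
            purity=0.6,
            depth_model=DepthModel.fixed(10_000),
        )
        sample = simulate_sample(cfg)
        props = sample.alt_counts() / sample.depths()
        se = props.std(ddof=1) / math.sqrt(props.size)
        assert abs(props.mean() - 0.3) < 3 * se

    def test_deterministic_for_fixed_seed(self):
        a = simulate_sample(subclonal_config())
        b = simulate_sample(subclonal_config())
        assert a.sites == b.sites
        assert a.seed == b.seed

    def test_config_validation_lists_fields(self):
        with pytest.raises(ValueError, match="purity"):
            subclonal_config(purity=1.5)
        with pytest.raises(ValueError, match="n_clonal"):
            SimulationConfig(
                n_clonal=0, n_subclonal=0, subclonal_spectrum=STEEP
            )


class TestDownsampling:
    def test_fraction_one_is_identity(self):
        sample = simulate_sample(subclonal_config())
        copy = downsample_sample(sample, 1.0, seed=5)
        assert copy.sites == sample.sites
        assert copy is not sample

    def test_half_fraction_halves_depth(self):
        cfg = subclonal_config(n_subclonal=5000)
        sample = simulate_sample(cfg)
        thinned = downsample_sample(sample, 0.5, seed=6)
        mean_depth = thinned.depths().mean()
        se = thinned.depths().std(ddof=1) / math.sqrt(len(thinned))
        assert abs(mean_depth - 50.0) < 3 * se

    def test_alt_thinning_law_chisquare(self):
        # alt=4 at fraction 0.5 -> Binomial(4, 1/2) over repeated seeds
        site = SimulatedSite("s", 0.04, 100, 4, False)
        base = TumourSample([site], 1.0, 0.0, 1.0, 0)
        alts = np.array(
            [
                downsample_sample(base, 0.5, seed=s).sites[0].alt_count
                for s in range(10_000)
            ]
        )
        observed = np.bincount(alts, minlength=5)
        expected = 10_000 * np.array([math.comb(4, k) for k in range(5)]) / 16
        assert chisquare(observed, expected).pvalue > 0.01

    def test_thinning_composition_moments(self):
        # thin by 0.8 then 0.5 == thin by 0.4 in distribution (first two moments)
        site = SimulatedSite("s", 0.3, 200, 60, False)
        base = TumourSample([site], 1.0, 0.0, 1.0, 0)
        two_step, one_step = [], []
        for s in range(5000):
            mid = downsample_sample(base, 0.8, seed=2 * s)
            two_step.append(downsample_sample(mid, 0.5, seed=2 * s + 1).sites[0].depth)
            one_step.append(downsample_sample(base, 0.4, seed=s + 10**6).sites[0].depth)
        two_step, one_step = np.asarray(two_step), np.asarray(one_step)
        se_mean = math.sqrt(two_step.var() / 5000 + one_step.var() / 5000)
        assert abs(two_step.mean() - one_step.mean()) < 3 * se_mean
        assert abs(two_step.var() - one_step.var()) / one_step.var() < 0.15

    def test_invalid_fraction(self):
        sample = simulate_sample(subclonal_config())
        with pytest.raises(ValueError):
            downsample_sample(sample, 0.0, seed=1)
        with pytest.raises(ValueError):
            downsample_sample(sample, 1.2, seed=1)


class TestCohort:
    def test_degenerate_ranges(self):
        base = subclonal_config(n_clonal=10, n_subclonal=90)
        cohort = simulate_cohort(base, 10, (100, 100), (1, 1), seed=3)
        assert len(cohort) == 10
        assert all(s.clonal_fraction == 1.0 for s in cohort)
        cohort0 = simulate_cohort(base, 5, (100, 100), (0, 0), seed=3)
        assert all(s.clonal_fraction == 0.0 for s in cohort0)

    def test_uniform_clonal_fraction_split(self):
        base = subclonal_config(n_clonal=10, n_subclonal=90)
        cohort = simulate_cohort(base, 100, (50, 400), (0, 1), seed=4)
        high = sum(s.clonal_fraction > 0.5 for s in cohort)
        se = math.sqrt(0.25 / 100)
        assert abs(high / 100 - 0.5) < 3 * se

    def test_reproducible_and_validated(self):
        base = subclonal_config()
        a = simulate_cohort(base, 3, (50, 100), (0, 1), seed=9)
        b = simulate_cohort(base, 3, (50, 100), (0, 1), seed=9)
        assert all(x.sites == y.sites for x, y in zip(a, b))
        with pytest.raises(ValueError):
            simulate_cohort(base, 1, (50, 100), (0, 1), seed=9)
        with pytest.raises(ValueError):
            simulate_cohort(base, 5, (100, 50), (0, 1), seed=9)


class TestSerialization:
    def test_tsv_round_trip_is_bit_exact(self, tmp_path):
        sample = simulate_sample(subclonal_config(n_clonal=7, n_subclonal=93, purity=0.7))
        path = tmp_path / "sample.tsv"
        write_sample_tsv(sample, path)
        loaded = read_sample_tsv(path)
        assert loaded.sites == sample.sites
        assert loaded.purity == sample.purity
        assert loaded.clonal_fraction == sample.clonal_fraction
        assert loaded.region_size_mb == sample.region_size_mb
        assert loaded.seed == sample.seed

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "# purity=1.0\n# clonal_fraction=0.0\n# region_size_mb=1.0\n# seed=0\n"
            "site_id\ttrue_vaf\tdepth\talt_count\tis_clonal\n"
            "site_0\toops\t100\t3\t0\n"
        )
        with pytest.raises(ValueError, match=":6"):
            read_sample_tsv(path)

    def test_empty_sample_cannot_exist(self):
        with pytest.raises(ValueError):
            TumourSample([], 1.0, 0.0, 1.0, 0)

    def test_vcf_records_and_ad_consistency(self, tmp_path):
        sample = simulate_sample(subclonal_config(n_clonal=1, n_subclonal=2))
        path = tmp_path / "sample.vcf"
        write_sample_vcf(sample, path)
        lines = path.read_text().splitlines()
        records = [l for l in lines if not l.startswith("#")]
        assert len(records) == 3
        assert lines[0] == "##fileformat=VCFv4.2"
        for rec, site in zip(records, sample.sites):
            fields = rec.split("\t")
            gt, ad, dp = fields[9].split(":")
            ref_reads, alt_reads = map(int, ad.split(","))
            assert ref_reads + alt_reads == int(dp) == site.depth
            assert alt_reads == site.alt_count

    def test_vcf_parses_with_cyvcf2(self, tmp_path):
        cyvcf2 = pytest.importorskip("cyvcf2")
        sample = simulate_sample(subclonal_config(n_clonal=2, n_subclonal=8))
        path = tmp_path / "sample.vcf"
        write_sample_vcf(sample, path)
        variants = list(cyvcf2.VCF(str(path)))
        assert len(variants) == 10
        v = variants[0]
        assert v.INFO.get("TRUE_VAF") == pytest.approx(
            sample.sites[0].true_vaf, rel=1e-5
        )
        assert v.format("DP")[0][0] == sample.sites[0].depth
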