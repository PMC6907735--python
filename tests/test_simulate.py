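"""Generator realism, oracle correctness, and the error-report sweep."""

import dataclasses

import numpy as np
import pytest

from sumpc import (
    Analysis,
    PanelError,
    SimConfig,
    ols_oracle,
    simulate_dataset,
    summarize_raw,
    validate,
)
from sumpc.moments import ModelSpec
from sumpc.simulate import read_raw, write_raw


class TestGenerator:
    def test_same_seed_identical(self, small_config):
        a = simulate_dataset(small_config)
        b = simulate_dataset(small_config)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.phenotypes, b.phenotypes)
        assert np.array_equal(a.age, b.age)

    def test_different_seed_differs(self, small_config, small_raw):
        other = simulate_dataset(dataclasses.replace(small_config, seed=99))
        assert not np.array_equal(other.genotypes, small_raw.genotypes)

    def test_null_model_identity_residuals(self):
        cfg = SimConfig(
            n_subjects=2000, n_snps=20, n_causal=2,
            snp_effects=((0.0, 0.0),) * 3,
            age_effects=(0.0, 0.0, 0.0), sex_effects=(0.0, 0.0, 0.0),
            residual_cov=tuple(map(tuple, np.eye(3))), seed=5,
        )
        raw = simulate_dataset(cfg)
        cov = np.cov(raw.phenotypes, rowvar=False, ddof=1)
        # sampling SEs for iid N(0,1): sqrt(2/n) for variances, sqrt(1/n)
        # for covariances; allow 4 SEs entrywise
        dev = np.abs(cov - np.eye(3))
        off = ~np.eye(3, dtype=bool)
        assert np.max(np.diag(dev)) < 4.0 * np.sqrt(2.0 / 2000)
        assert np.max(dev[off]) < 4.0 / np.sqrt(2000)

    def test_mafs_respect_bounds(self, small_raw):
        lo, hi = small_raw.config.maf_bounds
        assert small_raw.mafs.min() >= lo and small_raw.mafs.max() <= hi

    def test_genotypes_are_dosages(self, small_raw):
        assert set(np.unique(small_raw.genotypes)) <= {0, 1, 2}

    def test_hwe_moment_relation(self):
        # sample genotype variance against 2p(1-p): slope ~ 1 under HWE
        raw = simulate_dataset(SimConfig(n_subjects=2000, n_snps=500, seed=3))
        G = raw.genotypes.astype(float)
        p_hat = G.mean(axis=0) / 2
        x = 2 * p_hat * (1 - p_hat)
        slope = np.polyfit(x, G.var(axis=0, ddof=1), 1)[0]
        assert abs(slope - 1.0) < 0.05

    def test_default_correlations_near_targets(self):
        # lighter analogue of the calibration check: causal effects and
        # residual structure set the correlations, not the null SNP count
        cfg = SimConfig(n_snps=100, n_replicates=5, seed=2)
        seeds = np.random.SeedSequence(cfg.seed).spawn(5)
        cors = []
        for ss in seeds:
            raw = simulate_dataset(cfg, np.random.default_rng(ss))
            c = np.corrcoef(raw.phenotypes, rowvar=False)
            cors.append([c[0, 1], c[0, 2], c[1, 2]])
        mean = np.mean(cors, axis=0)
        assert mean == pytest.approx([0.30, -0.08, 0.07], abs=0.1)

    def test_invalid_config_rejected(self):
        with pytest.raises(Exception):
            SimConfig(n_causal=5)  # effect matrix shape no longer matches
        with pytest.raises(Exception):
            SimConfig(maf_bounds=(0.0, 0.5))


class TestSummarize:
    def test_slopes_match_closed_form_simple_regression(self, small_raw, exact_panel):
        g = small_raw.column("snp000044")
        y = small_raw.column("y3")
        b = np.cov(g, y, ddof=1)[0, 1] / g.var(ddof=1)
        rec = exact_panel.assoc_record("snp000044", "y3")
        assert rec.slope == pytest.approx(b, rel=1e-12)
        assert rec.intercept == pytest.approx(y.mean() - b * g.mean(), rel=1e-12)

    def test_monomorphic_snps_excluded(self):
        cfg = SimConfig(n_subjects=50, n_snps=100, seed=7)
        raw = simulate_dataset(cfg)
        raw.genotypes[:, 60] = 0
        panel = summarize_raw(raw)
        assert "snp000061" not in panel.snp_ids
        assert len(panel.snps) == 99

    def test_exact_mode_carries_sample_moments(self, small_raw, exact_panel):
        s = exact_panel.snp("snp000010")
        g = small_raw.column("snp000010")
        # axis-wise and per-column reductions differ in summation order only
        assert s.geno_mean == pytest.approx(g.mean(), rel=1e-13)
        assert s.geno_var == pytest.approx(g.var(ddof=1), rel=1e-12)

    def test_hwe_mode_omits_moments(self, hwe_panel):
        s = hwe_panel.snp("snp000010")
        assert s.geno_mean is None and s.geno_var is None


class TestOracle:
    def test_exact_line_zero_residual(self):
        cfg = SimConfig(n_subjects=50, n_snps=12, seed=1)
        raw = simulate_dataset(cfg)
        raw.phenotypes[:, 0] = 2.0 + 3.0 * raw.column("snp000001")
        res = ols_oracle(raw, ModelSpec(response=(("y1", 1.0),), snp_id="snp000001"))
        assert res.coefficients == pytest.approx([2.0, 3.0], abs=1e-10)
        assert res.standard_errors == pytest.approx([0.0, 0.0], abs=1e-9)

    def test_intercept_only_is_mean(self, small_raw):
        res = ols_oracle(small_raw, ModelSpec(response=(("y2", 1.0),)))
        assert res.coefficients[0] == pytest.approx(small_raw.column("y2").mean(),
                                                    rel=1e-12)

    def test_agrees_with_statsmodels(self, small_raw):
        # independent reference implementation on the same design
        import statsmodels.api as sm

        spec = ModelSpec(response=(("y1", 1.0),), covariates=("age", "sex"),
                         snp_id="snp000002")
        ours = ols_oracle(small_raw, spec)
        X = sm.add_constant(np.column_stack([small_raw.column(p)
                                             for p in spec.predictors]))
        ref = sm.OLS(small_raw.column("y1"), X).fit()
        assert ours.coefficients == pytest.approx(ref.params, rel=1e-10)
        assert ours.standard_errors == pytest.approx(ref.bse, rel=1e-10)
        assert ours.p_values == pytest.approx(ref.pvalues, rel=1e-8, abs=1e-12)

    def test_rank_deficiency_rejected(self, small_raw):
        raw = dataclasses.replace(small_raw)
        raw.phenotypes = small_raw.phenotypes.copy()
        raw.age = np.ones_like(small_raw.age)  # collinear with the intercept
        with pytest.raises(Exception):
            ols_oracle(raw, ModelSpec(response=(("y1", 1.0),), covariates=("age",)))


@pytest.fixture(scope="module")
def report():
    cfg = SimConfig(n_subjects=200, n_snps=60, n_replicates=2, seed=13)
    analyses = [
        Analysis(name="y1", weights=(1.0, 0.0, 0.0)),
        Analysis(name="pc1", component=1),
    ]
    return validate(cfg, analyses, cov_source="true")


class TestValidate:
    def test_exact_mode_errors_at_rounding_level(self, report):
        per = report.per_snp
        scale = per["oracle_slope"].abs().max()
        assert per["slope"].abs().max() < 1e-10 * max(scale, 1.0)
        assert per["se"].abs().max() < 1e-10

    def test_summary_recomputable_from_per_snp_table(self, report):
        # error-metric algebra: the stored summaries are exactly the
        # aggregates of the per-SNP error table
        for row in report.per_replicate.itertuples():
            sub = report.per_snp[
                (report.per_snp.analysis == row.analysis)
                & (report.per_snp.replicate == row.replicate)
            ][row.metric].to_numpy()
            assert row.mean_error == sub.mean()
            assert row.intra_genomic_variance == sub.var(ddof=1)

    def test_summary_max_geq_mean(self, report):
        s = report.summary
        assert (s.max_intra_genomic_variance >= s.mean_intra_genomic_variance - 1e-30).all()
        assert (s.max_abs_mean_error >= s.mean_error.abs() - 1e-30).all()

    def test_determinism(self):
        cfg = SimConfig(n_subjects=120, n_snps=30, n_replicates=1, seed=4)
        analyses = [Analysis(name="y1", weights=(1.0, 0.0, 0.0))]
        a = validate(cfg, analyses)
        b = validate(cfg, analyses)
        assert a.per_snp.equals(b.per_snp)

    def test_no_analyses_rejected(self):
        with pytest.raises(PanelError):
            validate(SimConfig(n_subjects=100, n_snps=10, seed=1), [])

    def test_zero_snps_rejected(self):
        with pytest.raises(PanelError):
            validate(
                SimConfig(n_subjects=100, n_snps=10, seed=1),
                [Analysis(name="y1", weights=(1.0, 0.0, 0.0))],
                n_fit_snps=0,
            )


class TestRawRoundTrip:
    def test_write_read(self, tmp_path):
        cfg = SimConfig(n_subjects=30, n_snps=12, seed=2)
        raw = simulate_dataset(cfg)
        write_raw(raw, tmp_path)
        back = read_raw(tmp_path)
        assert np.array_equal(back.genotypes, raw.genotypes)
        assert np.array_equal(back.phenotypes, raw.phenotypes)
        assert back.snp_ids == raw.snp_ids
        assert back.config == cfg
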