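import numpy as np
import pandas as pd
import pytest

from empanet import association as assoc
from empanet.synthetic import (
    CohortConfig,
    cohort_frame,
    generate_cohort,
    null_metric_table,
    plant_effect,
    planted_partition_labels,
)
from empanet.validation import association_replicate


def make_table(beta=3.2, beta_sex=0.0, n_subjects=24, n_nodes=12, seed=0, **sds):
    defaults = dict(subject_sd=1.0, node_slope_sd=0.5, group_sd=0.5, residual_sd=1.0)
    defaults.update(sds)
    cfg = CohortConfig(
        n_subjects=n_subjects, n_nodes=n_nodes, n_modules_planted=3,
        planted_beta=beta, planted_beta_sex=beta_sex, seed=seed, **defaults,
    )
    records = generate_cohort(cfg)
    table = plant_effect(null_metric_table(records, cfg), records, cfg, seed=seed + 1)
    nodes = np.flatnonzero(planted_partition_labels(cfg) == 0)
    long = assoc.build_long_table(
        table, cohort_frame(records), 1.0, nodes, "degree", "ve"
    )
    return long, cfg, records


class TestBuildLongTable:
    def test_row_count_is_nodes_times_subjects(self):
        long, cfg, _ = make_table(n_subjects=20, n_nodes=15)
        assert len(long) == 20 * 5  # 15 nodes in 3 modules -> 5 per module

    def test_missing_trait_subjects_excluded(self):
        long, cfg, records = make_table(n_subjects=20)
        table = plant_effect(null_metric_table(records, cfg), records, cfg)
        cohort = cohort_frame(records)
        cohort.loc[cohort.index[:3], "ve_t"] = np.nan
        nodes = np.flatnonzero(planted_partition_labels(cfg) == 0)
        out = assoc.build_long_table(table, cohort, 1.0, nodes, "degree", "ve")
        assert out["subject_id"].nunique() == 17
        assert len(out) == 17 * len(nodes)

    def test_empty_module_rejected(self):
        long, cfg, records = make_table()
        with pytest.raises(ValueError, match="empty module"):
            assoc.build_long_table(
                null_metric_table(records, cfg), cohort_frame(records),
                1.0, np.array([]), "degree", "ve",
            )

    def test_sex_contrast_coding(self):
        long, _, _ = make_table()
        assert set(long["sex_code"].unique()) <= {-0.5, 0.5}
        assert long.loc[long.sex == "female", "sex_code"].eq(-0.5).all()


class TestFitModuleModel:
    def test_exact_recovery_without_noise(self):
        long, _, _ = make_table(
            beta=3.2, subject_sd=0.0, node_slope_sd=0.0, group_sd=0.0,
            residual_sd=0.0,
        )
        fit = assoc.fit_module_model(long, assoc.ModelSpec("degree", "ve"))
        assert fit.beta_trait.estimate == pytest.approx(3.2, abs=1e-6)

    def test_planted_effect_recovered_with_noise(self):
        fit = association_replicate(seed=123, beta=3.2)
        assert fit.beta_trait.estimate == pytest.approx(3.2, abs=0.8)
        assert fit.beta_trait.p < 0.01
        assert fit.beta_trait.ci_low <= fit.beta_trait.estimate <= fit.beta_trait.ci_high

    def test_partial_slopes_follow_contrast_algebra(self):
        fit = association_replicate(seed=5, beta=3.2, beta_sex=-6.4)
        b, bi = fit.beta_trait.estimate, fit.beta_sex_interaction.estimate
        assert fit.partial_beta_by_sex["female"] == pytest.approx(b - 0.5 * bi)
        assert fit.partial_beta_by_sex["male"] == pytest.approx(b + 0.5 * bi)

    def test_planted_interaction_detected(self):
        # male partial slope planted at 0, female at 6.4
        fits = [
            association_replicate(seed=200 + s, beta=3.2, beta_sex=-6.4,
                                  n_subjects=60)
            for s in range(3)
        ]
        female = np.mean([f.partial_beta_by_sex["female"] for f in fits])
        male = np.mean([f.partial_beta_by_sex["male"] for f in fits])
        assert female == pytest.approx(6.4, abs=1.0)
        assert male == pytest.approx(0.0, abs=1.0)

    def test_blups_centered_and_track_planted_slopes(self):
        cfg = CohortConfig(
            n_subjects=60, n_nodes=45, n_modules_planted=3, planted_beta=3.2,
            node_slope_sd=1.0, seed=31,
        )
        records = generate_cohort(cfg)
        rng = np.random.default_rng(cfg.seed + 1)
        node_slopes = rng.normal(0.0, cfg.node_slope_sd, cfg.n_nodes)
        table = plant_effect(
            null_metric_table(records, cfg), records, cfg, seed=cfg.seed + 1
        )
        nodes = np.flatnonzero(planted_partition_labels(cfg) == 0)
        long = assoc.build_long_table(
            table, cohort_frame(records), 1.0, nodes, "degree", "ve"
        )
        fit = assoc.fit_module_model(long, assoc.ModelSpec("degree", "ve"))
        assert abs(fit.blups.mean()) < 0.15
        rho = np.corrcoef(fit.blups.loc[nodes], node_slopes[nodes])[0, 1]
        assert rho >= 0.5

    def test_single_scan_group_drops_term_with_warning(self):
        long, _, _ = make_table()
        long["scan_group"] = "G1"
        with pytest.warns(RuntimeWarning, match="scanning groups"):
            fit = assoc.fit_module_model(long, assoc.ModelSpec("degree", "ve"))
        assert "scangroup" in fit.dropped_terms

    def test_too_few_subjects_rejected(self):
        long, _, _ = make_table(n_subjects=12)
        small = long[long.subject_id.isin(long.subject_id.unique()[:5])]
        with pytest.raises(ValueError, match="10 subjects"):
            assoc.fit_module_model(small, assoc.ModelSpec("degree", "ve"))


class TestResidualScreen:
    def test_alpha_zero_keeps_everything(self):
        long, _, _ = make_table(seed=3)
        first, refit, excluded = assoc.residual_screen(
            long, assoc.ModelSpec("degree", "ve"), alpha_ad=0.0
        )
        assert excluded == []
        assert refit is first

    def test_gaussian_residuals_rarely_excluded(self):
        # cohorts large enough that BLUP estimation error does not induce
        # visible scale-mixing in the conditional residuals
        n_tested = n_excluded = 0
        for seed in range(8):
            long, _, _ = make_table(seed=400 + seed, n_subjects=60)
            _, _, excluded = assoc.residual_screen(
                long, assoc.ModelSpec("degree", "ve")
            )
            n_tested += long["node_id"].nunique()
            n_excluded += len(excluded)
        assert n_excluded / n_tested < 0.15  # ~5% nominal

    def test_heavy_tailed_node_usually_caught(self):
        caught = 0
        n_seeds = 10
        for seed in range(n_seeds):
            long, _, _ = make_table(seed=600 + seed, n_subjects=60, n_nodes=24)
            bad_node = long["node_id"].unique()[0]
            rng = np.random.default_rng(seed)
            mask = long["node_id"] == bad_node
            long.loc[mask, "y"] += rng.standard_t(2, size=int(mask.sum())) * 2
            _, _, excluded = assoc.residual_screen(
                long, assoc.ModelSpec("degree", "ve")
            )
            caught += bad_node in excluded
        assert caught / n_seeds >= 0.8

    def test_anderson_darling_matches_reference_implementation(self):
        # frozen oracle values from R nortest::ad.test on the same draws
        rng = np.random.default_rng(42)
        x_norm = rng.standard_normal(60).round(6)
        x_exp = rng.exponential(1.0, 60).round(6)
        assert assoc.anderson_darling_pvalue(x_norm) == pytest.approx(0.7705, abs=2e-4)
        assert assoc.anderson_darling_pvalue(x_exp) == pytest.approx(2.996e-5, rel=2e-3)


class TestFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(assoc.fdr_correct([0.03]), [0.03])

    def test_hand_computed_worked_example(self):
        np.testing.assert_allclose(
            assoc.fdr_correct([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(assoc.fdr_correct([0.2, 0.2, 0.2]), 0.2)

    def test_monotone_in_ranked_p(self, rng):
        p = rng.uniform(size=20)
        q = assoc.fdr_correct(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assoc.fdr_correct([0.5, 1.5])


class TestCrossGamma:
    def test_duplicated_tables_match_single_fit(self):
        long, _, _ = make_table(seed=9)
        single = assoc.fit_module_model(long, assoc.ModelSpec("degree", "ve"))
        t1 = long.copy()
        t2 = long.copy()
        t1["gamma"], t2["gamma"] = 1.0, 1.5
        stacked = assoc.cross_gamma_model([t1, t2], assoc.ModelSpec("degree", "ve"))
        assert stacked.beta_trait.estimate == pytest.approx(
            single.beta_trait.estimate, abs=1e-4
        )

    def test_constant_effect_matches_per_gamma_mean(self):
        long, cfg, records = make_table(seed=21, n_subjects=40)
        table = plant_effect(
            null_metric_table(records, cfg, gammas=(1.0, 1.5)), records, cfg,
            seed=77,
        )
        cohort = cohort_frame(records)
        nodes = np.flatnonzero(planted_partition_labels(cfg) == 0)
        tables, betas = [], []
        for g in (1.0, 1.5):
            t = assoc.build_long_table(table, cohort, g, nodes, "degree", "ve")
            tables.append(t)
            betas.append(
                assoc.fit_module_model(t, assoc.ModelSpec("degree", "ve"))
                .beta_trait.estimate
            )
        pooled = assoc.cross_gamma_model(tables, assoc.ModelSpec("degree", "ve"))
        assert pooled.beta_trait.estimate == pytest.approx(
            np.mean(betas), rel=0.10
        )

    def test_single_table_falls_back_with_warning(self):
        long, _, _ = make_table(seed=13)
        with pytest.warns(RuntimeWarning, match="single resolution"):
            fit = assoc.cross_gamma_model([long], assoc.ModelSpec("degree", "ve"))
        assert fit.n_subjects == long["subject_id"].nunique()


class TestICECurves:
    def test_null_model_curves_flat(self):
        long, _, _ = make_table(
            beta=0.0, subject_sd=0.0, node_slope_sd=0.0, group_sd=0.0,
            residual_sd=0.2, seed=15,
        )
        fit = assoc.fit_module_model(long, assoc.ModelSpec("degree", "ve"))
        curves = ice = assoc.ice_curves(fit, long, np.linspace(-2, 2, 5))
        slopes = curves.groupby("subject_id").apply(
            lambda d: np.polyfit(d.trait, d.predicted, 1)[0], include_groups=False
        )
        assert np.abs(slopes).max() < 0.3

    def test_mean_curve_slope_equals_fixed_beta(self):
        long, _, _ = make_table(beta=3.2, seed=16)
        fit = assoc.fit_module_model(long, assoc.ModelSpec("degree", "ve"))
        curves = assoc.ice_curves(fit, long, np.linspace(-2, 2, 7))
        slopes = curves.groupby("subject_id").apply(
            lambda d: np.polyfit(d.trait, d.predicted, 1)[0], include_groups=False
        )
        sex_codes = long.drop_duplicates("subject_id").set_index("subject_id")["sex_code"]
        expected = (
            fit.beta_trait.estimate
            + fit.beta_sex_interaction.estimate * sex_codes.loc[slopes.index].mean()
            + fit.blups.mean()
        )
        assert slopes.mean() == pytest.approx(expected, abs=1e-8)

    def test_positive_beta_gives_positive_slopes(self):
        fit = association_replicate(seed=17, beta=3.2)
        long, _, _ = make_table(seed=17)  # same covariate structure
        curves = assoc.ice_curves(fit, long, np.array([-1.0, 1.0]))
        inc = curves.groupby("subject_id").apply(
            lambda d: d.predicted.iloc[-1] > d.predicted.iloc[0],
            include_groups=False,
        )
        assert inc.mean() > 0.9
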