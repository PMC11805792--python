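import numpy as np
import pandas as pd
import pytest

from intersim import (ConfigurationError, ExperimentConfig, ParameterGrid,
                      aggregate_power, aggregate_tables, count_analyses,
                      enumerate_conditions, expected_misspecified, f2_survey,
                      f2_survey_summary, run_cell, run_conditions, run_grid)
from intersim.experiment import population_spec


@pytest.fixture
def table2_grid():
    # the worked-example cell crossed over all nine product-term weights
    return ParameterGrid(noise_levels=(0.65,), correlations=(0.0001,),
                         beta1_values=(1.0,), beta2_values=(1.0,))


class TestRunCell:
    def test_record_count(self, tiny_grid):
        config = ExperimentConfig(grid=tiny_grid, population_size=2000,
                                  reps=2, sample_sizes=(25, 100), master_seed=1)
        cond = enumerate_conditions(tiny_grid)[0]
        records = run_cell(cond, config)
        assert len(records) == 4  # 2 reps x 2 sample sizes
        assert records.attrs["skipped"] == []

    def test_deterministic_output(self, tiny_config, tiny_grid, tmp_path):
        cond = enumerate_conditions(tiny_grid)[0]
        a = run_cell(cond, tiny_config)
        b = run_cell(cond, tiny_config)
        pd.testing.assert_frame_equal(a, b)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_matches_reference_fit_path(self, tiny_grid):
        # the batched QR kernel agrees with the per-sample reference API
        from intersim import (INTERACTION, SIMPLE, draw_sample, fit_ols,
                              generalization_record, generate_population,
                              loocv_r2)
        from intersim.experiment import population_seed, replicate_seed
        config = ExperimentConfig(grid=tiny_grid, population_size=3000, reps=3,
                                  sample_sizes=(30, 80), master_seed=5,
                                  loocv=True)
        cond = enumerate_conditions(tiny_grid)[0]
        records = run_cell(cond, config)
        pop = generate_population(population_spec(cond, 3000),
                                  population_seed(5, cond.index))
        for n_index, n in enumerate(config.sample_sizes):
            for rep in range(config.reps):
                s = draw_sample(pop, n, replicate_seed(5, cond.index, n_index, rep),
                                replicate_index=rep)
                fit_s = fit_ols(s, SIMPLE)
                fit_i = fit_ols(s, INTERACTION)
                row = records[(records.n == n) & (records.replicate == rep)].iloc[0]
                np.testing.assert_allclose(
                    [row.b0_simple, row.b1_simple, row.b2_simple],
                    fit_s.coefficients, rtol=1e-9)
                np.testing.assert_allclose(
                    [row.se_b0_inter, row.se_b1_inter, row.se_b2_inter,
                     row.se_b3_inter], fit_i.standard_errors, rtol=1e-9)
                np.testing.assert_allclose(
                    [row.p_b0_simple, row.p_b1_simple, row.p_b2_simple],
                    fit_s.p_values, rtol=1e-9, atol=1e-12)
                assert row.r2s_inter == pytest.approx(fit_i.r2_sample, abs=1e-12)
                rec = generalization_record(fit_i, pop)
                assert row.r2p_inter == pytest.approx(rec.r2_p, abs=1e-9)
                assert row.overfit_inter == pytest.approx(rec.overfit, abs=1e-9)
                assert row.r2cv_inter == pytest.approx(
                    loocv_r2(s, INTERACTION).r2_cv, abs=1e-9)

    def test_mean_b2_matches_expected_misspecified(self, tiny_grid):
        # the misspecified Z coefficient averages to the closed form
        config = ExperimentConfig(grid=tiny_grid, population_size=50_000,
                                  reps=300, sample_sizes=(1000,), master_seed=2)
        cond = enumerate_conditions(tiny_grid)[0]
        records = run_cell(cond, config)
        ee = expected_misspecified(population_spec(cond, config.population_size))
        mc_se = records.b2_simple.std(ddof=1) / np.sqrt(len(records))
        assert abs(records.b2_simple.mean() - ee.b_e2) < 3 * mc_se + 1e-3

    def test_centering_flag(self, tiny_grid):
        base = ExperimentConfig(grid=tiny_grid, population_size=2000, reps=3,
                                sample_sizes=(50,), master_seed=4)
        centered = ExperimentConfig(grid=tiny_grid, population_size=2000,
                                    reps=3, sample_sizes=(50,), master_seed=4,
                                    centering=True)
        cond = enumerate_conditions(tiny_grid)[0]
        ru = run_cell(cond, base)
        rc = run_cell(cond, centered)
        # product-term row and every R2 measure invariant; intercept not
        np.testing.assert_allclose(ru.b3_inter, rc.b3_inter, atol=1e-10)
        np.testing.assert_allclose(ru.se_b3_inter, rc.se_b3_inter, atol=1e-10)
        np.testing.assert_allclose(ru.r2s_inter, rc.r2s_inter, atol=1e-12)
        np.testing.assert_allclose(ru.r2p_inter, rc.r2p_inter, atol=1e-10)
        assert not np.allclose(ru.b0_inter, rc.b0_inter)

    def test_dr2s_nonnegative(self, tiny_grid):
        config = ExperimentConfig(grid=tiny_grid, population_size=2000,
                                  reps=50, sample_sizes=(25,), master_seed=6)
        records = run_cell(enumerate_conditions(tiny_grid)[0], config)
        assert (records.dr2s >= 0).all()
        np.testing.assert_allclose(records.doverfit,
                                   records.dr2s - records.dr2p, atol=1e-12)


class TestAggregateTables:
    def _fixture_records(self):
        rng = np.random.default_rng(0)
        n = 100
        return pd.DataFrame({
            "shape": ["synergistic"] * 50 + ["none"] * 50,
            "noise_level": [0.65] * n,
            "n": [25] * n,
            "dr2s": np.abs(rng.normal(size=n)),
            "dr2p": rng.normal(size=n),
            "doverfit": rng.normal(size=n),
        })

    def test_quantiles_match_brute_force(self):
        records = self._fixture_records()
        table = aggregate_tables(records, "shape_noise")
        sub = records[records["shape"] == "synergistic"]["dr2p"].to_numpy()
        row = table[table["shape"] == "synergistic"].iloc[0]
        # brute-force quantile via sorted linear interpolation
        srt = np.sort(sub)
        for q, col in [(0.1, "dr2p_q10"), (0.5, "dr2p_mdn"), (0.9, "dr2p_q90")]:
            pos = q * (len(srt) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            brute = srt[lo] + (pos - lo) * (srt[hi] - srt[lo])
            assert row[col] == pytest.approx(brute, abs=1e-12)
        assert row["dr2p_pct_neg"] == pytest.approx(100 * (sub < 0).mean())
        assert row["k"] == 50

    def test_all_zero_deltas(self):
        records = self._fixture_records()
        for col in ("dr2s", "dr2p", "doverfit"):
            records[col] = 0.0
        table = aggregate_tables(records, "shape_n")
        assert (table.filter(like="_q10") == 0).all().all()
        assert (table.filter(like="_mdn") == 0).all().all()
        assert (table.filter(like="_pct_neg") == 0).all().all()

    def test_quantile_ordering_invariant(self):
        table = aggregate_tables(self._fixture_records(), "shape_noise")
        for m in ("dr2s", "dr2p", "doverfit"):
            assert (table[f"{m}_q10"] <= table[f"{m}_mdn"]).all()
            assert (table[f"{m}_mdn"] <= table[f"{m}_q90"]).all()

    def test_bad_group_by(self):
        with pytest.raises(ConfigurationError):
            aggregate_tables(self._fixture_records(), "bogus")


class TestAggregatePower:
    def test_noiseless_full_power(self):
        grid = ParameterGrid(noise_levels=(0.0,), correlations=(0.25,),
                             beta1_values=(1.0,), beta2_values=(-1.0,),
                             beta3_values=(0.5,))
        config = ExperimentConfig(grid=grid, population_size=2000, reps=10,
                                  sample_sizes=(50,), master_seed=8)
        records = run_cell(enumerate_conditions(grid)[0], config)
        power = aggregate_power(records, alpha=0.05)
        inter = power[power.model == "inter"].set_index("coefficient")
        for coef in ("b1", "b2", "b3"):
            assert inter.loc[coef, "pct_significant"] == 100.0

    def test_power_increases_with_n_under_correct_model(self, table2_grid):
        config = ExperimentConfig(grid=table2_grid, population_size=20_000,
                                  reps=150, sample_sizes=(25, 100, 1000),
                                  master_seed=9)
        conds = [c for c in enumerate_conditions(table2_grid)
                 if c.betas.beta3 == -1.0]
        records = run_cell(conds[0], config)
        power = aggregate_power(records, alpha=0.05)
        b3 = power[(power.model == "inter") & (power.coefficient == "b3")]
        by_n = b3.sort_values("n")["pct_significant"].to_numpy()
        assert (np.diff(by_n) >= 0).all()
        assert by_n[-1] > 95


class TestF2Survey:
    def test_no_interaction_cells_near_zero(self):
        grid = ParameterGrid(noise_levels=(1.0,), correlations=(0.25, 0.75),
                             beta1_values=(1.0, -0.5), beta2_values=(1.0,),
                             beta3_values=(0.0,))
        survey = f2_survey(grid, 20_000, seed=3)
        assert np.all(np.abs(survey["f2"]) < 1e-3)
        assert np.all(np.abs(survey["f2_rel_simple"]) < 1e-3)

    def test_summary_digest(self):
        grid = ParameterGrid(noise_levels=(0.65, 3.0), correlations=(0.25,),
                             beta1_values=(1.0,), beta2_values=(1.0,),
                             beta3_values=(-1.0, 0.0))
        survey = f2_survey(grid, 10_000, seed=4)
        digest = f2_survey_summary(survey)
        assert 0 <= digest["pct_gt_0.5"] <= 100
        assert digest["p5"] <= digest["p95"]
        # Cohen's normalization has the heavier tail by construction
        assert f2_survey_summary(survey, "f2")["p95"] >= digest["p95"]


class TestRunGrid:
    def test_manifest_counts_and_determinism(self, tmp_path):
        grid = ParameterGrid(noise_levels=(0.65,), correlations=(0.25,),
                             beta1_values=(1.0, -1.0), beta2_values=(1.0,),
                             beta3_values=(-1.0, 0.0, 1.0))
        config = ExperimentConfig(grid=grid, population_size=1500, reps=10,
                                  sample_sizes=(25, 100), master_seed=12)
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        man_a = run_grid(config, out_a, write_records=True, progress=False)
        man_b = run_grid(config, out_b, write_records=True, progress=False)
        assert man_a.n_conditions == 6
        assert man_a.n_records == 6 * 10 * 2
        assert man_a.n_skipped == 0
        for name in ("summary_by_noise", "summary_by_n", "power",
                     "bias_table", "records"):
            assert (out_a / f"{name}.csv").exists()
            assert (out_a / f"{name}.csv").read_bytes() == \
                (out_b / f"{name}.csv").read_bytes()
        assert man_a.files == man_b.files

    def test_k_matches_combinatorics(self, tmp_path):
        grid = ParameterGrid(noise_levels=(0.65, 1.0), correlations=(0.25,),
                             beta1_values=(1.0,), beta2_values=(1.0, -1.0),
                             beta3_values=(-0.5, 0.0))
        config = ExperimentConfig(grid=grid, population_size=1500, reps=5,
                                  sample_sizes=(25, 50), master_seed=13)
        records = run_conditions(enumerate_conditions(grid), config)
        table = aggregate_tables(records, "shape_noise")
        expected = count_analyses(grid, reps=5, sample_sizes=(25, 50),
                                  group_by="shape_noise")
        merged = table.merge(expected, on=["shape", "noise_level"],
                             suffixes=("", "_expected"))
        assert (merged["k"] == merged["k_expected"]).all()

    def test_round_trip_of_records_csv(self, tmp_path, tiny_config, tiny_grid):
        cond = enumerate_conditions(tiny_grid)[0]
        records = run_cell(cond, tiny_config)
        path = tmp_path / "records.csv"
        records.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(records.reset_index(drop=True), back,
                                      check_exact=False, rtol=1e-12)
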