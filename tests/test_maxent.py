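"""MaxEnt mechanics: feature arithmetic, the Gibbs normalization, the 1-D
objective oracle, the logistic output closed form, AUC pair counting, and
variable-importance behaviour on species with known drivers."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from flywaysdm.maxent import (
    FeatureDef,
    FeatureSet,
    auc,
    build_features,
    evaluate_subsample,
    fit,
    jackknife_gain,
    logistic_scores,
    percent_contribution,
    predict_logistic,
    sample_background,
)
from flywaysdm.raster import Grid, RasterLayer, RasterStack
from flywaysdm.synthetic import TrueGroup, make_true_suitability, sample_occurrences


def _simple_feature_set():
    return FeatureSet(
        ["a"], [FeatureDef("a", "linear")], {"a": 2.0}, {"a": 4.0}
    )


class TestFeatures:
    def test_linear_minmax_scaling(self):
        fs = _simple_feature_set()
        assert fs.transform(np.array([[3.0]]))[0, 0] == pytest.approx(0.5)

    def test_quadratic_of_scaled_value(self):
        fs = FeatureSet(["a"], [FeatureDef("a", "quadratic")], {"a": 2.0}, {"a": 4.0})
        assert fs.transform(np.array([[3.0]]))[0, 0] == pytest.approx(0.25)

    def test_hinge_definition(self):
        fs = FeatureSet(["a"], [FeatureDef("a", "hinge", 0.6)], {"a": 0.0}, {"a": 1.0})
        assert fs.transform(np.array([[0.8]]))[0, 0] == pytest.approx(0.5)
        assert fs.transform(np.array([[0.5]]))[0, 0] == 0.0

    def test_constant_variables_dropped(self, env_stack):
        grid = env_stack.grid
        flat = RasterLayer(grid, "flat", np.ones(grid.shape))
        stack = RasterStack([env_stack["env1"], flat])
        rng = np.random.default_rng(0)
        bg = sample_background(grid, np.ones(grid.shape, bool), 500, rng)
        fs = build_features(stack, bg, bg, ("linear",))
        assert fs.variables == ["env1"]

    def test_all_constant_stack_errors(self):
        grid = Grid(8, 8, 1.0)
        stack = RasterStack([RasterLayer(grid, "c", np.full(grid.shape, 3.0))])
        bg = (np.arange(8), np.arange(8))
        with pytest.raises(ValueError, match="constant"):
            build_features(stack, bg, bg, ("linear",))


class TestFit:
    def test_background_distribution_normalizes(self, env_stack, structured_species):
        _, _, occ = structured_species
        rng = np.random.default_rng(1)
        valid = env_stack.finite_mask(["env1", "env2", "env3"])
        bg = sample_background(env_stack.grid, valid, 2000, rng)
        pr = occ.unique_cells(env_stack.grid)
        fs = build_features(env_stack, pr, bg, ("linear", "quadratic"),
                            ["env1", "env2", "env3"])
        f_bg = fs.transform(env_stack.values_at_cells(*bg, fs.variables))
        f_pr = fs.transform(env_stack.values_at_cells(*pr, fs.variables))
        mdl = fit(fs, f_pr, f_bg)
        q = np.exp(f_bg @ mdl.lam - mdl.log_partition)
        assert abs(q.sum() - 1.0) < 1e-9
        assert mdl.entropy >= 0

    def test_huge_regularization_shrinks_to_uniform(self):
        rng = np.random.default_rng(2)
        fs = _simple_feature_set()
        f_bg = rng.uniform(2, 4, (200, 1))
        f_pr = rng.uniform(3, 4, (50, 1))
        mdl = fit(fs, fs.transform(f_pr), fs.transform(f_bg), beta=np.array([1e6]))
        assert np.allclose(mdl.lam, 0.0)
        assert mdl.gain == pytest.approx(0.0, abs=1e-9)

    def test_one_feature_matches_brute_force_oracle(self):
        # binary feature: background (1,1,0,0); presences (1,1,1,0)
        fs = FeatureSet(["a"], [FeatureDef("a", "linear")], {"a": 0.0}, {"a": 1.0})
        f_bg = np.array([[1.0], [1.0], [0.0], [0.0]])
        f_pr = np.array([[1.0], [1.0], [1.0], [0.0]])
        for beta in (0.0, 0.1):
            mdl = fit(fs, f_pr, f_bg, beta=np.array([beta]), tol=1e-12)

            def objective(lam):
                return (-(f_pr @ [lam]).mean() + logsumexp(f_bg @ [lam])
                        + beta * abs(lam))

            oracle = minimize_scalar(objective, bounds=(-20, 20), method="bounded",
                                     options={"xatol": 1e-10})
            assert mdl.lam[0] == pytest.approx(oracle.x, abs=1e-3)

    def test_unregularized_solution_is_closed_form(self):
        # p_emp = 0.75 with half the background on the feature -> lam = ln 3
        fs = FeatureSet(["a"], [FeatureDef("a", "linear")], {"a": 0.0}, {"a": 1.0})
        f_bg = np.array([[1.0], [1.0], [0.0], [0.0]])
        f_pr = np.array([[1.0], [1.0], [1.0], [0.0]])
        mdl = fit(fs, f_pr, f_bg, beta=np.array([0.0]), tol=1e-12)
        assert mdl.lam[0] == pytest.approx(np.log(3.0), abs=1e-6)

    def test_duplicated_feature_coefficients_sum_to_single(self):
        rng = np.random.default_rng(3)
        x_bg = rng.uniform(0, 1, (300, 1))
        x_pr = rng.beta(3, 1.5, (80, 1))
        single = FeatureSet(["a"], [FeatureDef("a", "linear")], {"a": 0.0}, {"a": 1.0})
        double = FeatureSet(
            ["a"], [FeatureDef("a", "linear"), FeatureDef("a", "linear")],
            {"a": 0.0}, {"a": 1.0},
        )
        m1 = fit(single, x_pr, x_bg, beta=np.array([0.0]), tol=1e-12)
        m2 = fit(double, np.hstack([x_pr, x_pr]), np.hstack([x_bg, x_bg]),
                 beta=np.zeros(2), tol=1e-12)
        assert m2.lam.sum() == pytest.approx(m1.lam[0], abs=1e-3)

    def test_l1_path_never_gains_nonzeros(self, env_stack, structured_species):
        _, _, occ = structured_species
        rng = np.random.default_rng(4)
        valid = env_stack.finite_mask()
        bg = sample_background(env_stack.grid, valid, 1500, rng)
        pr = occ.unique_cells(env_stack.grid)
        vars_ = ["env1", "env2", "env3", "env4"]
        fs = build_features(env_stack, pr, bg, ("linear", "quadratic"), vars_)
        f_bg = fs.transform(env_stack.values_at_cells(*bg, fs.variables))
        f_pr = fs.transform(env_stack.values_at_cells(*pr, fs.variables))
        nnz = [
            int(np.count_nonzero(fit(fs, f_pr, f_bg, beta_multiplier=b).lam))
            for b in (1.0, 10.0, 100.0)
        ]
        assert nnz[0] >= nnz[1] >= nnz[2]


class TestLogisticOutput:
    def test_uniform_model_scores_half_everywhere(self, env_stack):
        rng = np.random.default_rng(5)
        bg = sample_background(env_stack.grid, env_stack.finite_mask(["env1"]), 1000, rng)
        fs = build_features(env_stack, bg, bg, ("linear",), ["env1"])
        f_bg = fs.transform(env_stack.values_at_cells(*bg, fs.variables))
        mdl = fit(fs, f_bg[:5], f_bg, beta=np.array([1e9]))
        out = predict_logistic(mdl, env_stack)
        np.testing.assert_allclose(out.values, 0.5, atol=1e-9)

    def test_three_cell_closed_form(self):
        # lam.f = (0, 1, 2) over a 3-cell background
        fs = FeatureSet(["a"], [FeatureDef("a", "linear")], {"a": 0.0}, {"a": 2.0})
        raw = np.array([[0.0], [1.0], [2.0]])
        f = fs.transform(raw)
        lam = np.array([2.0])
        s = f @ lam
        logZ = logsumexp(s)
        q = np.exp(s - logZ)
        H = -(q * (s - logZ)).sum()
        from flywaysdm.maxent import MaxEntModel

        mdl = MaxEntModel(fs, lam, float(logZ), float(H), np.zeros(1), 3, True, 1, 0.0)
        got = logistic_scores(mdl, raw)
        expected = q * np.exp(H) / (1 + q * np.exp(H))
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_monotone_in_linear_predictor(self):
        fs = FeatureSet(["a"], [FeatureDef("a", "linear")], {"a": 0.0}, {"a": 1.0})
        from flywaysdm.maxent import MaxEntModel

        mdl = MaxEntModel(fs, np.array([3.0]), 0.5, 1.2, np.zeros(1), 10, True, 1, 0.0)
        raw = np.linspace(0, 1, 50)[:, None]
        scores = logistic_scores(mdl, raw)
        assert np.all(np.diff(scores) > 0)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([3, 4, 5], [0, 1, 2]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([1.0] * 5, [1.0] * 7) == 0.5

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            p = np.round(rng.uniform(0, 1, 20), 2)  # rounding forces ties
            b = np.round(rng.uniform(0, 1, 30), 2)
            brute = np.mean(
                [(1.0 if pi > bi else 0.5 if pi == bi else 0.0) for pi in p for bi in b]
            )
            assert auc(p, b) == pytest.approx(brute, abs=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            auc([], [1.0])


class TestImportanceStatistics:
    def test_single_variable_contribution_is_100(self):
        fs = FeatureSet(["a"], [FeatureDef("a", "linear")], {"a": 0.0}, {"a": 1.0})
        rng = np.random.default_rng(7)
        f_bg = rng.uniform(0, 1, (300, 1))
        f_pr = rng.beta(4, 1.5, (60, 1))
        mdl = fit(fs, f_pr, f_bg)
        contrib = percent_contribution(mdl)
        assert contrib["a"] == pytest.approx(100.0)

    def test_contributions_sum_to_100(self, env_stack, structured_species):
        _, _, occ = structured_species
        rng = np.random.default_rng(8)
        bg = sample_background(env_stack.grid, env_stack.finite_mask(), 1500, rng)
        pr = occ.unique_cells(env_stack.grid)
        fs = build_features(env_stack, pr, bg, ("linear", "quadratic"),
                            ["env1", "env2", "env3"])
        f_bg = fs.transform(env_stack.values_at_cells(*bg, fs.variables))
        f_pr = fs.transform(env_stack.values_at_cells(*pr, fs.variables))
        contrib = percent_contribution(fit(fs, f_pr, f_bg))
        assert sum(contrib.values()) == pytest.approx(100.0, abs=1e-6)

    def test_jackknife_noise_variable_has_negligible_solo_gain(self, env_stack,
                                                               structured_species):
        _, _, occ = structured_species
        rng = np.random.default_rng(9)
        bg = sample_background(env_stack.grid, env_stack.finite_mask(), 2000, rng)
        pr = occ.unique_cells(env_stack.grid)
        vars_ = ["env1", "env4"]  # env4 plays no role in the truth
        fs = build_features(env_stack, pr, bg, ("linear", "quadratic"), vars_)
        f_bg = fs.transform(env_stack.values_at_cells(*bg, fs.variables))
        f_pr = fs.transform(env_stack.values_at_cells(*pr, fs.variables))
        jk = jackknife_gain(fs, f_pr, f_bg)
        assert jk["env4"][0] < 0.05
        assert jk["env1"][0] > 5 * max(jk["env4"][0], 1e-6)
        # removing the noise variable barely moves the full gain
        full = fit(fs, f_pr, f_bg).gain
        assert abs(jk["env4"][1] - full) / full < 0.05


class TestEvaluateSubsample:
    def test_null_species_auc_near_half(self, env_stack):
        grid = env_stack.grid
        flat = RasterLayer(grid, "u", np.ones(grid.shape))
        occ = sample_occurrences(flat, 300, seed=10, species="null", group="g")
        rep = evaluate_subsample(
            env_stack, occ, variables=["env1", "env2", "env3"],
            n_background=2000, n_replicates=10, seed=11,
            classes=("linear", "quadratic"), compute_jackknife=False,
        )
        assert abs(rep.auc_mean - 0.5) < 0.07
        assert rep.excluded  # the reliability rule must flag a null model

    def test_structured_species_beats_null_and_is_stable(self, env_stack,
                                                         structured_species):
        _, truth, occ = structured_species
        rep = evaluate_subsample(
            env_stack, occ, variables=["env1", "env2", "env3", "env4"],
            n_background=2000, n_replicates=5, seed=12,
            classes=("linear", "quadratic"), compute_jackknife=False,
        )
        assert rep.auc_mean > 0.7
        assert rep.cv < 0.15
        assert max(rep.contributions, key=rep.contributions.get) == "env1"

    def test_too_few_presences_error_names_species(self, env_stack):
        grid = env_stack.grid
        vals = np.zeros(grid.shape)
        vals[3, 3] = 1.0
        occ = sample_occurrences(RasterLayer(grid, "s", vals), 5, seed=1,
                                 species="rare_sp", group="g")
        with pytest.raises(ValueError, match="rare_sp"):
            evaluate_subsample(env_stack, occ, variables=["env1"], n_background=500,
                               seed=1)
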