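"""Model core: feature expansion, the penalised fit against a generic
convex-optimizer oracle, prediction transforms, the lambdas text format, and
variable contribution/importance."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import spearmanr

import sdmpipe as s
from sdmpipe.grids import EnvStack, Grid
from sdmpipe.maxent import (
    Feature,
    build_features,
    compute_betas,
    expand_features,
    fit_gibbs,
    penalized_objective,
)

from conftest import make_stack


def oracle_fit(Xp, Xb, betas):
    """Independent solver: split λ = a − b with a, b ≥ 0 and L-BFGS-B."""
    F = Xb.shape[1]

    def obj(ab):
        lam = ab[:F] - ab[F:]
        return logsumexp(Xb @ lam) - (Xp @ lam).mean() + betas @ (ab[:F] + ab[F:])

    res = minimize(
        obj,
        np.zeros(2 * F),
        method="L-BFGS-B",
        bounds=[(0, None)] * 2 * F,
        options={"maxiter": 3000, "ftol": 1e-15, "gtol": 1e-12},
    )
    return res.x[:F] - res.x[F:]


class TestFeatureExpansion:
    def test_linear_scales_to_unit_interval_endpoints(self):
        f = Feature("linear", ("v",), 2.0, 12.0)
        vals = {"v": np.array([2.0, 12.0, 7.0])}
        assert np.allclose(f.evaluate(vals), [0.0, 1.0, 0.5])

    def test_hinge_with_knot_at_min_reduces_to_linear(self):
        lin = Feature("linear", ("v",), 0.0, 10.0)
        hin = Feature("hinge", ("v",), 0.0, 10.0, knot=0.0)
        vals = {"v": np.linspace(0, 10, 21)}
        assert np.allclose(lin.evaluate(vals), hin.evaluate(vals))

    def test_quadratic_at_midpoint_of_0_10_is_quarter(self):
        # raw v² spans [0, 100] over training data covering [0, 10]
        f = Feature("quadratic", ("v",), 0.0, 100.0)
        assert f.evaluate({"v": np.array([5.0])})[0] == pytest.approx(0.25)

    def test_threshold_and_categorical_are_indicators(self):
        th = Feature("threshold", ("v",), 0.0, 1.0, knot=4.0)
        cat = Feature("categorical", ("r",), 0.0, 1.0, code=2.0)
        assert np.array_equal(th.evaluate({"v": np.array([3.0, 4.0, 5.0])}), [0, 1, 1])
        assert np.array_equal(cat.evaluate({"r": np.array([1.0, 2.0])}), [0, 1])

    def test_clamping_restricts_to_training_range(self):
        feats = [Feature("linear", ("v",), 0.0, 10.0)]
        X = expand_features({"v": np.array([-5.0, 15.0])}, feats, {"v": (0.0, 10.0)}, clamp=True)
        assert np.allclose(X[:, 0], [0.0, 1.0])
        X_raw = expand_features({"v": np.array([-5.0, 15.0])}, feats, clamp=False)
        assert X_raw[0, 0] < 0.0 < 1.0 < X_raw[1, 0]


class TestFit:
    def test_no_features_gives_uniform_raw(self):
        stack = make_stack({"v": np.random.default_rng(0).random((6, 6))})
        cfg = s.FeatureConfig(classes=(), beta_multiplier=1.0)
        m = s.fit_maxent(np.array([1, 5, 9]), np.arange(36), stack, cfg)
        raw = m.score_cells(stack, np.arange(36), output="raw")
        assert np.allclose(raw, 1.0 / 36.0)

    def test_binary_feature_beta_to_zero_concentrates_mass(self):
        v = np.zeros((10, 10))
        v[:5, :] = 1.0
        stack = EnvStack(["b"], Grid(10, 10, 5.0), v[None])
        pres = np.arange(0, 50, 3)
        bg = np.arange(100)
        cfg = s.FeatureConfig(classes=("linear",), beta_multiplier=1e-6)
        m = s.fit_maxent(pres, bg, stack, cfg)
        raw = m.score_cells(stack, bg, output="raw")
        assert raw[:50].sum() == pytest.approx(1.0, abs=1e-4)
        # and the fit matches the independent convex solver at the same betas
        Xp = np.ones((len(pres), 1))
        Xb = np.concatenate([np.ones(50), np.zeros(50)])[:, None]
        betas = compute_betas([m.features[0]], Xp, cfg)
        lam_o = oracle_fit(Xp, Xb, betas)
        J_mine = penalized_objective(np.array([m.features[0].lam]), Xp, Xb, betas)
        J_oracle = penalized_objective(lam_o, Xp, Xb, betas)
        assert J_mine <= J_oracle + 1e-4

    def test_duplicate_presences_do_not_change_fit(self, landscape, gaussian_species):
        occ = s.sample_occurrences(gaussian_species, landscape, 80, seed=3)
        cfg = s.FeatureConfig(classes=("linear", "quadratic"))
        m1 = s.fit_maxent(occ.cell_index, landscape.valid_cells, landscape, cfg)
        dup = np.concatenate([occ.cell_index, occ.cell_index])
        m2 = s.fit_maxent(dup, landscape.valid_cells, landscape, cfg)
        assert np.array_equal([f.lam for f in m1.features], [f.lam for f in m2.features])

    def test_raw_normalizes_over_background(self, landscape, gaussian_species):
        occ = s.sample_occurrences(gaussian_species, landscape, 60, seed=4)
        m = s.fit_maxent(occ, landscape.valid_cells, landscape, s.FeatureConfig(classes=("linear", "quadratic")))
        raw = m.score_cells(landscape, landscape.valid_cells, output="raw")
        assert raw.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_usable_presences_rejected(self, landscape):
        with pytest.raises(ValueError, match="presence"):
            s.fit_maxent(np.array([], dtype=int), landscape.valid_cells, landscape)

    def test_monotone_regularization_path(self, landscape, gaussian_species):
        occ = s.sample_occurrences(gaussian_species, landscape, 100, seed=2)
        counts = []
        for bm in (0.2, 0.5, 1.0, 2.0, 5.0, 10.0):
            cfg = s.FeatureConfig(classes=("linear", "quadratic", "hinge"), n_hinge_knots=10, beta_multiplier=bm)
            m = s.fit_maxent(occ, landscape.valid_cells, landscape, cfg)
            counts.append(sum(1 for f in m.features if abs(f.lam) > 1e-10))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @pytest.mark.parametrize("seed", range(4))
    def test_oracle_equivalence_on_small_landscapes(self, seed):
        """Penalised log-likelihood matches a generic convex optimizer."""
        rng = np.random.default_rng(seed)
        rows, cols = int(rng.integers(5, 11)), int(rng.integers(5, 10))
        stack = make_stack({f"v{i}": rng.random((rows, cols)) * 10 for i in range(3)})
        n_cells = rows * cols
        pres = rng.choice(n_cells, size=int(rng.integers(8, 20)), replace=False)
        cfg = s.FeatureConfig(classes=("linear", "quadratic"))
        model = s.fit_maxent(pres, np.arange(n_cells), stack, cfg)
        Xp, Xb, betas, lam = rebuild_matrices(model, pres, np.arange(n_cells), stack, cfg)
        J_mine = penalized_objective(lam, Xp, Xb, betas)
        J_oracle = penalized_objective(oracle_fit(Xp, Xb, betas), Xp, Xb, betas)
        assert J_mine <= J_oracle + 1e-4


def rebuild_matrices(model, pres_cells, bg_cells, stack, cfg):
    """Reconstruct the design matrices a fitted model was trained on."""
    variables = model.variables
    pv = {v: stack.values_at_cells(np.unique(pres_cells), [v])[:, 0] for v in variables}
    bv = {v: stack.values_at_cells(bg_cells, [v])[:, 0] for v in variables}
    feats = [f for f in model.features if f.kind in cfg.classes]
    Xp = expand_features(pv, feats)
    Xb = expand_features(bv, feats)
    betas = compute_betas(feats, Xp, cfg)
    lam = np.array([f.lam for f in feats])
    return Xp, Xb, betas, lam


class TestPredict:
    def test_projection_onto_training_stack_reproduces_training_scores(self, landscape, gaussian_species):
        occ = s.sample_occurrences(gaussian_species, landscape, 60, seed=5)
        m = s.fit_maxent(occ, landscape.valid_cells, landscape, s.FeatureConfig(classes=("linear", "quadratic")))
        pred = s.predict(m, landscape, output="cloglog")
        again = s.predict(m, landscape, output="cloglog")
        assert np.array_equal(pred.values, again.values)
        assert pred.clamp_fraction == 0.0

    def test_all_variables_beyond_max_clamp_to_training_max(self):
        rng = np.random.default_rng(1)
        stack = make_stack({"v": rng.random((6, 6)) * 10})
        pres = np.array([1, 7, 30])
        m = s.fit_maxent(pres, np.arange(36), stack, s.FeatureConfig(classes=("linear", "quadratic")))
        beyond = make_stack({"v": np.full((6, 6), 99.0)})
        at_max = make_stack({"v": np.full((6, 6), m.training_ranges["v"][1])})
        p1 = s.predict(m, beyond, clamp=True)
        p2 = s.predict(m, at_max, clamp=True)
        assert np.allclose(p1.values, p2.values)
        assert p1.clamp_fraction == 1.0

    def test_missing_variable_rejected_by_name(self, landscape, gaussian_species):
        occ = s.sample_occurrences(gaussian_species, landscape, 50, seed=6)
        m = s.fit_maxent(occ, landscape.valid_cells, landscape, s.FeatureConfig(classes=("linear",)))
        bad = make_stack({"other": np.zeros((4, 4))})
        with pytest.raises(KeyError, match="bio01"):
            s.predict(m, bad)

    def test_output_transforms_are_monotone_in_raw(self, landscape, gaussian_species):
        occ = s.sample_occurrences(gaussian_species, landscape, 60, seed=7)
        m = s.fit_maxent(occ, landscape.valid_cells, landscape, s.FeatureConfig(classes=("linear", "quadratic")))
        cells = landscape.valid_cells
        raw = m.score_cells(landscape, cells, output="raw")
        for out in ("cloglog", "logistic"):
            v = m.score_cells(landscape, cells, output=out)
            assert spearmanr(raw, v).statistic == pytest.approx(1.0)
            assert v.min() >= 0 and v.max() <= 1


class TestLambdasFormat:
    def test_round_trip_reproduces_model(self, tmp_path, landscape, gaussian_species):
        occ = s.sample_occurrences(gaussian_species, landscape, 60, seed=8)
        cfg = s.FeatureConfig(classes=("linear", "quadratic", "hinge", "threshold", "categorical"), n_hinge_knots=5, n_threshold_knots=4)
        m = s.fit_maxent(occ, landscape.valid_cells, landscape, cfg)
        path = s.write_lambdas(m, tmp_path / "m.lambdas")
        m2 = s.read_lambdas(path)
        assert len(m2.features) == len(m.features)
        for a, b in zip(m.features, m2.features):
            assert a.name == b.name
            assert a.lam == b.lam and a.fmin == b.fmin and a.fmax == b.fmax
        assert m2.linear_predictor_normalizer == m.linear_predictor_normalizer
        assert m2.density_normalizer == m.density_normalizer
        assert m2.entropy == m.entropy
        assert m2.training_ranges == m.training_ranges

    def test_missing_entropy_line_rejected(self, tmp_path):
        p = tmp_path / "bad.lambdas"
        p.write_text(
            "v, 1.0, 0.0, 1.0\nlinearPredictorNormalizer, 0.5\ndensityNormalizer, 2.0\nnumBackgroundPoints, 10\n"
        )
        with pytest.raises(ValueError, match="entropy"):
            s.read_lambdas(p)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.lambdas"
        p.write_text("v, 1.0, 0.0\n")
        with pytest.raises(ValueError, match="line 1"):
            s.read_lambdas(p)

    def test_hand_written_file_matches_pocket_calculator(self, tmp_path):
        """Predictions from a 2-feature file equal hand-computed arithmetic."""
        p = tmp_path / "hand.lambdas"
        p.write_text(
            "temp, 1.5, 0, 10\n"
            "rain, -0.5, 0, 2\n"
            "linearPredictorNormalizer, 1.2\n"
            "densityNormalizer, 3.0\n"
            "numBackgroundPoints, 4\n"
            "entropy, 1.1\n"
        )
        m = s.read_lambdas(p)
        vals = {"temp": np.array([10.0, 0.0, 5.0]), "rain": np.array([0.0, 2.0, 1.0])}
        raw = m.score_values(vals, output="raw")
        # raw = exp(1.5 t/10 − 0.5 r/2 − 1.2) / 3, worked out by hand per cell
        assert np.allclose(raw, [0.449952935859, 0.060894508018, 0.165528434597], atol=1e-9)
        clog = m.score_values(vals, output="cloglog")
        assert np.allclose(clog, [0.741208697068, 0.167179554800, 0.391814228961], atol=1e-9)


class TestContributionImportance:
    def _single_var_model(self, landscape, gaussian_species):
        occ = s.sample_occurrences(gaussian_species, landscape, 80, seed=9)
        names = ["bio01"]
        stack = make_stack({"bio01": landscape.layer("bio01")})
        return s.fit_maxent(occ, stack.valid_cells, stack, s.FeatureConfig(classes=("linear", "quadratic"))), stack, occ

    def test_single_variable_contribution_is_100(self, landscape, gaussian_species):
        m, _, _ = self._single_var_model(landscape, gaussian_species)
        contrib = s.percent_contribution(m)
        assert contrib == {"bio01": pytest.approx(100.0)}

    def test_zero_lambda_variable_has_zero_importance(self, landscape, gaussian_species):
        m, stack, occ = self._single_var_model(landscape, gaussian_species)
        # append an untouched variable: model λ for it is absent => permuting is a no-op
        imp = s.permutation_importance(m, occ, stack.valid_cells, stack, seed=0)
        assert imp == {"bio01": pytest.approx(100.0)}

    def test_symmetric_variables_split_contribution_evenly(self):
        rng = np.random.default_rng(12)
        a = rng.random((25, 25)) * 10
        b = rng.random((25, 25)) * 10
        stack = make_stack({"a": a, "b": b})
        vs = s.VirtualSpecies(
            "sym",
            "bird",
            niche={
                "a": s.GaussianResponse(5.0, 2.0),
                "b": s.GaussianResponse(5.0, 2.0),
            },
        )
        occ = s.sample_occurrences(vs, stack, 400, seed=12)
        m = s.fit_maxent(occ, stack.valid_cells, stack, s.FeatureConfig(classes=("linear", "quadratic")))
        contrib = s.percent_contribution(m)
        assert contrib["a"] == pytest.approx(50.0, abs=5.0)
        assert contrib["b"] == pytest.approx(50.0, abs=5.0)
        imp = s.permutation_importance(m, occ, stack.valid_cells, stack, seed=1)
        assert imp["a"] == pytest.approx(50.0, abs=10.0)
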