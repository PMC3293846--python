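"""Design-problem evaluation, landscape scans, model scoring and conversions."""

import numpy as np
import pytest

from kindisc.design import (
    DesignProblem,
    absorbance_to_concentration,
    evaluate_design,
    glyoxalase_design_problem,
    landscape_scan,
    run_design,
    score_models,
)
from kindisc.divergence import kl_extended
from kindisc.estimation import Dataset
from kindisc.gde3 import GDE3Settings
from kindisc.models import (
    TimeGrid,
    build_glyoxalase_model,
    reaction_rates,
    simulate,
)
from kindisc.synthetic import NoiseModel, generate_experiment


@pytest.fixture(scope="module")
def problem():
    return glyoxalase_design_problem()


class TestEvaluateDesign:
    def test_identical_candidates_zero_vector(self):
        m = build_glyoxalase_model(2)
        p = glyoxalase_design_problem()
        p = DesignProblem(
            models=(m, m),
            decision_variables=p.decision_variables,
            bounds=p.bounds,
            fixed=p.fixed,
            observables=p.observables,
            grid=p.grid,
        )
        np.testing.assert_allclose(evaluate_design([0.4, 0.6], p), 0.0, atol=1e-10)

    def test_red_dot_objectives_match_direct_computation(
        self, problem, model1, model2, red_dot_ic, design_grid
    ):
        vec = evaluate_design([0.221, 0.441], problem)
        f = simulate(model1, red_dot_ic, design_grid)
        g = simulate(model2, red_dot_ic, design_grid)
        assert len(vec) == 2
        assert vec[0] == pytest.approx(kl_extended(f, g, ["SDLGS"]))
        assert vec[1] == pytest.approx(kl_extended(g, f, ["SDLGS"]))
        assert np.all(vec > 0)

    def test_model_order_swaps_directed_components(self, problem):
        swapped = DesignProblem(
            models=problem.models[::-1],
            decision_variables=problem.decision_variables,
            bounds=problem.bounds,
            fixed=problem.fixed,
            observables=problem.observables,
            grid=problem.grid,
        )
        a = evaluate_design([0.3, 0.5], problem)
        b = evaluate_design([0.3, 0.5], swapped)
        np.testing.assert_allclose(a, b[::-1], rtol=1e-12)

    def test_decision_fixed_must_cover_species(self, problem):
        with pytest.raises(ValueError):
            DesignProblem(
                models=problem.models,
                decision_variables=("GSH",),
                bounds=np.array([[0.0, 1.0]]),
                fixed={"HTA": 0.0},  # MGO, SDLGS missing
                observables=("SDLGS",),
                grid=problem.grid,
            )


class TestRunDesign:
    def test_collapsed_bounds_front_is_that_point(self, problem):
        point = DesignProblem(
            models=problem.models,
            decision_variables=problem.decision_variables,
            bounds=np.array([[0.221, 0.221], [0.441, 0.441]]),
            fixed=problem.fixed,
            observables=problem.observables,
            grid=problem.grid,
        )
        settings = GDE3Settings(np_size=6, max_generations=2, seed=0)
        res = run_design(point, settings)
        np.testing.assert_allclose(res.front_decisions(), [[0.221, 0.441]] * len(res.front))
        np.testing.assert_allclose(
            res.front_objectives()[0], evaluate_design([0.221, 0.441], problem)
        )

    def test_front_within_bounds_and_reproducible(self, problem):
        settings = GDE3Settings(np_size=12, max_generations=8, seed=42)
        r1 = run_design(problem, settings)
        r2 = run_design(problem, settings)
        X = r1.front_decisions()
        assert np.all(X >= 0.0) and np.all(X <= 1.0)
        np.testing.assert_array_equal(X, r2.front_decisions())
        assert len(r1.time_courses) == len(r1.front)


class TestLandscape:
    def test_identical_models_all_zero(self):
        m = build_glyoxalase_model(1)
        p = glyoxalase_design_problem()
        p = DesignProblem(
            models=(m, m),
            decision_variables=p.decision_variables,
            bounds=p.bounds,
            fixed=p.fixed,
            observables=p.observables,
            grid=TimeGrid(0.0, 4.0, 31),
        )
        _, values = landscape_scan(p, "I12", resolution=4)
        np.testing.assert_allclose(values["I12"], 0.0, atol=1e-10)

    def test_requires_two_decision_variables(self, problem):
        one_d = DesignProblem(
            models=problem.models,
            decision_variables=("GSH",),
            bounds=np.array([[0.0, 1.0]]),
            fixed={"MGO": 0.4, "HTA": 0.0, "SDLGS": 0.0},
            observables=("SDLGS",),
            grid=problem.grid,
        )
        with pytest.raises(ValueError):
            landscape_scan(one_d, "I12", resolution=3)

    def test_coarse_kl_maximum_interior_l2_on_boundary(self, problem):
        """Even a coarse lattice shows the structural difference: directed
        KL peaks in the interior, plain L2 peaks on the box boundary."""
        axes, values = landscape_scan(problem, ("I12", "L2"), resolution=9)
        i, j = np.unravel_index(np.nanargmax(values["I12"]), (9, 9))
        assert 0 < i < 8 and 0 < j < 8
        bi, bj = np.unravel_index(np.nanargmax(values["L2"]), (9, 9))
        assert bi in (0, 8) or bj in (0, 8)


class TestScoreModels:
    def test_data_from_model2_prefers_model2(self, model1, model2, red_dot_ic):
        exp = generate_experiment(
            model2, red_dot_ic, np.linspace(0, 120, 61), NoiseModel(sd=0.005), 7
        )
        scores = score_models(Dataset([exp]), [model1, model2])
        assert scores.ranking[0] == model2.name
        assert scores.ssq[model2.name] < scores.ssq[model1.name]

    def test_identical_models_equal_scores(self, model2, red_dot_ic):
        exp = generate_experiment(
            model2, red_dot_ic, np.linspace(0, 120, 31), NoiseModel(sd=0.01), 3
        )
        twin = build_glyoxalase_model(2)
        scores = score_models(Dataset([exp]), [model2, twin])
        vals = list(scores.ssq.values())
        assert vals[0] == pytest.approx(vals[1])

    def test_empty_dataset_zero_scores_no_ranking(self, model1, model2):
        scores = score_models(Dataset([]), [model1, model2])
        assert all(v == 0.0 for v in scores.ssq.values())
        assert scores.ranking == []


class TestQuasiEquilibrium:
    """At the discriminatory design point the two models differ in how the
    non-enzymatic hemithioacetal step behaves: in model 1 its net rate is
    indistinguishable from the glyoxalase I rate (it limits the pathway),
    while in model 2 it idles at quasi-equilibrium.

    The comparison is made while the pathway is active (glyoxalase I flux
    above 1% of its peak); after methylglyoxal exhaustion both rates decay
    to numerical zero and their ratio is meaningless."""

    @staticmethod
    def _active_window(grid, v_gi):
        late = grid.times > 5
        return late & (v_gi > 0.01 * v_gi[late].max())

    def test_model1_hta_step_limits_glyoxalase_i(self, model1, red_dot_ic, design_grid):
        tc = simulate(model1, red_dot_ic, design_grid)
        r = reaction_rates(model1, tc)
        mask = self._active_window(design_grid, r["glyoxalase_I"])
        assert mask.sum() > 10
        rel = np.abs(r["hta_formation"][mask] - r["glyoxalase_I"][mask])
        assert np.all(rel < 0.02 * r["glyoxalase_I"][mask])

    def test_model2_hta_step_at_quasi_equilibrium(self, model2, red_dot_ic, design_grid):
        tc = simulate(model2, red_dot_ic, design_grid)
        r = reaction_rates(model2, tc)
        mask = self._active_window(design_grid, r["glyoxalase_I"])
        assert mask.sum() > 10
        assert np.all(np.abs(r["hta_formation"][mask]) < 0.02 * r["glyoxalase_I"][mask])


class TestAbsorbance:
    def test_known_coefficient(self):
        assert absorbance_to_concentration(2.86, 1.0) == pytest.approx(1.0)
        assert absorbance_to_concentration(0.0) == 0.0
        assert absorbance_to_concentration(1.43, 1.0) == pytest.approx(0.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            absorbance_to_concentration(-0.1)
        with pytest.raises(ValueError):
            absorbance_to_concentration(1.0, 0.0)
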