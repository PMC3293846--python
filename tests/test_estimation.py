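"""Least-squares objective, sensitivity equations, FIM and standard errors."""

import numpy as np
import pytest

from kindisc.errors import SloppinessWarning
from kindisc.estimation import (
    Dataset,
    EstimationSettings,
    Experiment,
    fisher_information,
    fit_collective,
    integrate_sensitivities,
    predict,
    sensitivity_system,
    ssq_objective,
    standard_errors,
)
from kindisc.models import (
    MASS_ACTION_REVERSIBLE,
    KineticModel,
    RateLaw,
    Reaction,
    build_glyoxalase_model,
)
from kindisc.synthetic import NoiseModel, make_glyoxalase_suite


def _decay_model(p=0.7):
    """dx/dt = -p*x as a degenerate mass-action model (x + x -> 2x sink)."""
    # encode first-order decay with a pseudo reaction X -> (nothing):
    # mass_action_reversible with kr = 0 and a dummy partner held at 1
    law = RateLaw(MASS_ACTION_REVERSIBLE, ("X", "ONE"), ("p", "zero"), ("SINK",))
    rxn = Reaction("decay", {"X": -1}, law)
    return KineticModel(
        name="decay",
        species=("X", "ONE", "SINK"),
        constants={},
        parameters={"p": p, "zero": 0.0},
        reactions=(rxn,),
    )


class TestSSQ:
    def test_zero_on_self_generated_data(self, model1):
        suite = make_glyoxalase_suite(1, NoiseModel(sd=0.0), seed=4)
        assert ssq_objective({}, model1, suite.dataset) <= 1e-10

    def test_empty_dataset_zero(self, model1):
        assert ssq_objective({}, model1, Dataset([])) == 0.0

    def test_single_residual_squared(self, model2):
        # MGO = 0 forces SDLGS(t) = 0, so a 0.5 mM "measurement" leaves
        # a 0.25 mM^2 objective
        exp = Experiment(
            initial_conditions={"GSH": 0.5, "MGO": 0.0, "HTA": 0.0, "SDLGS": 0.0},
            observed=("SDLGS",),
            times=np.array([30.0]),
            values=np.array([[0.5]]),
        )
        assert ssq_objective({}, model2, Dataset([exp])) == pytest.approx(0.25)

    def test_invariant_under_experiment_permutation(self, model1):
        suite = make_glyoxalase_suite(1, NoiseModel(sd=0.01), seed=8)
        data = suite.dataset
        flipped = Dataset(list(reversed(data.experiments)))
        p = {"kcat_GLOI": 7e4, "Km_HTA": 0.3}
        assert ssq_objective(p, model1, data) == pytest.approx(
            ssq_objective(p, model1, flipped)
        )


class TestSensitivities:
    def test_exponential_decay_closed_form(self):
        """For dx/dt = -p x, S(t) = dx/dp = -t x0 exp(-pt)."""
        model = _decay_model(p=0.7)
        times = np.linspace(0, 5, 21)
        states, S = integrate_sensitivities(
            model, ["p"], {"X": 2.0, "ONE": 1.0, "SINK": 0.0}, times
        )
        expected_x = 2.0 * np.exp(-0.7 * times)
        expected_s = -times * 2.0 * np.exp(-0.7 * times)
        np.testing.assert_allclose(states[:, 0], expected_x, atol=1e-6)
        np.testing.assert_allclose(S[:, 0, 0], expected_s, atol=1e-6)

    def test_sensitivities_start_at_zero(self, model1, red_dot_ic):
        free = ["kcat_GLOII"]
        _, S = integrate_sensitivities(model1, free, red_dot_ic, np.array([0.0, 1.0]))
        np.testing.assert_allclose(S[0], 0.0, atol=1e-14)
        assert abs(S[1, model1.index("SDLGS"), 0]) > 0

    @pytest.mark.parametrize("variant", [1, 2])
    def test_symbolic_vs_finite_difference(self, variant, red_dot_ic):
        """Symbolic sensitivities match central finite differences to 1e-4
        relative on the dominant entries.

        The FD oracle runs the solver at very tight tolerances and uses a
        relative step of 1e-5: central differencing divides solver noise by
        2h, so smaller steps (or default tolerances) would leave the oracle
        itself noisier than the tolerance being checked.
        """
        model = build_glyoxalase_model(variant)
        free = [p for p in model.parameters if p.startswith(("kcat", "Km"))]
        times = np.linspace(0.0, 120.0, 13)
        _, S = integrate_sensitivities(model, free, red_dot_ic, times,
                                       rtol=1e-10, atol=1e-13)
        row = model.index("SDLGS")
        for qi, name in enumerate(free):
            p0 = model.parameters[name]
            h = 1e-5 * p0
            exp = Experiment(red_dot_ic, ("SDLGS",), times[1:], np.zeros((1, 12)))
            up = predict(model.with_parameters({name: p0 + h}), exp,
                         rtol=1e-12, atol=1e-15)[0]
            dn = predict(model.with_parameters({name: p0 - h}), exp,
                         rtol=1e-12, atol=1e-15)[0]
            fd = (up - dn) / (2 * h)
            scale = np.max(np.abs(fd)) + 1e-30
            np.testing.assert_allclose(
                S[1:, row, qi] / scale, fd / scale, atol=1e-4
            )

    def test_unknown_free_parameter_rejected(self, model1):
        with pytest.raises(ValueError):
            sensitivity_system(model1, ["not_a_param"])


class TestFisherInformation:
    def test_linear_model_closed_form(self):
        """For x(t) = x0 e^{-pt} ~ measurements of X, the FIM reduces to
        sum S_i^2 / sigma^2; checked against the closed-form sensitivity."""
        model = _decay_model(p=0.4)
        times = np.array([1.0, 2.0, 3.0, 4.0])
        sigma = 0.05
        exp = Experiment(
            {"X": 1.5, "ONE": 1.0, "SINK": 0.0}, ("X",), times,
            np.zeros((1, len(times))),
        )
        fim = fisher_information(model, ["p"], Dataset([exp]), sigma)
        s_closed = -times * 1.5 * np.exp(-0.4 * times)
        assert fim[0, 0] == pytest.approx(np.sum(s_closed**2) / sigma**2, rel=1e-5)

    def test_doubling_sigma_quarters_fim(self, model1, red_dot_ic):
        times = np.linspace(10, 120, 5)
        exp = Experiment(red_dot_ic, ("SDLGS",), times, np.zeros((1, 5)))
        data = Dataset([exp])
        f1 = fisher_information(model1, ["kcat_GLOI", "Km_HTA"], data, 0.01)
        f2 = fisher_information(model1, ["kcat_GLOI", "Km_HTA"], data, 0.02)
        np.testing.assert_allclose(f2, f1 / 4)

    def test_fim_symmetric_psd(self, model2, red_dot_ic):
        times = np.linspace(5, 120, 8)
        exp = Experiment(red_dot_ic, ("SDLGS",), times, np.zeros((1, 8)))
        fim = fisher_information(
            model2, ["kcat_GLOI", "Km_GSH", "Km_MGO"], Dataset([exp]), 0.005
        )
        np.testing.assert_allclose(fim, fim.T)
        assert np.all(np.linalg.eigvalsh(fim) >= -1e-8 * np.max(np.abs(fim)))


class TestStandardErrors:
    def test_diagonal_fim(self):
        se = standard_errors(np.diag([4.0, 16.0]))
        np.testing.assert_allclose(se, [0.5, 0.25])

    def test_linear_model_sigma_over_sqrt_sum_t2(self):
        # y = p*t with V = sigma^2 I: FIM = sum t_i^2 / sigma^2,
        # SE = sigma / sqrt(sum t_i^2) exactly
        t = np.array([1.0, 2.0, 3.0, 5.0])
        sigma = 0.3
        fim = np.array([[np.sum(t**2) / sigma**2]])
        assert standard_errors(fim)[0] == pytest.approx(sigma / np.sqrt(np.sum(t**2)))

    def test_near_singular_fim_warns_and_withholds(self):
        fim = np.array([[1.0, 1.0], [1.0, 1.0 + 1e-14]])
        with pytest.warns(SloppinessWarning):
            assert standard_errors(fim) is None


class TestFitCollective:
    def test_noise_free_recovery_model1(self):
        """DE + simplex recovers the generating kcat/Km within 1% from
        noise-free glyoxalase-I time courses."""
        suite = make_glyoxalase_suite(1, NoiseModel(sd=0.0), seed=0)
        model = build_glyoxalase_model(1)
        settings = EstimationSettings(
            bounds={"kcat_GLOI": (1e2, 1e7), "Km_HTA": (1e-3, 1e2)},
            de_popsize=15, de_generations=40, seed=1,
        )
        est = fit_collective(model, suite.glyoxalase_i_data(), settings)
        assert est.objective_value < 1e-8
        for name in settings.bounds:
            assert est.values[name] == pytest.approx(
                suite.truth_parameters[name], rel=0.01
            )

    def test_noisy_fit_reports_standard_errors(self):
        suite = make_glyoxalase_suite(1, NoiseModel(sd=0.005), seed=3)
        model = build_glyoxalase_model(1)
        settings = EstimationSettings(
            bounds={"kcat_GLOII": (1e2, 1e7), "Km_SDLGS": (1e-3, 1e2)},
            de_popsize=12, de_generations=30, seed=2,
        )
        est = fit_collective(model, suite.glyoxalase_ii_data(), settings)
        assert est.standard_errors is not None
        for name in settings.bounds:
            truth = suite.truth_parameters[name]
            assert abs(est.values[name] - truth) < 3 * est.standard_errors[name]

    def test_empty_dataset_rejected(self, model1):
        with pytest.raises(ValueError):
            fit_collective(model1, Dataset([]), EstimationSettings(bounds={"Km_HTA": (1e-3, 1e2)}))
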