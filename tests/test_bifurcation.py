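import numpy as np
import pytest

from cscflow._errors import DomainError
from cscflow.bifurcation import (
    classify_stability,
    find_equilibrium,
    invasion_threshold,
    scan_parameter,
)
from cscflow.ensemble import TimeGrid, simulate_one
from cscflow.models import CSCParameters, csc_model, fixture_model


def random_csc_params(rng, gamma_PC=0.0):
    """A random admissible parameter set with a threshold inside (0, 1)."""
    omega = rng.uniform(0.5, 2.0)
    eta1 = rng.uniform(0.005, 0.2)
    delta1 = rng.uniform(0.005, 0.2)
    return CSCParameters(
        P_sy=0.5, omega_CSC=omega, omega_PC=rng.uniform(0.1, 1.0),
        eta_1=eta1, eta_2=rng.uniform(0.01, 0.2), eta_3=rng.uniform(0.05, 0.3),
        gamma_PC=gamma_PC, delta_1=delta1, delta_2=rng.uniform(0.005, 0.05),
        delta_3=rng.uniform(0.05, 0.3), delta_4=rng.uniform(0.1, 0.5),
        h_CSC=rng.uniform(1e-4, 2e-3), h_PC=rng.uniform(1e-4, 2e-3),
    )


class TestFindEquilibrium:
    def test_zero_state_always_equilibrium_of_population_model(self, csc):
        res = find_equilibrium(csc, csc.default_parameters, np.zeros(5))
        assert res.converged
        assert res.state == pytest.approx(np.zeros(5), abs=1e-12)

    def test_logistic_carrying_capacity_root(self):
        m = fixture_model("logistic")
        res = find_equilibrium(m, np.array([1.0, 100.0]), np.array([50.0]))
        assert res.converged
        assert res.state[0] == pytest.approx(100.0, abs=1e-8)

    def test_bistable_roots_from_three_guesses(self):
        m = fixture_model("bistable_toy")
        p = np.array([0.3])
        roots = [find_equilibrium(m, p, np.array([g])).state[0]
                 for g in (-0.1, 0.4, 1.2)]
        assert roots == pytest.approx([0.0, 0.3, 1.0], abs=1e-8)

    def test_nonconvergence_is_a_result_not_an_exception(self):
        # an equilibrium-free system: constant positive derivative
        m = fixture_model("monotone_linear", weights=(1.0,))
        res = find_equilibrium(m, np.array([2.0]), np.array([0.0]), max_iter=5)
        assert not res.converged and res.state is None


class TestClassifyStability:
    def test_logistic_at_capacity(self):
        m = fixture_model("logistic")
        s = classify_stability(m, np.array([100.0]), np.array([1.0, 100.0]))
        assert s.stable
        assert s.max_real_eigenvalue == pytest.approx(-1.0)

    @pytest.mark.parametrize("p_sy,stable", [(0.015, True), (0.035, False)])
    def test_extinction_state_threshold_without_dedifferentiation(self, p_sy, stable):
        """With gamma_PC = 0 the origin's leading eigenvalue is
        P_sy*omega_CSC - eta_1 - delta_1; stability flips at the ratio."""
        params = CSCParameters(P_sy=p_sy, gamma_PC=0.0)  # threshold 0.025
        model = csc_model(params)
        s = classify_stability(model, np.zeros(5), params.to_array())
        assert s.stable is stable


class TestInvasionThreshold:
    def test_closed_form(self):
        p = CSCParameters(eta_1=0.01, delta_1=0.015, omega_CSC=1.0, gamma_PC=0.0)
        assert invasion_threshold(p) == pytest.approx(0.025)

    def test_shipped_defaults_sit_on_the_published_value(self, csc_defaults):
        with pytest.warns(UserWarning):
            assert invasion_threshold(csc_defaults) == pytest.approx(0.025)

    def test_no_loss_means_zero_threshold(self):
        p = CSCParameters(eta_1=0.0, delta_1=0.0, gamma_PC=0.0)
        assert invasion_threshold(p) == 0.0

    def test_zero_proliferation_rejected(self):
        with pytest.raises(DomainError):
            invasion_threshold(CSCParameters(omega_CSC=0.0, gamma_PC=0.0))

    def test_dedifferentiation_warns(self, csc_defaults):
        with pytest.warns(UserWarning, match="gamma_PC"):
            invasion_threshold(csc_defaults)


class TestScanParameter:
    def test_bistable_branches_and_stability_pattern(self):
        """All three equilibrium branches of the cubic with the known
        stable / unstable / stable pattern, and no crossing inside (0.1, 0.9)."""
        m = fixture_model("bistable_toy")
        diagram = scan_parameter(
            m, m.default_parameters, "p", (0.1, 0.9), n_points=17,
            seed_guesses=[np.array([0.0]), np.array([0.12]), np.array([1.2])],
        )
        assert diagram.transcritical_points == []
        e0, mid, one = (diagram.branches[k] for k in ("E1", "E2", "E3"))
        for pt in e0:
            assert pt.state[0] == pytest.approx(0.0, abs=1e-8) and pt.stable
        for pt in mid:
            assert pt.state[0] == pytest.approx(pt.parameter_value, abs=1e-6)
            assert not pt.stable
        for pt in one:
            assert pt.state[0] == pytest.approx(1.0, abs=1e-8) and pt.stable

    def test_csc_crossing_matches_closed_form(self, csc_defaults):
        import dataclasses

        params = dataclasses.replace(csc_defaults, gamma_PC=0.0)
        model = csc_model(params)
        diagram = scan_parameter(model, params, "P_sy", (0.0, 0.2), n_points=21)
        assert len(diagram.transcritical_points) == 1
        tp = diagram.transcritical_points[0]
        assert tp.parameter_value == pytest.approx(0.025, abs=1e-4)
        assert tp.stability_swap_verified

    def test_positive_branch_bounded_by_feedback(self, csc_defaults):
        model = csc_model(csc_defaults)
        diagram = scan_parameter(model, csc_defaults, "P_sy", (0.3, 1.0), n_points=8)
        e1 = diagram.branches["E1"]
        assert len(e1) == 8
        for pt in e1:
            assert np.all(np.isfinite(pt.state))
            assert np.all(pt.state > 0)

    def test_every_reported_equilibrium_satisfies_rhs_tolerance(self, csc_defaults):
        """Residual check independent of the Newton solver's own report."""
        model = csc_model(csc_defaults)
        diagram = scan_parameter(model, csc_defaults, "P_sy", (0.0, 1.0), n_points=11)
        for pts in diagram.branches.values():
            for pt in pts:
                f = model.rhs(pt.state, model.parameter_vector({"P_sy": pt.parameter_value}), 0.0)
                scale = max(1.0, float(np.max(np.abs(pt.state))))
                assert np.linalg.norm(f) <= 1e-8 * scale

    def test_trajectories_agree_with_threshold_sides(self):
        """Simulation consistency: 10 seeded parameter sets, starting from a
        small stem-cell seed 10% on either side of the invasion boundary —
        decay to extinction below it, growth above it."""
        rng = np.random.default_rng(77)
        grid = TimeGrid.uniform(0.0, 4000.0, 9)
        checked = 0
        while checked < 10:
            base = random_csc_params(rng, gamma_PC=0.0)
            pstar = invasion_threshold(base)
            if not 0.05 < pstar < 0.8:
                continue
            model = csc_model(base)
            y0 = np.array([10.0, 0.0, 0.0, 0.0, 0.0])
            finals = {}
            for side in (0.9, 1.1):
                p = model.parameter_vector({"P_sy": side * pstar})
                res = simulate_one(model, p, y0, grid)
                assert res.success
                finals[side] = res.trace[-1, 0]
            assert finals[0.9] < 1.0  # decay toward extinction below the boundary
            assert finals[1.1] > 10.0 * finals[0.9]  # clear separation above it
            checked += 1

    def test_bad_inputs_rejected(self, csc):
        with pytest.raises(DomainError):
            scan_parameter(csc, csc.default_parameters, "P_sy", (1.0, 0.0))
        with pytest.raises(DomainError):
            scan_parameter(csc, csc.default_parameters, "nope", (0.0, 1.0))


class TestDiagramSerialization:
    def test_csv_roundtrip_columns(self, csc_defaults, tmp_path):
        model = csc_model(csc_defaults)
        diagram = scan_parameter(model, csc_defaults, "P_sy", (0.0, 0.1), n_points=5)
        path = diagram.save(tmp_path / "diagram.csv")
        import pandas as pd

        frame = pd.read_csv(path)
        assert {"parameter_value", "branch", "max_real_eigenvalue", "stable"} <= set(frame.columns)
        assert len(frame) == sum(len(v) for v in diagram.branches.values())

    def test_plot_written(self, csc_defaults, tmp_path):
        model = csc_model(csc_defaults)
        diagram = scan_parameter(model, csc_defaults, "P_sy", (0.0, 0.1), n_points=5)
        out = diagram.plot(tmp_path / "diagram.png", state_label="N_CSC")
        assert out.exists()
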