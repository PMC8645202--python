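"""Invasion fitness, selection gradients, singular points and region maps."""

import math

import numpy as np
import pytest

from castecoevo.colony import (
    ModelParams,
    TraitPair,
    plasticity_equilibrium,
    worker_loss_threshold,
)
from castecoevo.invasion import (
    MutantSpec,
    ResidentInviableError,
    classify_cell,
    classify_region,
    eta_zero_unstable,
    find_singular_points,
    gradient_jacobian,
    integrate_trajectory,
    invasion_fitness,
    mutant_hessian,
    omega_root_at_eta,
    selection_gradient,
    transmission_matrix,
    worker_loss_stable,
)

M_INF = ModelParams(m=None, e=1.0)


class TestNeutralityAndMatrix:
    def test_resident_is_neutral_across_parameter_sweep(self, rng):
        worst = 0.0
        for _ in range(120):
            m = rng.choice([1, 2, 3, 5, 8, None])
            params = ModelParams(
                m=None if m is None else int(m),
                e=rng.uniform(0.05, 2.5),
                f=rng.uniform(0.15, 0.85),
                c=rng.uniform(0.0, 0.9),
                gamma=rng.uniform(0.4, 1.0),
            )
            resident = TraitPair(rng.uniform(0.05, 0.95), rng.uniform(0.02, 0.95))
            lam = invasion_fitness(resident, MutantSpec("omega", 0.0), params)
            worst = max(worst, abs(lam - 1.0))
        assert worst < 1e-10

    def test_matrix_structure(self):
        tm = transmission_matrix(
            TraitPair(0.3, 0.2), MutantSpec("both", (0.01, -0.01)), ModelParams(m=3, e=0.8)
        )
        A = tm.as_array()
        assert A[1, 1] == 0.0  # no father-to-son transmission under arrhenotoky
        assert (A >= 0).all()

    def test_inviable_resident_raises(self):
        with pytest.raises(ResidentInviableError):
            invasion_fitness(
                TraitPair(0.0, 0.0), MutantSpec("omega", 0.01), ModelParams(m=2, c=0.0)
            )
        # monandrous worker loss without parthenogenesis: conspecific-mated
        # queens have no workers, so no queen channel exists at all
        with pytest.raises(ResidentInviableError):
            selection_gradient(TraitPair(0.0, 0.5), ModelParams(m=1, e=1.0, c=0.0))

    def test_stable_equilibrium_resists_omega_mutants(self):
        # at the caste equilibrium, both mutant directions are non-invading
        # to second order
        for delta in (-0.02, 0.02):
            lam = invasion_fitness(TraitPair(1 / 3, 0.0), MutantSpec("omega", delta), M_INF)
            assert lam <= 1.0 + 1e-12

    def test_hybridization_mutant_invades_when_hybrids_efficient(self):
        lam = invasion_fitness(
            TraitPair(1 / 3, 0.0), MutantSpec("eta", 0.02), ModelParams(m=None, e=0.7)
        )
        assert lam > 1.0


class TestSelectionGradient:
    def test_gradient_zero_at_closed_form_equilibrium(self):
        for eta in (0.0, 0.1, 0.2):
            omega_star = plasticity_equilibrium(eta, 1.0).clipped
            g = selection_gradient(TraitPair(omega_star, eta), M_INF)
            assert abs(g.g_omega) < 1e-6

    @pytest.mark.parametrize("e,eta", [(0.5, 0.0), (0.5, 0.2), (1.0, 0.1), (2.0, 0.1)])
    def test_gradient_root_matches_closed_form(self, e, eta):
        params = ModelParams(m=None, e=e)
        root = omega_root_at_eta(params, eta)
        assert root == pytest.approx(plasticity_equilibrium(eta, e).clipped, abs=1e-6)

    def test_clipped_region_matches_threshold_formula(self):
        for e in (0.5, 1.0, 2.0):
            thr = worker_loss_threshold(e)
            assert omega_root_at_eta(ModelParams(m=None, e=e), thr + 0.02) is None
            below = omega_root_at_eta(ModelParams(m=None, e=e), thr - 0.02)
            assert below is not None and below > 0

    def test_low_efficiency_selects_against_hybridization(self):
        g = selection_gradient(TraitPair(1 / 3, 0.05), ModelParams(m=None, e=0.1))
        assert g.g_eta < 0

    def test_high_efficiency_selects_for_hybridization(self):
        g = selection_gradient(TraitPair(1 / 3, 0.0), ModelParams(m=None, e=0.7))
        assert g.g_eta > 0

    def test_finite_m_baseline_equilibrium(self):
        # independent closed form for the selected omega at eta=0:
        # omega* = (m+1)/(3m+1), derived analytically from the
        # transmission matrix (m=1 -> 1/2, m=2 -> 3/7, m -> inf -> 1/3)
        for m, expected in [(1, 0.5), (2, 3 / 7), (4, 5 / 13)]:
            root = omega_root_at_eta(ModelParams(m=m, e=1.0), 0.0)
            assert root == pytest.approx(expected, abs=1e-8)

    def test_equilibria_do_not_depend_on_f(self):
        roots = [
            omega_root_at_eta(ModelParams(m=None, e=1.0, f=f), 0.2) for f in (0.3, 0.5, 0.7)
        ]
        assert max(roots) - min(roots) < 1e-4
        hats = [
            worker_loss_stable(ModelParams(m=None, e=0.7, f=f)).eta_hat
            for f in (0.3, 0.5, 0.7)
        ]
        assert max(hats) - min(hats) < 1e-4


class TestTrajectories:
    def test_arms_race_reaches_worker_loss(self):
        tr = integrate_trajectory(TraitPair(1 / 3, 0.0), ModelParams(m=None, e=0.7))
        assert tr.endpoint.omega == pytest.approx(0.0, abs=0.01)
        assert tr.endpoint.eta == pytest.approx(2 / 3, abs=0.01)

    def test_low_efficiency_reaches_avoidance(self):
        tr = integrate_trajectory(TraitPair(0.6, 0.5), ModelParams(m=None, e=0.1))
        assert tr.endpoint.omega == pytest.approx(1 / 3, abs=0.01)
        assert tr.endpoint.eta == pytest.approx(0.0, abs=0.01)

    def test_bistable_band_depends_on_initial_conditions(self):
        params = ModelParams(m=None, e=0.4)
        low = integrate_trajectory(TraitPair(0.4, 0.1), params)
        high = integrate_trajectory(TraitPair(0.1, 0.9), params)
        assert low.endpoint.eta == pytest.approx(0.0, abs=0.01)
        assert high.endpoint.omega == pytest.approx(0.0, abs=0.01)
        assert high.endpoint.eta == pytest.approx(2 / 3, abs=0.01)

    def test_states_stay_in_unit_square(self):
        tr = integrate_trajectory(TraitPair(0.9, 0.9), ModelParams(m=None, e=0.7))
        assert (tr.states >= 0).all() and (tr.states <= 1).all()

    def test_step_limit_flagged(self):
        tr = integrate_trajectory(
            TraitPair(0.5, 0.5), ModelParams(m=None, e=0.7), max_steps=3
        )
        assert tr.termination == "step-limit"


class TestSingularPoints:
    def test_interior_repellor_in_bistable_band(self):
        pts = [
            s
            for s in find_singular_points(ModelParams(m=None, e=0.4))
            if s.label != "boundary-state"
        ]
        assert pts, "expected an interior singular point at e=0.4"
        assert any(not s.convergence_stable and s.label == "repellor" for s in pts)

    def test_low_polyandry_interior_attractor_is_ess(self):
        pts = [
            s
            for s in find_singular_points(ModelParams(m=2, e=1.0))
            if s.convergence_stable and s.label != "boundary-state"
        ]
        assert len(pts) == 1
        assert pts[0].label == "attractor-ESS"

    def test_monandry_efficient_hybrids_attractor_branches(self):
        pts = [
            s
            for s in find_singular_points(ModelParams(m=1, e=1.5))
            if s.convergence_stable and s.label != "boundary-state"
        ]
        assert len(pts) == 1
        assert pts[0].label == "attractor-branching"
        H = pts[0].hessian_eigenvalues
        assert max(H) > 0

    def test_branching_is_driven_by_correlational_selection(self):
        # the mixed Hessian term is positive and required for invadability:
        # without it the diagonal terms alone would not make the point invadable
        pts = [
            s
            for s in find_singular_points(ModelParams(m=1, e=1.5))
            if s.convergence_stable and s.label != "boundary-state"
        ]
        H = mutant_hessian(pts[0].location, ModelParams(m=1, e=1.5))
        assert H[0, 1] > 0
        assert max(H[0, 0], H[1, 1]) < 0
        assert np.linalg.eigvalsh(H).max() > 0


class TestWorkerLossAndEtaZero:
    def test_worker_loss_state_infinite_m(self):
        wl = worker_loss_stable(ModelParams(m=None, e=0.7))
        assert wl.viable and wl.stable
        assert wl.eta_hat == pytest.approx(2 / 3, abs=1e-6)

    def test_worker_loss_uninvadable_only_past_quarter(self):
        assert worker_loss_stable(ModelParams(m=None, e=0.3)).stable
        assert not worker_loss_stable(ModelParams(m=None, e=0.2)).stable

    def test_monandry_without_parthenogenesis_inviable(self):
        wl = worker_loss_stable(ModelParams(m=1, e=1.0, c=0.0))
        assert not wl.stable

    def test_monandry_with_parthenogenesis_full_hybridization(self):
        wl = worker_loss_stable(ModelParams(m=1, e=0.9, c=0.4))
        assert wl.viable and wl.stable
        assert wl.eta_hat == pytest.approx(1.0)

    @pytest.mark.parametrize("m", [2, 3, 5])
    def test_full_hybridization_parthenogenesis_condition(self, m):
        # worker loss couples with complete hybridization exactly when
        # c >= (m-1)/(3m-1) under polyandry
        c_star = (m - 1) / (3 * m - 1)
        above = worker_loss_stable(ModelParams(m=m, e=1.0, c=c_star + 0.02))
        below = worker_loss_stable(ModelParams(m=m, e=1.0, c=c_star - 0.02))
        assert above.eta_hat == pytest.approx(1.0)
        assert below.eta_hat < 1.0

    def test_eta_zero_unstable_threshold_infinite_m(self):
        assert eta_zero_unstable(ModelParams(m=None, e=0.7))
        assert not eta_zero_unstable(ModelParams(m=None, e=0.1))
        assert not eta_zero_unstable(ModelParams(m=None, e=0.45))

    def test_worthless_hybrids_never_invade(self):
        for m in (1, 3, None):
            assert not eta_zero_unstable(ModelParams(m=m, e=0.0))
            assert not eta_zero_unstable(ModelParams(m=m, e=0.0, c=0.5))


class TestRegionMaps:
    def test_infinite_m_outcome_bands(self):
        # avoidance for e<=1/4, bistable between, worker loss for e>=1/2
        for e, expected in [
            (0.15, "plasticity-maintained"),
            (0.35, "bistable"),
            (0.7, "worker-loss-always"),
            (1.5, "worker-loss-always"),
        ]:
            assert classify_cell(ModelParams(m=None, e=e)) == expected

    def test_bistable_cell_confirmed_by_trajectories(self):
        assert classify_cell(ModelParams(m=None, e=0.4), confirm_bistable=True) == "bistable"

    def test_internal_attractor_only_at_low_polyandry(self):
        rm = classify_region(
            ("m", [1, 2, 4, 5, 6]),
            ("e", np.arange(0.2, 2.01, 0.15)),
            ModelParams(m=2, e=1.0),
        )
        df = rm.to_frame()
        with_attr = sorted(df.loc[df.outcome == "internal-attractor", "m"].unique())
        assert set(with_attr) <= {1.0, 2.0, 4.0}
        assert 2.0 in with_attr and 5.0 not in with_attr and 6.0 not in with_attr

    def test_worker_loss_cells_satisfy_both_conditions(self):
        rm = classify_region(
            ("m", [2, 4]), ("e", [0.5, 1.0, 1.8]), ModelParams(m=2, e=1.0)
        )
        df = rm.to_frame()
        for _, row in df.iterrows():
            params = ModelParams(m=int(row.m), e=row.e)
            if row.outcome == "worker-loss-always":
                assert worker_loss_stable(params).stable
                assert eta_zero_unstable(params)

    def test_parthenogenesis_map_contains_monandrous_worker_loss(self):
        assert classify_cell(ModelParams(m=1, e=0.9, c=0.4)) == "worker-loss-always"

    def test_diminishing_returns_enlarge_worker_loss_region(self):
        es = np.arange(0.15, 0.9, 0.05)
        def wl_count(gamma):
            n = 0
            for e in es:
                p = ModelParams(m=None, e=e, gamma=gamma)
                if worker_loss_stable(p).stable and eta_zero_unstable(p):
                    n += 1
            return n
        linear = wl_count(1.0)
        diminishing = wl_count(0.7)
        assert diminishing > linear
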