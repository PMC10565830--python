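"""Enthalpy balance, uncertainty propagation and decomposition."""

import numpy as np
import pytest

from calorimd import (
    SystemQuadruple,
    decompose,
    default_study_spec,
    delta_h,
    ensemble_mean,
    gen_component_quadruples,
    gen_quadruple,
    sem_delta_h,
)
from calorimd.calorimetry import group_for_term
from calorimd.energy_io import ROLES, TraceValidationError

from conftest import constant_quadruple, make_ensemble, make_trace


class TestEnsembleMean:
    def test_constant_trajectories(self):
        ens = make_ensemble("complex", [[-10.0] * 4, [-10.0] * 4])
        assert ensemble_mean(ens) == -10.0

    def test_mean_of_means_not_pooled_mean(self):
        """Trajectories weigh equally regardless of length: means 1 (n=4)
        and 3 (n=8) average to 2, not to the pooled 7/3."""
        ens = make_ensemble("complex", [[1.0] * 4, [3.0] * 8])
        assert ensemble_mean(ens) == pytest.approx(2.0)
        assert ensemble_mean(ens, weighting="snapshot") == pytest.approx(7 / 3)

    def test_recovers_common_mean_under_noise(self):
        """20 autocorrelated trajectories around a common mean estimate it
        within 4 analytic SEMs (50 seeds)."""
        from calorimd import OUParams, TrajectoryEnsemble, gen_trace

        mu, sigma, n, k = -50.0, 5.0, 2000, 20
        params = OUParams(mu=mu, sigma=sigma, tau=1.0, dt=0.1)
        phi = params.phi
        sem = sigma * np.sqrt((1 + phi) / ((1 - phi) * n * k))
        bad = 0
        for s in range(50):
            traces = tuple(
                gen_trace(params, n, seed=np.random.SeedSequence(s, spawn_key=(t,)),
                          trajectory_id=f"c-{t}")
                for t in range(k)
            )
            ens = TrajectoryEnsemble(system_role="complex", traces=traces)
            if abs(ensemble_mean(ens) - mu) > 4 * sem:
                bad += 1
        assert bad <= 2


class TestQuadratureSEM:
    def test_zero(self):
        assert sem_delta_h({r: 0.0 for r in ROLES}).combined_sem == 0.0

    def test_three_four_five(self):
        sems = dict(zip(ROLES, [3.0, 4.0, 0.0, 0.0]))
        assert sem_delta_h(sems).combined_sem == pytest.approx(5.0)

    def test_hand_arithmetic(self):
        sems = dict(zip(ROLES, [0.09, 0.05, 0.08, 0.03]))
        assert sem_delta_h(sems).combined_sem == pytest.approx(np.sqrt(0.0179), rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            sem_delta_h(dict(zip(ROLES, [0.1, -0.1, 0.1, 0.1])))

    def test_monotone_in_each_component(self):
        base = dict(zip(ROLES, [0.1, 0.2, 0.3, 0.4]))
        ref = sem_delta_h(base).combined_sem
        for role in ROLES:
            bumped = dict(base, **{role: base[role] + 0.05})
            assert sem_delta_h(bumped).combined_sem > ref


class TestDeltaH:
    def test_equal_means_give_zero(self):
        est = delta_h(constant_quadruple([-55.5] * 4))
        assert est.delta_h == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_component_sum(self, quad_2lqc_like):
        est = delta_h(quad_2lqc_like)
        assert est.delta_h == pytest.approx(-7.63)
        assert est.sem == 0.0
        assert est.n_trajectories == {r: 2 for r in ROLES}

    def test_antisymmetric_under_bound_unbound_swap(self):
        quad = constant_quadruple([-100.0, -50.0, -80.0, -62.37])
        swapped = SystemQuadruple(
            complex=make_ensemble("complex", [[-80.0] * 8, [-80.0] * 8]),
            solvent=make_ensemble("solvent", [[-62.37] * 8, [-62.37] * 8]),
            receptor=make_ensemble("receptor", [[-100.0] * 8, [-100.0] * 8]),
            ligand=make_ensemble("ligand", [[-50.0] * 8, [-50.0] * 8]),
        )
        assert delta_h(swapped).delta_h == pytest.approx(-delta_h(quad).delta_h)

    def test_global_shift_cancels_but_complex_shift_adds(self):
        base = [-100.0, -50.0, -80.0, -62.37]
        ref = delta_h(constant_quadruple(base)).delta_h
        shifted_all = delta_h(constant_quadruple([m + 7.5 for m in base])).delta_h
        # +c on complex and receptor (or on all four) cancels in the balance
        assert shifted_all == pytest.approx(ref, abs=1e-9)
        only_complex = delta_h(
            constant_quadruple([base[0] + 7.5, base[1], base[2], base[3]])
        ).delta_h
        assert only_complex == pytest.approx(ref + 7.5, abs=1e-9)

    def test_mixed_terms_rejected(self):
        with pytest.raises(TraceValidationError, match="term"):
            SystemQuadruple(
                complex=make_ensemble("complex", [[1.0] * 4], term="LJ (SR)"),
                solvent=make_ensemble("solvent", [[1.0] * 4]),
                receptor=make_ensemble("receptor", [[1.0] * 4]),
                ligand=make_ensemble("ligand", [[1.0] * 4]),
            )

    def test_parameter_recovery_on_synthetic_quadruples(self):
        """Estimate +/- 3 SEM covers the construction truth in >= 90% of
        seeds (reduced problem size; the acceptance suite runs the full
        study conditions)."""
        hits = 0
        for s in range(20):
            q = gen_quadruple(default_study_spec(seed=s, n=20_000))
            est = delta_h(q.quadruple)
            if abs(est.delta_h - q.true_delta_h) <= 3 * est.sem:
                hits += 1
        assert hits >= 18


class TestDecomposition:
    def test_all_zero_groups(self):
        quads = {g: constant_quadruple([0.0] * 4, term=g) for g in ("val", "coul", "lj")}
        comps = decompose(quads)
        assert (comps.val, comps.coul, comps.lj) == (0.0, 0.0, 0.0)

    def test_missing_group_named(self):
        quads = {g: constant_quadruple([0.0] * 4, term=g) for g in ("val", "coul")}
        with pytest.raises(ValueError, match="lj"):
            decompose(quads)

    def test_components_sum_to_total_by_construction(self):
        """When per-snapshot val+coul+lj equals the total trace, the
        component enthalpies sum to the total enthalpy to 1e-6 kcal/mol."""
        spec = default_study_spec(seed=3, n=2_000, sigma=5.0)
        quads = gen_component_quadruples(spec)
        comps = decompose({g: quads[g] for g in ("val", "coul", "lj")})
        total = delta_h(quads["total"])
        assert comps.total == pytest.approx(total.delta_h, abs=1e-6)
        assert comps.val_sem >= 0 and comps.coul_sem >= 0 and comps.lj_sem >= 0


def test_gromacs_term_grouping():
    assert group_for_term("Coulomb (SR)") == "coul"
    assert group_for_term("Disp. corr.") == "lj"
    assert group_for_term("Proper Dih.") == "val"
    assert group_for_term("Position Rest.") is None
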