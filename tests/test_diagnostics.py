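"""Convergence profiling, heterogeneity detection, conditional estimates."""

import numpy as np
import pytest

from calorimd import (
    SystemQuadruple,
    conditional_delta_h,
    convergence_profile,
    default_study_spec,
    delta_h,
    gen_quadruple,
    trajectory_heterogeneity,
)
from calorimd.energy_io import ROLES

from conftest import constant_quadruple, make_ensemble, make_trace


class TestConvergenceProfile:
    def test_constant_traces_converge_with_zero_drift(self, quad_2lqc_like):
        prof = convergence_profile(quad_2lqc_like, n_points=10)
        np.testing.assert_allclose(prof.cumulative_delta_h, -7.63)
        assert prof.drift == 0.0
        assert prof.converged

    def test_fraction_one_reproduces_full_estimate(self):
        q = gen_quadruple(default_study_spec(seed=5, n=1_000)).quadruple
        prof = convergence_profile(q, n_points=8)
        est = delta_h(q)
        assert prof.final_value == est.delta_h  # bit-for-bit

    def test_linear_ramp_drift_matches_closed_form(self):
        """A ramp of total amplitude A on the complex only: the cumulative
        mean at fraction f is A*f/2 (cumulative mean of a line through 0),
        so drift over the trailing 20% of a dense grid is A/2 - A*0.9/2 =
        0.05*A up to grid discreteness. With A = 2 kcal/mol that exceeds a
        0.05 tolerance but the profile converges at the default 0.5."""
        n = 10_000
        amplitude = 2.0
        ramp = np.linspace(0.0, amplitude, n)
        quad = SystemQuadruple(
            complex=make_ensemble("complex", [ramp]),
            solvent=make_ensemble("solvent", [[0.0] * 8]),
            receptor=make_ensemble("receptor", [[0.0] * 8]),
            ligand=make_ensemble("ligand", [[0.0] * 8]),
        )
        prof = convergence_profile(quad, n_points=100, window=0.2, tol=0.5)
        # mean of f/2 over f in [0.9, 1] vs 1/2, times amplitude
        expected_drift = amplitude * (0.5 - np.mean(prof.fractions[prof.fractions >= 0.8]) / 2)
        assert prof.drift == pytest.approx(expected_drift, rel=0.05)
        assert prof.converged  # 0.1 kcal/mol < 0.5
        assert not convergence_profile(quad, n_points=100, window=0.9, tol=0.05).converged

    def test_stationary_quadruple_converges(self):
        """Stationary synthetic studies pass the 0.5 kcal/mol drift gate in
        nearly all seeds (reduced size here; acceptance runs full size)."""
        hits = sum(
            convergence_profile(
                gen_quadruple(default_study_spec(seed=s, n=10_000)).quadruple,
                n_points=20,
            ).converged
            for s in range(10)
        )
        assert hits >= 9

    def test_bad_grid_rejected(self, quad_2lqc_like):
        with pytest.raises(ValueError, match="n_points"):
            convergence_profile(quad_2lqc_like, n_points=1)


class TestHeterogeneity:
    def test_identical_means_single_group(self):
        ens = make_ensemble("complex", [[1.0, 1.0]] * 4)
        rep = trajectory_heterogeneity(ens, link_threshold=0.5)
        assert len(rep.groups) == 1
        assert rep.gap == 0.0
        assert not rep.flagged

    def test_two_clusters_found_by_single_linkage(self):
        """Means {0, 0.1, 5, 5.1} at threshold 1 split into two pairs with
        a 4.9 kcal/mol gap."""
        ens = make_ensemble("complex", [[0.0] * 2, [0.1] * 2, [5.0] * 2, [5.1] * 2])
        rep = trajectory_heterogeneity(ens, link_threshold=1.0)
        groups = sorted(sorted(g) for g in rep.groups)
        assert groups == [["complex-0", "complex-1"], ["complex-2", "complex-3"]]
        assert rep.gap == pytest.approx(4.9)
        assert rep.flagged

    def test_invariant_to_relabeling_and_global_shift(self):
        vals = [[0.0] * 2, [0.1] * 2, [5.0] * 2, [5.1] * 2]
        ens = make_ensemble("complex", vals)
        shifted = make_ensemble("complex", [[v + 100.0 for v in t] for t in vals])
        rep = trajectory_heterogeneity(ens, link_threshold=1.0)
        rep2 = trajectory_heterogeneity(shifted, link_threshold=1.0)
        assert [len(g) for g in rep.groups] == [len(g) for g in rep2.groups]
        assert rep2.gap == pytest.approx(rep.gap)

    def test_supplied_groups_used_verbatim(self):
        ens = make_ensemble("complex", [[0.0] * 2, [0.1] * 2, [5.0] * 2, [5.1] * 2])
        rep = trajectory_heterogeneity(
            ens, link_threshold=1.0,
            groups=[["complex-0", "complex-2"], ["complex-1", "complex-3"]],
        )
        assert len(rep.groups) == 2 and rep.flagged

    def test_mixture_detected_and_homogeneous_not(self):
        """An 8 kcal/mol two-state gap in complex-trajectory means is
        flagged; a homogeneous ensemble is not.  Trajectories are long
        enough that each mean is known to ~0.4 kcal/mol, the regime the
        mixture emulates (10-seed spot check; the acceptance suite runs
        the 50-seed version)."""
        det = fp = 0
        for s in range(10):
            mixed = gen_quadruple(
                default_study_spec(seed=s,
                                   complex_state_offsets=((-4.0, 0.5), (4.0, 0.5)))
            )
            det += trajectory_heterogeneity(mixed.quadruple.complex).flagged
            plain = gen_quadruple(default_study_spec(seed=100 + s))
            fp += trajectory_heterogeneity(plain.quadruple.complex).flagged
        assert det >= 9
        assert fp <= 1

    def test_single_trajectory_rejected(self):
        ens = make_ensemble("complex", [[1.0, 2.0]])
        with pytest.raises(ValueError, match="2"):
            trajectory_heterogeneity(ens)


class TestConditionalDeltaH:
    def test_full_subset_is_identity(self, quad_2lqc_like):
        full = {role: list(getattr(quad_2lqc_like, role).trajectory_ids) for role in ROLES}
        est = conditional_delta_h(quad_2lqc_like, full)
        assert est.delta_h == delta_h(quad_2lqc_like).delta_h

    def test_empty_subset_rejected(self, quad_2lqc_like):
        with pytest.raises(ValueError, match="empty"):
            conditional_delta_h(quad_2lqc_like, {"complex": []})

    def test_single_trajectory_per_role_supported(self):
        q = gen_quadruple(default_study_spec(seed=2, n=1_000)).quadruple
        subsets = {role: [getattr(q, role).trajectory_ids[0]] for role in ROLES}
        est = conditional_delta_h(q, subsets)
        assert np.isfinite(est.delta_h)
        assert est.sem > 0
        assert est.n_trajectories == {r: 1 for r in ROLES}

    def test_state_subset_recovers_state_enthalpy(self):
        """Restricting to the trajectories of one injected metastable state
        recovers that state's enthalpy within 3 SEM."""
        spec = default_study_spec(seed=11, n=20_000,
                                  complex_state_offsets=((-2.5, 0.5), (2.5, 0.5)))
        syn = gen_quadruple(spec)
        for state in (0, 1):
            ids = syn.state_subset("complex", state)
            assert len(ids) == 10
            est = conditional_delta_h(syn.quadruple, {"complex": ids})
            truth = spec.conditional_truth({"complex": state})
            assert abs(est.delta_h - truth) <= 3 * est.sem

    def test_partition_recombines_to_full_estimate(self):
        """Group enthalpies recombined with equal-trajectory weights equal
        the full estimate exactly (the ensemble mean is a flat average of
        per-trajectory means)."""
        q = gen_quadruple(default_study_spec(seed=4, n=1_000)).quadruple
        ids = list(q.complex.trajectory_ids)
        parts = [ids[:7], ids[7:12], ids[12:]]
        full = delta_h(q).delta_h
        weighted = sum(
            len(p) * conditional_delta_h(q, {"complex": p}).delta_h for p in parts
        ) / len(ids)
        assert weighted == pytest.approx(full, abs=1e-9)
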