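import numpy as np
import pytest

from calorimd import EnergyTrace, SystemQuadruple, TrajectoryEnsemble
from calorimd.energy_io import ROLES


def make_trace(values, trajectory_id="t0", term="Potential", dt=0.1):
    values = np.asarray(values, dtype=float)
    return EnergyTrace(
        trajectory_id=trajectory_id,
        term=term,
        times=np.arange(len(values)) * dt,
        values=values,
    )


def make_ensemble(role, value_lists, term="Potential"):
    traces = tuple(
        make_trace(v, trajectory_id=f"{role}-{i}", term=term)
        for i, v in enumerate(value_lists)
    )
    return TrajectoryEnsemble(system_role=role, traces=traces)


def constant_quadruple(means, n=8, term="Potential"):
    """Noise-free quadruple with the given per-role means (complex,
    solvent, receptor, ligand)."""
    return SystemQuadruple(
        **{
            role: make_ensemble(role, [[m] * n, [m] * n], term=term)
            for role, m in zip(ROLES, means)
        }
    )


@pytest.fixture
def quad_2lqc_like():
    """Noise-free quadruple whose enthalpy equals -7.63 kcal/mol, the
    component sum of the calmodulin-peptide complex."""
    return constant_quadruple([-100.0, -50.0, -80.0, -62.37])
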