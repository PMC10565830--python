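"""Absolute binding enthalpy by the direct (multibox) method.

The binding enthalpy of a protein-peptide complex is estimated as a balance
of mean potential energies from four separate simulations,

    dH = <E>_complex + <E>_solvent - <E>_receptor - <E>_ligand,

where the bound state is the complex in water plus a matching pure-water
box and the unbound state is the apo receptor in water plus the free
peptide in water.  Atom counts must balance between the two sides so that
force-field self-energies cancel.  The pressure-volume contribution is
negligible at ambient conditions and is not added (a hook exists and
returns zero).

Each ensemble average <E> is the unweighted mean of the K per-trajectory
time averages, so every independent trajectory contributes equally to the
estimate regardless of its length.  Per-system uncertainties come from
reblocking analysis and combine in quadrature, since dH is an additive
combination of four independent mean energies.

The enthalpy decomposes into physical components by applying the same
balance to valence (bond/angle/dihedral), Coulomb, and Lennard-Jones
energy terms separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .blocking import ensemble_sem
from .energy_io import ROLES, SystemQuadruple, TrajectoryEnsemble

__all__ = [
    "COMPONENT_GROUPS",
    "TERM_GROUPS",
    "UncertaintyEstimate",
    "EnergyComponents",
    "EnthalpyEstimate",
    "ensemble_mean",
    "sem_delta_h",
    "delta_h",
    "decompose",
    "pv_correction",
    "group_for_term",
]

logger = logging.getLogger(__name__)

#: The three physical component groups of the enthalpy decomposition.
COMPONENT_GROUPS = ("val", "coul", "lj")

#: Default mapping from GROMACS energy-term labels to component groups.
#: Valence covers bond-stretch, angle-bend and dihedral terms; Coulomb
#: covers short-range and reciprocal-space electrostatics; Lennard-Jones
#: covers short-range LJ plus the dispersion correction.  Restraint terms
#: are deliberately absent and trigger a warning when encountered.
TERM_GROUPS: dict[str, str] = {
    "Bond": "val",
    "Angle": "val",
    "Proper Dih.": "val",
    "Improper Dih.": "val",
    "U-B": "val",
    "Ryckaert-Bell.": "val",
    "Coulomb (SR)": "coul",
    "Coul. recip.": "coul",
    "Coulomb-14": "coul",
    "LJ (SR)": "lj",
    "LJ-14": "lj",
    "Disp. corr.": "lj",
}


def group_for_term(term: str, mapping: Mapping[str, str] | None = None) -> str | None:
    """Component group for a GROMACS term label, or None if unmapped."""
    mapping = TERM_GROUPS if mapping is None else mapping
    group = mapping.get(term)
    if group is None and ("restr" in term.lower() or "restraint" in term.lower()):
        logger.warning("restraint term %r excluded from the decomposition", term)
    return group


@dataclass(frozen=True)
class UncertaintyEstimate:
    """Per-system SEMs and their quadrature combination (kcal/mol)."""

    per_system_sem: dict
    combined_sem: float

    @classmethod
    def from_sems(cls, per_system_sem: Mapping[str, float]) -> "UncertaintyEstimate":
        sems = dict(per_system_sem)
        for role, s in sems.items():
            if s < 0:
                raise ValueError(f"negative SEM for role {role!r}: {s}")
        combined = float(np.sqrt(sum(s * s for s in sems.values())))
        return cls(per_system_sem=sems, combined_sem=combined)


@dataclass(frozen=True)
class EnergyComponents:
    """Valence / Coulomb / Lennard-Jones enthalpy components (kcal/mol)."""

    val: float
    coul: float
    lj: float
    val_sem: float = 0.0
    coul_sem: float = 0.0
    lj_sem: float = 0.0

    @property
    def total(self) -> float:
        return self.val + self.coul + self.lj

    def as_dict(self) -> dict:
        return {
            "val": self.val,
            "coul": self.coul,
            "lj": self.lj,
            "val_sem": self.val_sem,
            "coul_sem": self.coul_sem,
            "lj_sem": self.lj_sem,
        }


@dataclass(frozen=True)
class EnthalpyEstimate:
    """A binding enthalpy with its uncertainty and bookkeeping."""

    delta_h: float
    uncertainty: UncertaintyEstimate
    components: EnergyComponents | None = None
    n_trajectories: dict = field(default_factory=dict)
    n_snapshots: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_h):
            raise ValueError("delta_h must be finite")
        if self.uncertainty.combined_sem < 0:
            raise ValueError("combined SEM must be non-negative")

    @property
    def sem(self) -> float:
        return self.uncertainty.combined_sem

    def __str__(self) -> str:  # e.g. "-7.63 +/- 0.17 kcal/mol"
        return f"{self.delta_h:.2f} +/- {self.sem:.2f} kcal/mol"


def ensemble_mean(ensemble: TrajectoryEnsemble, weighting: str = "trajectory") -> float:
    """Ensemble average energy (kcal/mol).

    ``weighting="trajectory"`` (default) returns the unweighted mean of the
    K per-trajectory means, so short and long trajectories count equally.
    ``weighting="snapshot"`` pools all snapshots instead (grand mean); the
    two coincide when all trajectories have equal length.
    """
    if weighting == "trajectory":
        return float(np.mean([t.mean for t in ensemble.traces]))
    if weighting == "snapshot":
        total = sum(float(np.sum(t.values)) for t in ensemble.traces)
        return total / ensemble.n_snapshots
    raise ValueError(f"unknown weighting {weighting!r}")


def sem_delta_h(per_system_sem: Mapping[str, float]) -> UncertaintyEstimate:
    """Quadrature combination of the four per-system SEMs.

    combined = sqrt(sigma_complex^2 + sigma_solvent^2 + sigma_receptor^2 +
    sigma_ligand^2); valid because the four simulations are independent and
    dH is an additive combination of their mean energies.
    """
    return UncertaintyEstimate.from_sems(per_system_sem)


def pv_correction() -> float:
    """Pressure-volume work contribution to the binding enthalpy.

    Negligible for condensed-phase binding at ambient pressure; returns 0.
    Kept as an explicit hook so the assumption is visible and overridable.
    """
    return 0.0


def delta_h(
    quadruple: SystemQuadruple,
    sem_strategy: str = "max",
    sem_mode: str = "pooled",
    weighting: str = "trajectory",
) -> EnthalpyEstimate:
    """Binding enthalpy of a four-system quadruple with propagated SEM.

    Parameters
    ----------
    quadruple:
        Validated four-ensemble system sharing a single energy term.
    sem_strategy:
        Blocking-curve selection rule, ``"max"`` (conservative default) or
        ``"heuristic"`` (optimal-block-size criterion).
    sem_mode:
        ``"pooled"`` reblocks the concatenated trajectories per system;
        ``"per_trajectory"`` reblocks each trajectory and combines.
    """
    means = {role: ensemble_mean(getattr(quadruple, role), weighting) for role in ROLES}
    # grouped as bound minus unbound so that swapping the two sides flips
    # the sign bitwise exactly
    dh = (
        (means["complex"] + means["solvent"])
        - (means["receptor"] + means["ligand"])
        + pv_correction()
    )
    sems = {
        role: ensemble_sem(getattr(quadruple, role), strategy=sem_strategy, mode=sem_mode)
        for role in ROLES
    }
    return EnthalpyEstimate(
        delta_h=dh,
        uncertainty=sem_delta_h(sems),
        n_trajectories={r: getattr(quadruple, r).n_trajectories for r in ROLES},
        n_snapshots={r: getattr(quadruple, r).n_snapshots for r in ROLES},
    )


def decompose(
    quadruples: Mapping[str, SystemQuadruple],
    sem_strategy: str = "max",
    sem_mode: str = "pooled",
) -> EnergyComponents:
    """Valence / Coulomb / LJ enthalpy components from per-group quadruples.

    ``quadruples`` maps each group in ``("val", "coul", "lj")`` to a
    quadruple built from that group's energy traces.  The enthalpy balance
    is applied independently per group; each component carries its own
    quadrature SEM.  When the per-snapshot component traces sum to the
    total-potential traces, the components sum to the total enthalpy.
    """
    missing = [g for g in COMPONENT_GROUPS if g not in quadruples]
    if missing:
        raise ValueError(f"missing component group(s): {missing}")
    parts = {
        g: delta_h(quadruples[g], sem_strategy=sem_strategy, sem_mode=sem_mode)
        for g in COMPONENT_GROUPS
    }
    return EnergyComponents(
        val=parts["val"].delta_h,
        coul=parts["coul"].delta_h,
        lj=parts["lj"].delta_h,
        val_sem=parts["val"].sem,
        coul_sem=parts["coul"].sem,
        lj_sem=parts["lj"].sem,
    )
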