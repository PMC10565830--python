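"""Reading, validation and unit normalisation of per-trajectory energy series.

The direct (multibox) enthalpy method consumes scalar potential-energy time
series recorded during MD production runs of four system types: the
protein-peptide complex in water, a matching pure-water box, the apo receptor
in water, and the free peptide in water.  This module turns GROMACS XVG
energy files (or generic delimited tables) into validated
:class:`EnergyTrace` objects, groups them into per-system
:class:`TrajectoryEnsemble` collections, and assembles the four ensembles
into a :class:`SystemQuadruple` whose mean energies combine into the binding
enthalpy.

All energies are stored internally in kcal/mol; GROMACS emits kJ/mol, which
is converted on read with the exact factor 4.184 kJ per kcal.  Times are
assumed to be in picoseconds unless stated otherwise.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KJ_PER_KCAL",
    "ROLES",
    "EnergyTrace",
    "TrajectoryEnsemble",
    "SystemQuadruple",
    "EnergyFormatError",
    "EnergyParseError",
    "TraceValidationError",
    "read_xvg",
    "read_table",
    "write_xvg",
    "write_table",
    "build_quadruple",
]

logger = logging.getLogger(__name__)

#: Exact thermochemical conversion factor.
KJ_PER_KCAL = 4.184

#: The four system roles of the direct method, in the sign order of the
#: enthalpy balance: bound state (complex + solvent) minus unbound state
#: (receptor + ligand).
ROLES = ("complex", "solvent", "receptor", "ligand")

_TIME_TOL = 1e-6  # relative tolerance on uniform time spacing


class EnergyFormatError(ValueError):
    """File structure does not match the expected dialect (e.g. a missing
    energy-term column)."""


class EnergyParseError(ValueError):
    """A data row could not be interpreted as numbers."""


class TraceValidationError(ValueError):
    """Trace content violates an invariant (non-finite values, non-uniform
    or non-increasing time stamps, too few points)."""


def _to_kcal(values: np.ndarray, unit: str) -> np.ndarray:
    unit = unit.strip().lower().replace(" ", "")
    if unit in ("kcal/mol", "kcal"):
        return values
    if unit in ("kj/mol", "kj"):
        return values / KJ_PER_KCAL
    raise EnergyFormatError(f"unknown energy unit {unit!r}; expected kJ/mol or kcal/mol")


@dataclass(frozen=True)
class EnergyTrace:
    """One trajectory's scalar energy time series for a single energy term.

    Values are always held in kcal/mol; ``source_unit`` records the unit of
    the file the trace was read from (or generated in).
    """

    trajectory_id: str
    term: str
    times: np.ndarray
    values: np.ndarray
    source_unit: str = "kcal/mol"
    sampling_interval: float = field(default=0.0)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or times.ndim != 1:
            raise TraceValidationError("times and values must be 1-D")
        if len(values) != len(times):
            raise TraceValidationError(
                f"times ({len(times)}) and values ({len(values)}) differ in length"
            )
        if len(values) < 2:
            raise TraceValidationError("a trace needs at least 2 snapshots")
        if not np.all(np.isfinite(values)):
            raise TraceValidationError("non-finite energy values")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise TraceValidationError("time stamps must be strictly increasing")
        dt0 = float(np.median(dt))
        if np.max(np.abs(dt - dt0)) > _TIME_TOL * max(abs(dt0), 1.0):
            raise TraceValidationError(
                f"non-uniform time spacing (median {dt0} ps, "
                f"max deviation {np.max(np.abs(dt - dt0))})"
            )
        if self.sampling_interval == 0.0:
            object.__setattr__(self, "sampling_interval", dt0)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        """Time average of this trajectory (kcal/mol)."""
        return float(np.mean(self.values))

    def truncated(self, n: int) -> "EnergyTrace":
        """First ``n`` snapshots, for cumulative-convergence profiling."""
        n = max(2, min(n, len(self)))
        return replace(self, times=self.times[:n], values=self.values[:n])


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """The set of independent trajectories simulated for one system role.

    All traces must report the same energy term; trajectory ids are unique.
    ``atom_count`` supports the atom-balance check of the four-box setup and
    may be omitted.
    """

    system_role: str
    traces: tuple
    atom_count: int | None = None

    def __post_init__(self) -> None:
        if self.system_role not in ROLES:
            raise TraceValidationError(
                f"unknown system role {self.system_role!r}; expected one of {ROLES}"
            )
        traces = tuple(self.traces)
        object.__setattr__(self, "traces", traces)
        if not traces:
            raise TraceValidationError(f"ensemble {self.system_role!r} has no traces")
        terms = {t.term for t in traces}
        if len(terms) > 1:
            raise TraceValidationError(
                f"ensemble {self.system_role!r} mixes energy terms {sorted(terms)}"
            )
        ids = [t.trajectory_id for t in traces]
        if len(set(ids)) != len(ids):
            raise TraceValidationError(
                f"duplicate trajectory ids in ensemble {self.system_role!r}"
            )
        if self.atom_count is not None and self.atom_count < 0:
            raise TraceValidationError("atom_count must be non-negative")
        lengths = {len(t) for t in traces}
        if len(lengths) > 1:
            logger.warning(
                "ensemble %s: trajectories of unequal length %s; each still "
                "contributes one unweighted per-trajectory mean",
                self.system_role,
                sorted(lengths),
            )

    @property
    def term(self) -> str:
        return self.traces[0].term

    @property
    def n_trajectories(self) -> int:
        return len(self.traces)

    @property
    def n_snapshots(self) -> int:
        return int(sum(len(t) for t in self.traces))

    @property
    def trajectory_ids(self) -> tuple:
        return tuple(t.trajectory_id for t in self.traces)

    def trajectory_means(self) -> dict:
        return {t.trajectory_id: t.mean for t in self.traces}

    def subset(self, ids: Iterable[str]) -> "TrajectoryEnsemble":
        wanted = list(ids)
        if not wanted:
            raise TraceValidationError(
                f"empty trajectory subset for role {self.system_role!r}"
            )
        known = set(self.trajectory_ids)
        missing = [i for i in wanted if i not in known]
        if missing:
            raise TraceValidationError(
                f"unknown trajectory ids for role {self.system_role!r}: {missing}"
            )
        keep = set(wanted)
        return replace(
            self, traces=tuple(t for t in self.traces if t.trajectory_id in keep)
        )


@dataclass(frozen=True)
class SystemQuadruple:
    """The four trajectory ensembles whose mean energies form the enthalpy
    balance: complex + solvent (bound side) vs receptor + ligand (unbound)."""

    complex: TrajectoryEnsemble
    solvent: TrajectoryEnsemble
    receptor: TrajectoryEnsemble
    ligand: TrajectoryEnsemble

    def __post_init__(self) -> None:
        for role in ROLES:
            ens = getattr(self, role)
            if ens.system_role != role:
                raise TraceValidationError(
                    f"ensemble with role {ens.system_role!r} supplied for {role!r}"
                )
        terms = {getattr(self, role).term for role in ROLES}
        if len(terms) > 1:
            raise TraceValidationError(f"roles mix energy terms {sorted(terms)}")
        counts = [getattr(self, role).atom_count for role in ROLES]
        if all(c is not None for c in counts):
            bound = self.complex.atom_count + self.solvent.atom_count
            unbound = self.receptor.atom_count + self.ligand.atom_count
            if bound != unbound:
                raise TraceValidationError(
                    "atom counts do not balance between bound and unbound "
                    f"states: complex+solvent = {bound}, receptor+ligand = {unbound}"
                )

    @property
    def term(self) -> str:
        return self.complex.term

    def ensembles(self) -> dict:
        return {role: getattr(self, role) for role in ROLES}

    def restrict(self, subsets: Mapping[str, Iterable[str]]) -> "SystemQuadruple":
        """New quadruple keeping only the named trajectories per role; roles
        absent from ``subsets`` keep their full ensemble."""
        parts = {}
        for role in ROLES:
            ens = getattr(self, role)
            parts[role] = ens.subset(subsets[role]) if role in subsets else ens
        return SystemQuadruple(**parts)


# ---------------------------------------------------------------------------
# readers / writers

_LEGEND_RE = re.compile(r"^@\s*s(\d+)\s+legend\s+\"(.*)\"")
_YAXIS_RE = re.compile(r"^@\s*yaxis\s+label\s+\"(.*)\"")


def read_xvg(
    path,
    column=None,
    unit: str | None = None,
    trajectory_id: str | None = None,
    stride: int | None = None,
) -> EnergyTrace:
    """Read one energy term from a GROMACS XVG (Grace) energy file.

    Parameters
    ----------
    path:
        XVG file.  Lines beginning with ``#`` are comments, ``@`` are Grace
        plot metadata; ``@ sN legend "name"`` lines name the data series.
        Data rows are whitespace-separated numbers with time (ps) first.
    column:
        Energy-term selector: a legend name (e.g. ``"Potential"``,
        ``"Coulomb (SR)"``) or a 0-based series index.  May be omitted when
        the file holds a single series.
    unit:
        Energy unit of the file.  Default: taken from the y-axis label when
        it mentions kJ or kcal, else kJ/mol (the GROMACS convention).
    stride:
        Optional subsampling step applied after reading (default: none).
    """
    path = Path(path)
    legends: dict[int, str] = {}
    yaxis = None
    data_rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("@"):
                m = _LEGEND_RE.match(line)
                if m:
                    legends[int(m.group(1))] = m.group(2)
                m = _YAXIS_RE.match(line)
                if m:
                    yaxis = m.group(1)
                continue
            try:
                data_rows.append([float(x) for x in line.split()])
            except ValueError as exc:
                raise EnergyParseError(
                    f"{path.name}:{lineno}: non-numeric data row: {line!r}"
                ) from exc
    if not data_rows:
        raise EnergyFormatError(f"{path.name}: no data rows")
    widths = {len(r) for r in data_rows}
    if len(widths) > 1:
        raise EnergyParseError(f"{path.name}: ragged rows with widths {sorted(widths)}")
    data = np.asarray(data_rows, dtype=float)
    n_series = data.shape[1] - 1
    if n_series < 1:
        raise EnergyFormatError(f"{path.name}: no energy columns after the time column")

    if column is None:
        if n_series != 1:
            available = [legends.get(i, f"s{i}") for i in range(n_series)]
            raise EnergyFormatError(
                f"{path.name}: {n_series} series present, a column selector is "
                f"required; available terms: {available}"
            )
        idx = 0
    elif isinstance(column, int):
        if not 0 <= column < n_series:
            raise EnergyFormatError(
                f"{path.name}: series index {column} out of range 0..{n_series - 1}"
            )
        idx = column
    else:
        by_name = {name: i for i, name in legends.items()}
        if column not in by_name:
            available = [legends.get(i, f"s{i}") for i in range(n_series)]
            raise EnergyFormatError(
                f"{path.name}: no series named {column!r}; available terms: {available}"
            )
        idx = by_name[column]

    term = legends.get(idx, column if isinstance(column, str) else f"s{idx}")
    if unit is None:
        unit = "kJ/mol"
        if yaxis is not None:
            low = yaxis.lower()
            if "kcal" in low:
                unit = "kcal/mol"
            elif "kj" in low:
                unit = "kJ/mol"
    times = data[:, 0]
    values = _to_kcal(data[:, idx + 1], unit)
    if stride is not None and stride > 1:
        times, values = times[::stride], values[::stride]
    return EnergyTrace(
        trajectory_id=trajectory_id or path.stem,
        term=term,
        times=times,
        values=values,
        source_unit=unit,
    )


def read_table(path, config: Mapping | None = None, **overrides) -> EnergyTrace:
    """Read an energy trace from a delimited text table (CSV or TSV).

    ``config`` (or keyword overrides) names the relevant columns and unit:
    ``time_column`` (default: first column), ``value_column`` (default:
    second column), ``unit`` (default kcal/mol), ``term``, ``trajectory_id``,
    ``stride``.
    """
    path = Path(path)
    cfg = dict(config or {})
    cfg.update(overrides)
    import csv as _csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, _csv.Error) as exc:
        raise EnergyFormatError(f"{path.name}: empty or undelimited file") from exc
    if df.empty:
        raise EnergyFormatError(f"{path.name}: no data rows")
    time_col = cfg.get("time_column", df.columns[0])
    value_col = cfg.get("value_column", df.columns[1] if len(df.columns) > 1 else None)
    for col in (time_col, value_col):
        if col is None or col not in df.columns:
            raise EnergyFormatError(
                f"{path.name}: column {col!r} not found; available: {list(df.columns)}"
            )
    unit = cfg.get("unit", "kcal/mol")
    times = df[time_col].to_numpy(dtype=float)
    values = _to_kcal(df[value_col].to_numpy(dtype=float), unit)
    stride = cfg.get("stride")
    if stride is not None and stride > 1:
        times, values = times[::stride], values[::stride]
    return EnergyTrace(
        trajectory_id=cfg.get("trajectory_id", path.stem),
        term=cfg.get("term", str(value_col)),
        times=times,
        values=values,
        source_unit=unit,
    )


def write_xvg(trace: EnergyTrace, path, unit: str = "kJ/mol") -> None:
    """Write a trace as a GROMACS-style XVG file (values in ``unit``)."""
    values = trace.values
    if unit.lower().startswith("kj"):
        values = values * KJ_PER_KCAL
    elif not unit.lower().startswith("kcal"):
        raise EnergyFormatError(f"unknown output unit {unit!r}")
    with open(path, "w") as fh:
        fh.write(f"# trajectory {trace.trajectory_id}\n")
        fh.write('@    title "Energies"\n')
        fh.write('@    xaxis  label "Time (ps)"\n')
        fh.write(f'@    yaxis  label "({unit})"\n')
        fh.write(f'@ s0 legend "{trace.term}"\n')
        for t, v in zip(trace.times, values):
            fh.write(f"{t:.6f}  {v:.10e}\n")


def write_table(trace: EnergyTrace, path, delimiter: str = ",") -> None:
    """Write a trace as a two-column delimited table in kcal/mol."""
    df = pd.DataFrame({"time_ps": trace.times, trace.term: trace.values})
    df.to_csv(path, sep=delimiter, index=False, float_format="%.10e")


def build_quadruple(
    traces_by_role: Mapping[str, Sequence[EnergyTrace]],
    atom_counts: Mapping[str, int] | None = None,
) -> SystemQuadruple:
    """Assemble per-role trace collections into a validated quadruple.

    When ``atom_counts`` provides all four roles, the atom balance
    atoms(complex) + atoms(solvent) == atoms(receptor) + atoms(ligand) is
    enforced; otherwise a warning is logged and the check is skipped.
    """
    missing = [r for r in ROLES if r not in traces_by_role or not traces_by_role[r]]
    if missing:
        raise TraceValidationError(f"missing traces for roles: {missing}")
    counts = atom_counts or {}
    if any(counts.get(role) is None for role in ROLES):
        logger.warning(
            "atom counts absent for at least one role; atom-balance "
            "invariant of the four-box setup not checked"
        )
    ensembles = {
        role: TrajectoryEnsemble(
            system_role=role,
            traces=tuple(traces_by_role[role]),
            atom_count=counts.get(role),
        )
        for role in ROLES
    }
    units = {e.traces[0].source_unit for e in ensembles.values()}
    if len(units) > 1:
        raise TraceValidationError(f"roles mix source units {sorted(units)}")
    return SystemQuadruple(**ensembles)
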