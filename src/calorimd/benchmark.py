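"""Benchmarking computed enthalpies against experimental ITC values.

Ships a transcription of the experimental isothermal-titration-calorimetry
binding enthalpies for the 11-complex nonredundant protein-peptide test set
(with printed uncertainties and literature citations), together with the
corresponding valence / Coulomb / Lennard-Jones enthalpy components, and
computes the customary summary metrics: per-complex differences, the count
within a 2 kcal/mol accuracy band, RMSE, R^2 and per-component Pearson
correlations with experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ITCRecord",
    "BenchmarkReport",
    "load_fixtures",
    "compare",
    "component_correlation",
]


@dataclass(frozen=True)
class ITCRecord:
    """One complex's experimental calorimetric binding enthalpy."""

    pdb_id: str
    exp_delta_h: float  # kcal/mol
    exp_sem: float  # kcal/mol, as printed
    temperature: float | None = None  # deg C; not always reported
    reference: str = ""

    def __post_init__(self) -> None:
        if not (len(self.pdb_id) == 4 and self.pdb_id.isalnum()
                and self.pdb_id == self.pdb_id.upper()):
            raise ValueError(f"not a PDB code: {self.pdb_id!r}")
        if self.exp_sem < 0:
            raise ValueError("experimental SEM must be non-negative")


@dataclass(frozen=True)
class BenchmarkReport:
    """Per-complex calculated-vs-experimental comparison with summary metrics.

    ``r_squared`` is the squared Pearson correlation of calculated vs
    experimental values (set ``definition="identity"`` in :func:`compare`
    for the coefficient of determination about the equivalence line, which
    additionally penalises systematic offset).  Experimental uncertainties
    are carried in the table but do not weight the metrics.
    """

    per_complex: pd.DataFrame  # pdb_id, calc, exp, diff, within_limit
    limit: float
    rmse: float
    r_squared: float | None
    pearson_by_component: dict

    @property
    def n_within_limit(self) -> int:
        return int(self.per_complex["within_limit"].sum())


def _data(name: str) -> pd.DataFrame:
    with resources.files("calorimd.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_fixtures():
    """The bundled benchmark tables.

    Returns
    -------
    records : list of ITCRecord
        Experimental ITC enthalpies for the 11 complexes.
    components : pandas.DataFrame
        Val/Coul/LJ enthalpy components with their printed SEMs, indexed
        like the records by ``pdb_id``.
    """
    itc = _data("itc_benchmark.csv")
    records = [
        ITCRecord(
            pdb_id=row.pdb_id,
            exp_delta_h=float(row.dh_exp),
            exp_sem=float(row.dh_exp_sem),
            temperature=None if pd.isna(row.temperature_c) else float(row.temperature_c),
            reference=row.reference,
        )
        for row in itc.itertuples()
    ]
    components = _data("enthalpy_components.csv")
    return records, components


def compare(
    calc: Mapping[str, float],
    records: Sequence[ITCRecord],
    limit: float = 2.0,
    components: pd.DataFrame | None = None,
    definition: str = "pearson",
) -> BenchmarkReport:
    """Compare calculated enthalpies with the experimental records.

    Parameters
    ----------
    calc:
        Map of pdb_id -> calculated enthalpy (kcal/mol); keys must be a
        subset of the record ids.
    limit:
        Accuracy band half-width (kcal/mol, default 2): a complex counts as
        correctly predicted when |calc - exp| <= limit.
    components:
        Optional component table (as from :func:`load_fixtures`); when
        given, per-component Pearson correlations with experiment are
        included.
    definition:
        ``"pearson"`` (default) or ``"identity"`` for R^2 (see
        :class:`BenchmarkReport`).
    """
    by_id = {r.pdb_id: r for r in records}
    unknown = [k for k in calc if k not in by_id]
    if unknown:
        raise KeyError(f"calculated values for unknown complexes: {unknown}")
    rows = []
    for pdb_id, c in calc.items():
        e = by_id[pdb_id].exp_delta_h
        rows.append(
            {
                "pdb_id": pdb_id,
                "calc": float(c),
                "exp": e,
                "exp_sem": by_id[pdb_id].exp_sem,
                "diff": float(c) - e,
                "within_limit": abs(float(c) - e) <= limit,
            }
        )
    table = pd.DataFrame(rows).sort_values("pdb_id").reset_index(drop=True)
    rmse = float(np.sqrt(np.mean(np.square(table["diff"]))))
    if len(table) >= 2 and table["calc"].nunique() > 1 and table["exp"].nunique() > 1:
        if definition == "pearson":
            r2 = float(stats.pearsonr(table["calc"], table["exp"]).statistic ** 2)
        elif definition == "identity":
            ss_res = float(np.sum(np.square(table["diff"])))
            ss_tot = float(np.sum(np.square(table["exp"] - table["exp"].mean())))
            r2 = 1.0 - ss_res / ss_tot
        else:
            raise ValueError(f"unknown R^2 definition {definition!r}")
    else:
        r2 = None
    pearson = {}
    if components is not None:
        for which in ("val", "coul", "lj"):
            pearson[which] = component_correlation(components, records, which)
    return BenchmarkReport(
        per_complex=table,
        limit=limit,
        rmse=rmse,
        r_squared=r2,
        pearson_by_component=pearson,
    )


def component_correlation(
    components: pd.DataFrame,
    records: Sequence[ITCRecord],
    which: str,
) -> float | None:
    """Pearson correlation between one enthalpy component and experiment.

    Returns None (rather than 0) when either column is constant or fewer
    than 3 paired values exist; callers should report it as absent.
    """
    if which not in ("val", "coul", "lj"):
        raise ValueError(f"unknown component {which!r}")
    exp = {r.pdb_id: r.exp_delta_h for r in records}
    paired = components[components["pdb_id"].isin(exp)]
    if len(paired) < 3:
        return None
    x = paired[which].to_numpy(dtype=float)
    y = np.array([exp[p] for p in paired["pdb_id"]])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)
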