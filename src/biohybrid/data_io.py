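"""CSV/JSON readers and writers with column-by-column schema validation.

Formats: UTF-8 CSV with a header row and '.' decimal separator; models
and kinetic parameters as flat JSON.  Malformed inputs are rejected with
the offending column names or row indices.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .kinetics import BatchConditions, SpeciesState, Trajectory
from .synthetic_data import DigestionRecord

__all__ = [
    "SchemaError",
    "TRAJECTORY_COLUMNS",
    "CONDITIONS_COLUMNS",
    "DIGESTION_COLUMNS",
    "write_trajectories",
    "read_trajectories",
    "write_digestion",
    "read_digestion",
    "write_ranking",
]

#: fixed float formatting so identical data give byte-identical files
FLOAT_FORMAT = "%.12g"

TRAJECTORY_COLUMNS = ("run_id", "t_h", "T_molL", "Et_molL", "EO_molL", "P_molL")
CONDITIONS_COLUMNS = (
    "run_id",
    "e0_t0",
    "Et0_T0",
    "W0",
    "omega",
    "T0_Hex0",
    "T0_molL",
    "Et0_molL",
    "e0_gL",
)
DIGESTION_COLUMNS = (
    "run_id",
    "manure_pct",
    "ojw_pct",
    "pH0",
    "COD0_gL",
    "CN0",
    "day",
    "methane_L_STP",
)


class SchemaError(ValueError):
    """Input file violates the expected tabular schema."""


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad or coerced.isna().any():
            rows = bad or df.index[coerced.isna()].tolist()
            raise SchemaError(f"{path}: non-numeric or missing values in '{col}' at rows {rows[:10]}")
        df[col] = coerced
    return df


def write_trajectories(traj_path, cond_path, trajectories: Sequence[Trajectory]) -> None:
    """Write a campaign as a trajectory CSV plus a conditions CSV keyed by run."""
    rows, conds = [], []
    for traj in trajectories:
        c = traj.conditions
        conds.append(
            {
                "run_id": c.run_id,
                "e0_t0": c.e0_t0,
                "Et0_T0": c.Et0_T0,
                "W0": c.W0,
                "omega": c.omega,
                "T0_Hex0": c.T0_Hex0,
                "T0_molL": c.T0,
                "Et0_molL": c.Et0,
                "e0_gL": c.e0,
            }
        )
        for s in traj.states:
            rows.append(
                {
                    "run_id": c.run_id,
                    "t_h": s.t,
                    "T_molL": s.T,
                    "Et_molL": s.Et,
                    "EO_molL": s.EO,
                    "P_molL": s.P,
                }
            )
    pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).to_csv(
        traj_path, index=False, float_format=FLOAT_FORMAT
    )
    pd.DataFrame(conds, columns=CONDITIONS_COLUMNS).to_csv(
        cond_path, index=False, float_format=FLOAT_FORMAT
    )


def read_trajectories(traj_path, cond_path) -> list:
    """Read a trajectory CSV + conditions CSV back into Trajectory objects."""
    tdf = _read_csv(traj_path, TRAJECTORY_COLUMNS)
    cdf = _read_csv(cond_path, CONDITIONS_COLUMNS)
    for col in ("T_molL", "Et_molL", "EO_molL", "P_molL"):
        neg = tdf.index[tdf[col] < -1e-12].tolist()
        if neg:
            raise SchemaError(
                f"{traj_path}: negative concentration in '{col}' at rows {neg[:10]}"
            )
    conditions = {}
    for _, row in cdf.iterrows():
        conditions[int(row.run_id)] = BatchConditions(
            e0_t0=row.e0_t0,
            Et0_T0=row.Et0_T0,
            W0=row.W0,
            omega=int(row.omega),
            T0_Hex0=row.T0_Hex0,
            T0=row.T0_molL,
            Et0=row.Et0_molL,
            e0=row.e0_gL,
            run_id=int(row.run_id),
        )
    trajectories = []
    for run_id, grp in tdf.groupby("run_id", sort=True):
        run_id = int(run_id)
        if run_id not in conditions:
            raise SchemaError(f"{traj_path}: run {run_id} has no conditions row")
        grp = grp.sort_values("t_h")
        states = tuple(
            SpeciesState(r.T_molL, r.Et_molL, r.EO_molL, r.P_molL, r.t_h)
            for r in grp.itertuples()
        )
        trajectories.append(Trajectory(conditions[run_id], states))
    return trajectories


def write_digestion(path, records: Sequence[DigestionRecord]) -> None:
    rows = [
        {
            "run_id": r.run_id,
            "manure_pct": r.manure_pct,
            "ojw_pct": r.ojw_pct,
            "pH0": r.pH0,
            "COD0_gL": r.COD0,
            "CN0": r.CN0,
            "day": r.day,
            "methane_L_STP": r.methane_L,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=DIGESTION_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_digestion(path) -> list:
    df = _read_csv(path, DIGESTION_COLUMNS)
    neg = df.index[df.methane_L_STP < 0].tolist()
    if neg:
        raise SchemaError(f"{path}: negative cumulative methane at rows {neg[:10]}")
    return [
        DigestionRecord(
            run_id=int(r.run_id),
            ojw_pct=r.ojw_pct,
            pH0=r.pH0,
            COD0=r.COD0_gL,
            CN0=r.CN0,
            day=r.day,
            methane_L=r.methane_L_STP,
            manure_pct=r.manure_pct,
        )
        for r in df.itertuples()
    ]


def write_ranking(path, results: Sequence) -> None:
    """Write a ranked scenario table (ScenarioResult list, best first)."""
    rows = []
    for rank, res in enumerate(results, start=1):
        p1, p2, p3 = res.scenario.ojw_by_period
        i1, i2, i3 = res.per_period_increments
        rows.append(
            {
                "scenario_p1": p1,
                "scenario_p2": p2,
                "scenario_p3": p3,
                "increment_p1": i1,
                "increment_p2": i2,
                "increment_p3": i3,
                "cumulative_L": res.cumulative_methane_L,
                "rank": rank,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)
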