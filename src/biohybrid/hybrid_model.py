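"""Hybrid neural model of the transesterification batch.

The mechanistic Ping-Pong Bi-Bi rate law needs the co-species (ethanol,
ester, glyceride pool) expressed as functions of triolein.  Instead of
the empirical 2.25-slope linear correlation, a 6-10-3-1 perceptron
(ANN_1) learns ester formation from the run's operating conditions plus
the instantaneous triolein consumption dT = T0 - T, and that network is
wired into the kinetic integration as the closure — a continuous
exchange between the theoretical and neural blocks.  Ethanol then
follows from 1:1 ester stoichiometry and the pool from exact mass
balance, so all four species stay mutually consistent.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from .kinetics import BatchConditions, KineticParams, Trajectory, integrate_batch
from .neural_net import (
    MLPModel,
    SupervisedSet,
    TrainResult,
    ann1_architecture,
    make_split,
    train_bayes,
)

__all__ = [
    "ANN1_FEATURES",
    "HNM",
    "ann1_features",
    "build_ann1_dataset",
    "hybrid_closure",
    "simulate_hnm",
    "train_hnm",
]

#: fixed input ordering of ANN_1
ANN1_FEATURES = ("e0_t0", "Et0_T0", "W0", "omega", "T0_Hex0", "dT")

# reference split of the 144-point campaign: 70 train / 24 test / 50 validation
_SPLIT_FRACTIONS = (70 / 144, 24 / 144)


def ann1_features(conditions: BatchConditions, dT: float) -> np.ndarray:
    if dT < -1e-12:
        raise ValueError("triolein consumption dT must be nonnegative")
    return np.array(
        [
            conditions.e0_t0,
            conditions.Et0_T0,
            conditions.W0,
            float(conditions.omega),
            conditions.T0_Hex0,
            max(dT, 0.0),
        ]
    )


def build_ann1_dataset(trajectories: Sequence[Trajectory], seed: int = 0) -> SupervisedSet:
    """One row per (run, time): conditions + dT -> ester formed EO(t) - EO(0).

    144 rows split 70/24/50 (train/test/validation); other sizes use the
    same proportions.  Assignment is a seeded random permutation.
    """
    rows, targets, run_ids, times = [], [], [], []
    for traj in trajectories:
        conds = traj.conditions
        for s in traj.states:
            rows.append(ann1_features(conds, conds.T0 - s.T))
            targets.append(s.EO - traj.states[0].EO)
            run_ids.append(conds.run_id)
            times.append(s.t)
    n = len(rows)
    if n < 10:
        raise ValueError(f"need at least 10 rows to build a dataset, got {n}")
    if n == 144:
        n_train, n_test = 70, 24
    else:
        n_train = int(round(n * _SPLIT_FRACTIONS[0]))
        n_test = int(round(n * _SPLIT_FRACTIONS[1]))
    train, test, val = make_split(n, n_train, n_test, seed)
    return SupervisedSet(
        X=np.array(rows),
        y=np.array(targets),
        train_idx=train,
        test_idx=test,
        val_idx=val,
        feature_names=ANN1_FEATURES,
        meta={"run_id": np.array(run_ids), "t_h": np.array(times)},
    )


@dataclasses.dataclass
class HNM:
    """Kinetic constants plus the trained ester-formation network."""

    params: KineticParams
    ann1: MLPModel

    def __post_init__(self) -> None:
        sizes = self.ann1.architecture.layer_sizes
        if sizes[0] != 6 or sizes[-1] != 1:
            raise ValueError("ANN_1 must map 6 inputs to 1 output")


def hybrid_closure(ann1: MLPModel, conditions: BatchConditions) -> Callable:
    """Closure T -> (Et, EO, P) with network-predicted ester formation.

    EO = max(0, ANN_1(conditions, T0 - T)); P = T0 - T exactly;
    Et = max(0, Et0 - EO) by 1:1 stoichiometry.  Deterministic and
    side-effect free.
    """

    base = ann1_features(conditions, 0.0)

    def closure(T: float):
        dT = min(max(conditions.T0 - T, 0.0), conditions.T0)
        x = base.copy()
        x[5] = dT
        EO = max(float(ann1.forward(x)), 0.0)
        return (max(conditions.Et0 - EO, 0.0), EO, dT)

    return closure


def simulate_hnm(hnm: HNM, conditions: BatchConditions, t_grid) -> Trajectory:
    """Integrate the kinetic ODE with the neural closure for one run."""
    return integrate_batch(conditions, hnm.params, hybrid_closure(hnm.ann1, conditions), t_grid)


def train_hnm(
    trajectories: Sequence[Trajectory],
    params: KineticParams,
    seed: int = 0,
    max_epochs: int = 300,
) -> tuple[HNM, TrainResult]:
    """Build the ANN_1 dataset from a campaign, train it, assemble the HNM."""
    data = build_ann1_dataset(trajectories, seed=seed)
    result = train_bayes(ann1_architecture(), data, max_epochs=max_epochs, seed=seed)
    return HNM(params=params, ann1=result.model), result
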