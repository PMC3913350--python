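"""Grid search over piecewise feed-composition strategies.

The 28-day digestion batch is cut into three periods (days 1-9, 10-19,
20-28); at each period start the orange-juice-waste fraction of the feed
may be set to one of a few levels, giving |options|^3 scenarios (64 for
the canonical {0, 10, 15, 20}% grid).  Each scenario is scored by the
cumulative-productivity model: the increment earned in a period is the
model's prediction at the period end minus at the period start, both
evaluated at that period's composition, clamped nonnegative; scenario
productivity is the sum of the three increments.  The model was trained
on constant-composition batches, so this per-period increment convention
is an interpretation — the scoring function is pluggable.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Callable, Mapping, Sequence

from .digestion_model import predict_cumulative
from .neural_net import MLPModel
from .synthetic_data import initial_state_map

__all__ = [
    "FEED_OPTIONS",
    "PERIOD_BOUNDS",
    "FeedScenario",
    "ScenarioResult",
    "enumerate_scenarios",
    "default_mixture_map",
    "scenario_productivity",
    "best_scenario",
]

#: canonical OJW mass-percent options at each period start
FEED_OPTIONS = (0.0, 10.0, 15.0, 20.0)

#: (start, end) days of the three feed periods
PERIOD_BOUNDS = ((0.0, 9.0), (9.0, 19.0), (19.0, 28.0))


@dataclasses.dataclass(frozen=True)
class FeedScenario:
    """OJW mass % chosen for each of the three batch periods."""

    ojw_by_period: tuple

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "ojw_by_period", tuple(float(v) for v in self.ojw_by_period)
        )


@dataclasses.dataclass(frozen=True)
class ScenarioResult:
    scenario: FeedScenario
    cumulative_methane_L: float
    per_period_increments: tuple

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.per_period_increments):
            raise ValueError("per-period increments must be nonnegative")
        if abs(self.cumulative_methane_L - sum(self.per_period_increments)) > 1e-9:
            raise ValueError("cumulative must equal the sum of increments")


def enumerate_scenarios(
    options: Sequence[float] = FEED_OPTIONS, n_periods: int = 3
) -> list:
    """Full Cartesian product in deterministic lexicographic order."""
    if not options:
        raise ValueError("options must be nonempty")
    opts = sorted(set(float(v) for v in options))
    return [FeedScenario(combo) for combo in itertools.product(opts, repeat=n_periods)]


def default_mixture_map(ojw_pct: float) -> dict:
    """Initial-state inputs (pH0, COD0, CN0) for a feed OJW%, interpolated
    between the pure-manure and high-OJW anchor states of the campaign."""
    return initial_state_map(ojw_pct)


def _as_predict_fn(model) -> Callable[[Mapping, float], float]:
    if isinstance(model, MLPModel):
        return lambda conds, day: predict_cumulative(model, conds, day)
    if callable(model):
        return model
    raise TypeError("model must be an MLPModel or a predict(conds, day) callable")


def scenario_productivity(
    model,
    scenario: FeedScenario,
    mixture_map: Callable[[float], Mapping] = default_mixture_map,
) -> ScenarioResult:
    """Score one feed scenario with the cumulative-productivity model."""
    predict = _as_predict_fn(model)
    increments = []
    for ojw, (t_start, t_end) in zip(scenario.ojw_by_period, PERIOD_BOUNDS):
        conds = dict(mixture_map(ojw))
        conds["ojw_pct"] = ojw
        inc = predict(conds, t_end) - predict(conds, t_start)
        increments.append(max(inc, 0.0))
    return ScenarioResult(
        scenario=scenario,
        cumulative_methane_L=sum(increments),
        per_period_increments=tuple(increments),
    )


def best_scenario(
    model,
    scenarios: Sequence[FeedScenario],
    mixture_map: Callable[[float], Mapping] = default_mixture_map,
) -> tuple:
    """Exhaustive argmax over scenarios; returns (best, full ranked table).

    Ties go to the lexicographically smallest composition triple.  The
    table is sorted by descending productivity with the same tie-break.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("scenarios must be nonempty")
    results = [scenario_productivity(model, s, mixture_map) for s in scenarios]
    table = sorted(
        results, key=lambda r: (-r.cumulative_methane_L, r.scenario.ojw_by_period)
    )
    return table[0], table
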