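"""Model inputs: utilities, state probabilities, per-strategy parameter sets.

Two small derivations produce the decision-tree inputs from primary data:

* state utilities accrue a base annual utility weight plus a per-state
  decrement over the whole simulation horizon,
  ``u_i = (base + decrement_i) * horizon`` (QALYs);
* state probabilities are the per-state shares of all recorded medical
  visits, ``p_i = count_i / sum(counts)``.

Strategy parameter tables are exchanged as CSV/JSON with one row per
(strategy, state) and columns ``strategy, state, cost_cny, probability,
utility_qaly``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .states import N_STATES, STATE_LABELS

__all__ = [
    "UtilityModel",
    "StrategyParams",
    "WTPThreshold",
    "derive_state_utilities",
    "probabilities_from_visit_counts",
    "load_strategy_table",
    "write_strategy_table",
]

#: Tolerance on sum(p) == 1 for probabilities copied from a 4-decimal table.
TABLE_PROB_TOL = 5e-4
#: Tolerance on sum(p) == 1 for probabilities derived from counts.
DERIVED_PROB_TOL = 1e-9


@dataclass(frozen=True)
class UtilityModel:
    """Annual utility weights and the simulation horizon.

    Parameters
    ----------
    base_utility : float
        Utility weight per year of the reference (symptom-free) state,
        dimensionless in [0, 1].
    decrements : tuple of float
        Additive utility decrement per state (state order:
        hospitalization, outpatient exacerbation, symptom-free).
        Non-positive for the exacerbation states, 0 for symptom-free.
    horizon_years : float
        Simulation time horizon in years.
    discount_rate : float
        Annual discount rate on utilities. Reserved; the default model is
        undiscounted.
    """

    base_utility: float = 0.867
    decrements: tuple[float, float, float] = (-0.22, -0.1, 0.0)
    horizon_years: float = 18.0
    discount_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_utility <= 1.0:
            raise ValueError("base_utility must be in [0, 1]")
        if len(self.decrements) != N_STATES:
            raise ValueError(f"need exactly {N_STATES} decrements")
        for d in self.decrements:
            if not -1.0 <= self.base_utility + d <= 1.0:
                raise ValueError("base_utility + decrement outside [-1, 1]")
        if self.horizon_years <= 0:
            raise ValueError("horizon must be positive")
        if self.discount_rate != 0.0:
            raise NotImplementedError("only the undiscounted model is supported")

    def state_utilities(self) -> np.ndarray:
        return derive_state_utilities(self)


def derive_state_utilities(model: UtilityModel) -> np.ndarray:
    """Per-state utilities over the horizon, in QALYs.

    ``u_i = (base_utility + decrement_i) * horizon_years``.

    Raises
    ------
    ValueError
        If any resulting utility is negative ("utility below zero"),
        which signals a decrement inconsistent with the base utility.
    """
    u = (model.base_utility + np.asarray(model.decrements, dtype=float)) * model.horizon_years
    if np.any(u < 0):
        raise ValueError("utility below zero: decrement inconsistent with base utility")
    return u


def probabilities_from_visit_counts(counts: Sequence[int]) -> np.ndarray:
    """State probabilities as per-state shares of all visits.

    Parameters
    ----------
    counts : sequence of int
        Non-negative visit counts, one per state in state order.

    Returns
    -------
    ndarray
        ``p_i = count_i / sum(counts)``; sums to 1 up to float rounding.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (N_STATES,):
        raise ValueError(f"need exactly {N_STATES} counts")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("empty cohort: all visit counts are zero")
    return c / total


@dataclass(frozen=True)
class StrategyParams:
    """Decision-tree parameters for one treatment strategy.

    One cost, one probability and one utility per health state, in state
    order (hospitalization, outpatient exacerbation, symptom-free).
    """

    label: str
    state_costs: tuple[float, float, float]
    state_probs: tuple[float, float, float]
    state_utilities: tuple[float, float, float]
    cost_basis: str = "medication"
    prob_tol: float = field(default=TABLE_PROB_TOL, compare=False)

    def __post_init__(self) -> None:
        for name in ("state_costs", "state_probs", "state_utilities"):
            v = getattr(self, name)
            if len(v) != N_STATES:
                raise ValueError(f"incomplete strategy: {name} needs {N_STATES} entries")
        if any(c < 0 for c in self.state_costs):
            raise ValueError("costs must be non-negative")
        if any(not 0.0 <= p <= 1.0 for p in self.state_probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.state_probs) - 1.0) > self.prob_tol:
            raise ValueError(
                "probability normalization: state probabilities sum to "
                f"{sum(self.state_probs):.6f}, not 1"
            )
        if any(u < 0 for u in self.state_utilities):
            raise ValueError("utilities must be non-negative")

    @property
    def costs(self) -> np.ndarray:
        return np.asarray(self.state_costs, dtype=float)

    @property
    def probs(self) -> np.ndarray:
        return np.asarray(self.state_probs, dtype=float)

    @property
    def utilities(self) -> np.ndarray:
        return np.asarray(self.state_utilities, dtype=float)

    @classmethod
    def from_visit_counts(
        cls,
        label: str,
        counts: Sequence[int],
        state_costs: Sequence[float],
        utility_model: UtilityModel | None = None,
        cost_basis: str = "medication",
    ) -> "StrategyParams":
        """Build a parameter set from visit counts and per-state costs."""
        um = utility_model or UtilityModel()
        probs = probabilities_from_visit_counts(counts)
        return cls(
            label=label,
            state_costs=tuple(float(c) for c in state_costs),
            state_probs=tuple(float(p) for p in probs),
            state_utilities=tuple(float(u) for u in um.state_utilities()),
            cost_basis=cost_basis,
            prob_tol=DERIVED_PROB_TOL * 10,
        )


@dataclass(frozen=True)
class WTPThreshold:
    """Willingness-to-pay threshold in CNY per QALY."""

    value: float = 287_100.0
    basis: str = "3x 2024 per-capita GDP of China (95,700 CNY)"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("WTP threshold must be positive")


# ---------------------------------------------------------------------------
# serialization

_COLUMNS = ["strategy", "state", "cost_cny", "probability", "utility_qaly"]


def _params_from_frame(df: pd.DataFrame, cost_basis: str) -> list[StrategyParams]:
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"strategy table missing columns: {sorted(missing)}")
    out: list[StrategyParams] = []
    for label, grp in df.groupby("strategy", sort=False):
        grp = grp.set_index("state")
        if set(grp.index) != set(STATE_LABELS):
            raise ValueError(f"incomplete strategy {label!r}: need one row per state")
        grp = grp.loc[list(STATE_LABELS)]
        out.append(
            StrategyParams(
                label=str(label),
                state_costs=tuple(float(x) for x in grp["cost_cny"]),
                state_probs=tuple(float(x) for x in grp["probability"]),
                state_utilities=tuple(float(x) for x in grp["utility_qaly"]),
                cost_basis=cost_basis,
            )
        )
    return out


def load_strategy_table(source: str | Path, cost_basis: str = "medication") -> list[StrategyParams]:
    """Read strategy parameters from a CSV or JSON file.

    The CSV dialect has one row per (strategy, state) with columns
    ``strategy, state, cost_cny, probability, utility_qaly``; the JSON
    dialect is the same records under a top-level ``strategies`` list.
    """
    path = Path(source)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload["strategies"])
    else:
        df = pd.read_csv(path)
    return _params_from_frame(df, cost_basis)


def write_strategy_table(
    strategies: Iterable[StrategyParams], target: str | Path
) -> Path:
    """Write strategy parameters as CSV or JSON (by file suffix)."""
    rows = []
    for s in strategies:
        for i, state in enumerate(STATE_LABELS):
            rows.append(
                {
                    "strategy": s.label,
                    "state": state,
                    "cost_cny": s.state_costs[i],
                    "probability": s.state_probs[i],
                    "utility_qaly": s.state_utilities[i],
                }
            )
    path = Path(target)
    df = pd.DataFrame(rows, columns=_COLUMNS)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"strategies": rows}, indent=1))
    else:
        df.to_csv(path, index=False)
    return path
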