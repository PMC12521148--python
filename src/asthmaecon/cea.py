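"""Cost-effectiveness analysis.

Effectiveness is the percentage of patients whose longest symptom-free
duration reached a threshold (E3, E6, E12, E24 at 3/6/12/24 months).  The
cost-effectiveness ratio divides a strategy's average cost by that
percentage figure (units: CNY per percentage point); the incremental
ratio ICER = dC/dE compares two strategies, and pairs where one arm is
both cheaper and more effective are classified as dominance rather than
interpreted through the ratio.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dominance",
    "EffectivenessTable",
    "CEAResult",
    "ComparisonResult",
    "effectiveness_rates",
    "cost_effectiveness_ratio",
    "icer",
    "classify_dominance",
    "cea_table",
    "CostEffectivenessAnalysis",
    "CEAResults",
]


class Dominance(str, enum.Enum):
    """Quadrant classification of an incremental comparison."""

    ALT_DOMINATES = "alt_dominates"  # alternative cheaper and at least as effective
    REF_DOMINATES = "ref_dominates"  # reference cheaper and at least as effective
    TRADEOFF = "tradeoff"            # more effect at more cost (or less at less)
    EQUIVALENT = "equivalent"        # identical cost and effect


@dataclass(frozen=True)
class EffectivenessTable:
    """Exceedance rates of the longest symptom-free duration.

    ``rate_percent[k]`` is ``100 * (#patients with duration >= thresholds[k]) / n``.
    Rates are non-increasing in the threshold.
    """

    thresholds: tuple[float, ...]
    rate_percent: tuple[float, ...]
    n: int

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.rate_percent):
            raise ValueError("thresholds and rates differ in length")
        if any(t2 <= t1 for t1, t2 in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if any(r2 > r1 + 1e-9 for r1, r2 in zip(self.rate_percent, self.rate_percent[1:])):
            raise ValueError("exceedance rates must be non-increasing")
        if any(not 0.0 <= r <= 100.0 for r in self.rate_percent):
            raise ValueError("rates must lie in [0, 100]")

    def rate_at(self, threshold: float) -> float:
        try:
            i = self.thresholds.index(threshold)
        except ValueError:
            raise KeyError(f"no rate recorded at threshold {threshold}") from None
        return self.rate_percent[i]


@dataclass(frozen=True)
class CEAResult:
    """A cost-effectiveness ratio: cost per percentage point of effect."""

    cost: float
    effect_percent: float
    ratio: float


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental comparison of an alternative against a reference.

    ``ratio`` is dC/dE (ICER when the effect is a percentage, ICUR when it
    is QALYs) and is ``None`` when the effect difference is zero.  A bare
    negative ratio is never interpreted on its own: ``dominance`` carries
    the quadrant (a negative ratio can mean either "cheaper and more
    effective" or "costlier and less effective").
    """

    ref_label: str
    alt_label: str
    delta_cost: float
    delta_effect: float
    ratio: float | None
    dominance: Dominance
    effect_units: str = "percent"
    cost_effective_at_wtp: bool | None = None


def classify_dominance(delta_cost: float, delta_effect: float) -> Dominance:
    """Quadrant of (dC, dE) for alternative minus reference."""
    if delta_cost == 0 and delta_effect == 0:
        return Dominance.EQUIVALENT
    if delta_cost <= 0 and delta_effect >= 0:
        return Dominance.ALT_DOMINATES
    if delta_cost >= 0 and delta_effect <= 0:
        return Dominance.REF_DOMINATES
    return Dominance.TRADEOFF


def effectiveness_rates(
    longest_durations: Sequence[float], thresholds: Sequence[float] = (3, 6, 12, 24)
) -> EffectivenessTable:
    """Exceedance rates (percent) of longest symptom-free durations.

    Parameters
    ----------
    longest_durations : sequence of float
        One longest symptom-free duration (months, >= 0) per patient.
    thresholds : sequence of float
        Strictly increasing duration thresholds in months.
    """
    d = np.asarray(longest_durations, dtype=float)
    if d.size == 0:
        raise ValueError("empty cohort")
    if np.any(d < 0):
        raise ValueError("durations must be non-negative")
    t = np.asarray(thresholds, dtype=float)
    rates = tuple(100.0 * float(np.count_nonzero(d >= tk)) / d.size for tk in t)
    return EffectivenessTable(tuple(float(x) for x in t), rates, int(d.size))


def cost_effectiveness_ratio(cost: float, effect_percent: float) -> CEAResult:
    """C/E ratio in CNY per percentage point of effectiveness."""
    if effect_percent <= 0:
        raise ZeroDivisionError("undefined ratio: effectiveness rate is zero")
    return CEAResult(cost=cost, effect_percent=effect_percent, ratio=cost / effect_percent)


def icer(
    ref: tuple[float, float],
    alt: tuple[float, float],
    ref_label: str = "ref",
    alt_label: str = "alt",
) -> ComparisonResult:
    """Incremental cost-effectiveness ratio of ``alt`` against ``ref``.

    Each argument is a ``(cost, effect_percent)`` pair.  The ratio is left
    undefined (``None``) when the effects are equal.
    """
    dc = alt[0] - ref[0]
    de = alt[1] - ref[1]
    ratio = dc / de if de != 0 else None
    return ComparisonResult(
        ref_label=ref_label,
        alt_label=alt_label,
        delta_cost=dc,
        delta_effect=de,
        ratio=ratio,
        dominance=classify_dominance(dc, de),
    )


def cea_table(
    strategies: Sequence[tuple[str, float, EffectivenessTable]],
    comparisons: Iterable[tuple[str, str]] = (),
) -> pd.DataFrame:
    """C/E ratios for every strategy and ICERs for every requested pair.

    Parameters
    ----------
    strategies : sequence of (label, cost, EffectivenessTable)
    comparisons : iterable of (ref_label, alt_label)

    Returns
    -------
    DataFrame
        One row per quantity (``CE`` block then ``ICER`` block), one
        column per duration threshold; ICER cells are NaN where the
        effect difference is zero.
    """
    labels = [lab for lab, _, _ in strategies]
    if len(set(labels)) != len(labels):
        raise ValueError("strategy labels must be unique")
    by_label = {lab: (cost, eff) for lab, cost, eff in strategies}
    thresholds = strategies[0][2].thresholds
    for _, _, eff in strategies:
        if eff.thresholds != thresholds:
            raise ValueError("all strategies must share the threshold grid")

    rows = []
    for lab, cost, eff in strategies:
        row: dict[str, object] = {"block": "CE", "strategy": lab, "cost": cost}
        for t, r in zip(eff.thresholds, eff.rate_percent):
            row[f"E{t:g}"] = cost / r if r > 0 else np.nan
        rows.append(row)
    for ref_lab, alt_lab in comparisons:
        for lab in (ref_lab, alt_lab):
            if lab not in by_label:
                raise KeyError(f"unknown strategy label {lab!r}")
        (c_ref, e_ref), (c_alt, e_alt) = by_label[ref_lab], by_label[alt_lab]
        row = {"block": "ICER", "strategy": f"{alt_lab} vs {ref_lab}", "cost": c_alt - c_ref}
        for t in thresholds:
            de = e_alt.rate_at(t) - e_ref.rate_at(t)
            row[f"E{t:g}"] = (c_alt - c_ref) / de if de != 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


class CostEffectivenessAnalysis:
    """Cost-effectiveness model over a set of strategies.

    Parameters
    ----------
    strategies : sequence of (label, cost, EffectivenessTable)
        Average cost and effectiveness-rate table per strategy.
    comparisons : iterable of (ref_label, alt_label), optional
        Incremental comparisons to evaluate; the reference should be the
        cheaper arm (the convention followed by `fit`'s ICER block).
    """

    def __init__(
        self,
        strategies: Sequence[tuple[str, float, EffectivenessTable]],
        comparisons: Iterable[tuple[str, str]] = (),
    ) -> None:
        self.strategies = list(strategies)
        self.comparisons = list(comparisons)
        labels = [lab for lab, _, _ in self.strategies]
        if len(set(labels)) != len(labels):
            raise ValueError("strategy labels must be unique")

    @classmethod
    def from_durations(
        cls,
        cohorts: dict[str, Sequence[float]],
        costs: dict[str, float],
        thresholds: Sequence[float] = (3, 6, 12, 24),
        comparisons: Iterable[tuple[str, str]] = (),
    ) -> "CostEffectivenessAnalysis":
        """Build from per-strategy longest symptom-free durations."""
        strategies = [
            (lab, costs[lab], effectiveness_rates(durs, thresholds))
            for lab, durs in cohorts.items()
        ]
        return cls(strategies, comparisons)

    def fit(self) -> "CEAResults":
        table = cea_table(self.strategies, self.comparisons)
        by_label = {lab: (cost, eff) for lab, cost, eff in self.strategies}
        comparisons = []
        thresholds = self.strategies[0][2].thresholds
        for ref_lab, alt_lab in self.comparisons:
            (c_ref, e_ref), (c_alt, e_alt) = by_label[ref_lab], by_label[alt_lab]
            for t in thresholds:
                res = icer(
                    (c_ref, e_ref.rate_at(t)),
                    (c_alt, e_alt.rate_at(t)),
                    ref_label=ref_lab,
                    alt_label=alt_lab,
                )
                comparisons.append((t, res))
        return CEAResults(self, table, comparisons)


class CEAResults:
    """Fitted cost-effectiveness results with a printable summary table."""

    def __init__(
        self,
        model: CostEffectivenessAnalysis,
        table: pd.DataFrame,
        comparisons: list[tuple[float, ComparisonResult]],
    ) -> None:
        self.model = model
        self.table = table
        self.comparisons = comparisons

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def summary(self, float_format: str = "{:.2f}") -> str:
        df = self.table.copy()
        value_cols = [c for c in df.columns if c.startswith("E")] + ["cost"]
        for c in value_cols:
            df[c] = df[c].map(lambda x: "-" if pd.isna(x) else float_format.format(x))
        lines = ["Cost-effectiveness analysis (CNY per percentage point)", ""]
        lines.append(df.to_string(index=False))
        return "\n".join(lines)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path
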