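"""Decision-tree cost-utility analysis.

Each strategy is a single-decision tree with three chance branches — the
health states — so its expected cost and expected utility are probability-
weighted sums over the states:

    E[C] = sum_i p_i c_i        (CNY)
    E[U] = sum_i p_i u_i        (QALYs over the simulation horizon)

Incremental cost-utility ratios ICUR = dC/dU between two strategies are
judged against a willingness-to-pay threshold; net monetary benefit
NMB = lambda * E[U] - E[C] gives the equivalent ranking at a threshold.
Strategies evaluated on different cost bases (ICS-only versus total
medication cost) are kept apart and cannot be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cea import ComparisonResult, Dominance, classify_dominance
from .parameters import StrategyParams, WTPThreshold

__all__ = [
    "StrategyResult",
    "evaluate_strategy",
    "icur",
    "nmb",
    "cua_report",
    "DecisionTreeCUA",
    "CUAResults",
]


@dataclass(frozen=True)
class StrategyResult:
    """Expected cost (CNY) and expected utility (QALYs) of one strategy."""

    label: str
    expected_cost: float
    expected_utility: float
    cost_basis: str = "medication"


def evaluate_strategy(params: StrategyParams) -> StrategyResult:
    """Expected cost and utility of the three-branch decision tree.

    ``E[C] = sum_i p_i c_i`` and ``E[U] = sum_i p_i u_i``; both lie between
    the smallest and largest per-state value.
    """
    p = params.probs
    return StrategyResult(
        label=params.label,
        expected_cost=float(p @ params.costs),
        expected_utility=float(p @ params.utilities),
        cost_basis=params.cost_basis,
    )


def _check_basis(ref: StrategyResult, alt: StrategyResult) -> None:
    if ref.cost_basis != alt.cost_basis:
        raise ValueError(
            f"mismatched cost basis: {ref.cost_basis!r} vs {alt.cost_basis!r}; "
            "results from different bases cannot be compared"
        )


def icur(
    ref: StrategyResult, alt: StrategyResult, wtp: WTPThreshold | None = None
) -> ComparisonResult:
    """Incremental cost-utility ratio of ``alt`` against ``ref``.

    The ratio dC/dU is undefined (``None``) when the utilities are equal.
    The dominance quadrant is always reported alongside the ratio: a
    negative ICUR alone does not say which arm is preferred.  When a
    willingness-to-pay threshold is given, a tradeoff pair with dU > 0 is
    flagged cost-effective iff ICUR < lambda (dominant pairs are
    cost-effective by construction).
    """
    _check_basis(ref, alt)
    dc = alt.expected_cost - ref.expected_cost
    du = alt.expected_utility - ref.expected_utility
    ratio = dc / du if du != 0 else None
    dominance = classify_dominance(dc, du)
    verdict: bool | None = None
    if wtp is not None:
        if dominance == Dominance.ALT_DOMINATES:
            verdict = True
        elif dominance == Dominance.REF_DOMINATES:
            verdict = False
        elif dominance == Dominance.TRADEOFF and du > 0:
            verdict = bool(ratio < wtp.value)
        elif dominance == Dominance.TRADEOFF:
            # less utility at less cost: alt acceptable iff savings per QALY
            # forgone exceed the threshold
            verdict = bool(ratio > wtp.value)
    return ComparisonResult(
        ref_label=ref.label,
        alt_label=alt.label,
        delta_cost=dc,
        delta_effect=du,
        ratio=ratio,
        dominance=dominance,
        effect_units="QALY",
        cost_effective_at_wtp=verdict,
    )


def nmb(result: StrategyResult, wtp: WTPThreshold) -> float:
    """Net monetary benefit ``lambda * E[U] - E[C]`` in CNY.

    For any pair with dU > 0, ``nmb(alt) > nmb(ref)`` iff the pair's
    ICUR is below the threshold.
    """
    return wtp.value * result.expected_utility - result.expected_cost


def cua_report(
    strategies: Sequence[StrategyParams],
    pairs: Iterable[tuple[str, str]] = (),
    wtp: WTPThreshold | None = None,
) -> pd.DataFrame:
    """Tabular cost-utility report: strategy block plus pairwise block.

    One row per strategy (expected cost and utility) followed by one row
    per (ref, alt) pair (incremental cost, incremental utility, ICUR,
    dominance, WTP verdict).
    """
    labels = [s.label for s in strategies]
    if len(set(labels)) != len(labels):
        raise ValueError("strategy labels must be unique")
    results = {s.label: evaluate_strategy(s) for s in strategies}
    rows: list[dict[str, object]] = []
    for lab in labels:
        r = results[lab]
        rows.append(
            {
                "row": "strategy",
                "label": lab,
                "expected_cost": r.expected_cost,
                "expected_utility": r.expected_utility,
                "delta_cost": np.nan,
                "delta_utility": np.nan,
                "icur": np.nan,
                "dominance": "",
                "cost_effective": "",
            }
        )
    for ref_lab, alt_lab in pairs:
        for lab in (ref_lab, alt_lab):
            if lab not in results:
                raise KeyError(f"unknown strategy label {lab!r}")
        cmp = icur(results[ref_lab], results[alt_lab], wtp)
        rows.append(
            {
                "row": "comparison",
                "label": f"{alt_lab} vs {ref_lab}",
                "expected_cost": np.nan,
                "expected_utility": np.nan,
                "delta_cost": cmp.delta_cost,
                "delta_utility": cmp.delta_effect,
                "icur": cmp.ratio if cmp.ratio is not None else np.nan,
                "dominance": cmp.dominance.value,
                "cost_effective": "" if cmp.cost_effective_at_wtp is None
                else ("yes" if cmp.cost_effective_at_wtp else "no"),
            }
        )
    return pd.DataFrame(rows)


class DecisionTreeCUA:
    """Three-state decision-tree cost-utility model over a set of strategies.

    Parameters
    ----------
    strategies : sequence of StrategyParams
        All on the same cost basis.
    pairs : iterable of (ref_label, alt_label), optional
        Incremental comparisons; conventionally ref is the cheaper arm.
    wtp : WTPThreshold, optional
        Willingness-to-pay threshold used for verdicts and NMB.
    """

    def __init__(
        self,
        strategies: Sequence[StrategyParams],
        pairs: Iterable[tuple[str, str]] = (),
        wtp: WTPThreshold | None = None,
    ) -> None:
        self.strategies = list(strategies)
        bases = {s.cost_basis for s in self.strategies}
        if len(bases) > 1:
            raise ValueError(f"strategies mix cost bases: {sorted(bases)}")
        self.cost_basis = next(iter(bases)) if bases else "medication"
        self.pairs = list(pairs)
        self.wtp = wtp or WTPThreshold()

    @classmethod
    def from_strategy_table(
        cls,
        source: str | Path,
        pairs: Iterable[tuple[str, str]] = (),
        wtp: WTPThreshold | None = None,
        cost_basis: str = "medication",
    ) -> "DecisionTreeCUA":
        """Build the model from a strategy parameter CSV/JSON file."""
        from .parameters import load_strategy_table

        return cls(load_strategy_table(source, cost_basis), pairs, wtp)

    def fit(self) -> "CUAResults":
        """Evaluate every strategy and every requested comparison."""
        results = [evaluate_strategy(s) for s in self.strategies]
        by_label = {r.label: r for r in results}
        comparisons = []
        for ref_lab, alt_lab in self.pairs:
            for lab in (ref_lab, alt_lab):
                if lab not in by_label:
                    raise KeyError(f"unknown strategy label {lab!r}")
            comparisons.append(icur(by_label[ref_lab], by_label[alt_lab], self.wtp))
        return CUAResults(self, results, comparisons)


class CUAResults:
    """Fitted decision-tree results: expected values, ICURs, NMB ranking."""

    def __init__(
        self,
        model: DecisionTreeCUA,
        strategy_results: list[StrategyResult],
        comparisons: list[ComparisonResult],
    ) -> None:
        self.model = model
        self.strategy_results = strategy_results
        self.comparisons = comparisons

    def __getitem__(self, label: str) -> StrategyResult:
        for r in self.strategy_results:
            if r.label == label:
                return r
        raise KeyError(label)

    def nmb(self, label: str, wtp: WTPThreshold | None = None) -> float:
        return nmb(self[label], wtp or self.model.wtp)

    def nmb_ranking(self, wtp: WTPThreshold | None = None) -> list[str]:
        """Strategy labels ordered by decreasing net monetary benefit."""
        w = wtp or self.model.wtp
        return sorted(
            (r.label for r in self.strategy_results),
            key=lambda lab: self.nmb(lab, w),
            reverse=True,
        )

    def to_frame(self) -> pd.DataFrame:
        return cua_report(
            self.model.strategies, self.model.pairs, self.model.wtp
        )

    def summary(self) -> str:
        df = self.to_frame()
        strat = df[df["row"] == "strategy"]
        comp = df[df["row"] == "comparison"]
        lines = [
            f"Decision-tree cost-utility analysis ({self.model.cost_basis} cost basis)",
            f"WTP threshold: {self.model.wtp.value:,.0f} CNY/QALY",
            "",
            "Strategy              E[cost] CNY    E[utility] QALY",
        ]
        for _, r in strat.iterrows():
            lines.append(
                f"  {r['label']:<18}{r['expected_cost']:>12.2f}{r['expected_utility']:>16.4f}"
            )
        if len(comp):
            lines += ["", "Comparison            dC CNY     dU QALY        ICUR  dominance  CE@WTP"]
            for _, r in comp.iterrows():
                icur_s = "-" if pd.isna(r["icur"]) else f"{r['icur']:.2f}"
                lines.append(
                    f"  {r['label']:<18}{r['delta_cost']:>9.2f}{r['delta_utility']:>12.4f}"
                    f"{icur_s:>12}  {r['dominance']:<10} {r['cost_effective']}"
                )
        return "\n".join(lines)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def to_json(self) -> dict:
        """JSON-ready export of strategy results and comparisons."""
        return {
            "cost_basis": self.model.cost_basis,
            "wtp_cny_per_qaly": self.model.wtp.value,
            "strategies": [
                {
                    "label": r.label,
                    "expected_cost": r.expected_cost,
                    "expected_utility": r.expected_utility,
                }
                for r in self.strategy_results
            ],
            "comparisons": [
                {
                    "ref": c.ref_label,
                    "alt": c.alt_label,
                    "delta_cost": c.delta_cost,
                    "delta_utility": c.delta_effect,
                    "icur": c.ratio,
                    "dominance": c.dominance.value,
                    "cost_effective_at_wtp": c.cost_effective_at_wtp,
                }
                for c in self.comparisons
            ],
        }
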