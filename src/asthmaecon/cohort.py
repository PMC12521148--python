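"""Synthetic patient-level cohort generator and aggregator.

The study's raw visit records are not public, so this module generates
patient-level stand-ins with the cohort's marginal structure and
aggregates them back into the model's inputs, closing the loop between
patient data and the decision tree:

* visits per patient — negative binomial matched by moments (the
  published per-patient visit sds exceed the means, ruling out Poisson);
* health state at each visit — i.i.d. draws from the subgroup's
  visit-share vector (no within-patient serial correlation; the decision
  tree uses only the marginal shares);
* per-visit costs — independent Gamma draws per category (ICS,
  traditional Chinese medicine, other chemical medicines, non-medication
  services), non-negative and right-skewed like the published costs;
* longest symptom-free duration — piecewise-exponential, with hazards
  chosen so the exceedance probabilities at the 3/6/12/24-month
  thresholds equal the configured targets exactly in expectation.

``aggregate_cohort`` mirrors the study's own aggregation: visit-state
shares become the tree probabilities, per-visit mean costs per state
become the cost parameters (on both the ICS-only and the
total-medication basis), and the duration exceedance rates become the
effectiveness table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import datasets
from .cea import EffectivenessTable, effectiveness_rates
from .parameters import StrategyParams, UtilityModel
from .states import STATE_LABELS, STATE_ORDER, HealthState

__all__ = [
    "CostCategoryConfig",
    "SubgroupConfig",
    "CohortConfig",
    "Visit",
    "PatientRecord",
    "CohortAggregate",
    "generate_cohort",
    "aggregate_cohort",
    "study_cohort_config",
    "write_cohort_csv",
    "read_cohort_csv",
    "PiecewiseExponential",
]

COST_CATEGORIES = ("ics", "tcm", "other_chemical", "non_medication")


@dataclass(frozen=True)
class CostCategoryConfig:
    """Per-state (mean, sd) of one cost category, in CNY per visit."""

    means: tuple[float, float, float]
    sds: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.means) or any(s < 0 for s in self.sds):
            raise ValueError("cost moments must be non-negative")


class PiecewiseExponential:
    """Duration distribution hitting given exceedance targets exactly.

    A piecewise-constant hazard on the intervals between thresholds makes
    the survival function pass through ``S(t_k) = target_k``; beyond the
    last threshold the final positive hazard continues.
    """

    def __init__(self, thresholds: Sequence[float], exceedance: Sequence[float]):
        t = np.asarray(thresholds, dtype=float)
        s = np.asarray(exceedance, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0) or np.any(t <= 0):
            raise ValueError("thresholds must be positive and strictly increasing")
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("exceedance targets must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("infeasible exceedance targets: must be non-increasing")
        self.thresholds = t
        self.survival = s
        edges = np.concatenate([[0.0], t])
        # a zero target gets a negligible floor so the hazard stays finite
        surv = np.clip(np.concatenate([[1.0], s]), 1e-12, 1.0)
        widths = np.diff(edges)
        logs = np.log(surv)
        self.hazards = (logs[:-1] - logs[1:]) / widths
        positive = self.hazards[self.hazards > 0]
        self.tail_hazard = float(positive[-1]) if positive.size else 1.0 / t[-1]
        self._edges = edges
        self._surv = surv

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Inverse-CDF sampling of durations (months)."""
        u = 1.0 - rng.uniform(size=size)  # survival levels in (0, 1]
        out = np.empty(size)
        surv, edges = self._surv, self._edges
        n_seg = len(self.hazards)
        for j, uj in enumerate(u):
            if uj <= surv[-1]:
                # exponential tail beyond the last threshold
                out[j] = edges[-1] + (np.log(surv[-1]) - np.log(uj)) / self.tail_hazard
                continue
            k = 0
            while uj <= surv[k + 1]:  # flat segments carry no mass; skip them
                k += 1
            out[j] = edges[k] + (np.log(surv[k]) - np.log(uj)) / self.hazards[k]
        return out


@dataclass(frozen=True)
class SubgroupConfig:
    """Generator settings for one treatment subgroup."""

    label: str
    n_patients: int
    visit_mean: float
    visit_sd: float
    state_shares: tuple[float, float, float]
    cost_categories: dict[str, CostCategoryConfig]
    duration_thresholds: tuple[float, ...] = (3.0, 6.0, 12.0, 24.0)
    duration_exceedance: tuple[float, ...] = (0.75, 0.6, 0.4, 0.2)
    followup_mean: float = 30.0
    followup_sd: float = 20.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        if self.visit_mean <= 0 or self.visit_sd <= 0:
            raise ValueError("visit moments must be positive")
        if abs(sum(self.state_shares) - 1.0) > 1e-6:
            raise ValueError("state shares must sum to 1")
        missing = set(COST_CATEGORIES) - set(self.cost_categories)
        if missing:
            raise ValueError(f"missing cost categories: {sorted(missing)}")
        # validates feasibility of the exceedance targets
        PiecewiseExponential(self.duration_thresholds, self.duration_exceedance)


@dataclass(frozen=True)
class CohortConfig:
    """Full synthetic-cohort specification: one block per subgroup."""

    subgroups: tuple[SubgroupConfig, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [s.label for s in self.subgroups]
        if len(set(labels)) != len(labels):
            raise ValueError("subgroup labels must be unique")


@dataclass(frozen=True)
class Visit:
    state: HealthState
    ics_cost: float
    tcm_cost: float
    other_cost: float
    non_medication_cost: float

    @property
    def medication_cost(self) -> float:
        return self.ics_cost + self.tcm_cost + self.other_cost


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient: visit history plus symptom-free outcome."""

    patient_id: str
    subgroup: str
    visits: tuple[Visit, ...]
    longest_symptom_free: float  # months
    followup: float              # months

    def __post_init__(self) -> None:
        if not self.visits:
            raise ValueError("a patient must have at least one visit")
        if self.longest_symptom_free > self.followup + 1e-9:
            raise ValueError("longest symptom-free duration exceeds follow-up")


def _nbinom_draws(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    var = sd**2
    if var <= mean:
        # variance at or under the mean: Poisson limit
        draws = rng.poisson(mean, size=size)
    else:
        r = mean**2 / (var - mean)
        p = r / (r + mean)
        draws = rng.negative_binomial(r, p, size=size)
    return np.maximum(draws, 1)  # every patient has at least one visit


def _gamma_costs(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    if mean == 0 or sd == 0:
        return np.full(size, mean)
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=size)


def _gamma_costs_by_state(
    rng: np.random.Generator,
    means: Sequence[float],
    sds: Sequence[float],
    state_idx: np.ndarray,
) -> np.ndarray:
    """One gamma cost draw per visit, with per-state moments, vectorized."""
    m = np.asarray(means, dtype=float)[state_idx]
    s = np.asarray(sds, dtype=float)[state_idx]
    out = m.copy()  # degenerate where mean or sd is zero
    ok = (m > 0) & (s > 0)
    if np.any(ok):
        shape = (m[ok] / s[ok]) ** 2
        scale = s[ok] ** 2 / m[ok]
        out[ok] = rng.gamma(shape, scale)
    return out


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate synthetic patients for every configured subgroup.

    Fully reproducible: each subgroup gets its own child stream of the
    root seed, so subgroups do not perturb one another.
    """
    records: list[PatientRecord] = []
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(config.subgroups))
    for sub, child in zip(config.subgroups, children):
        rng = np.random.default_rng(child)
        n = sub.n_patients
        n_visits = _nbinom_draws(rng, sub.visit_mean, sub.visit_sd, n)
        duration_dist = PiecewiseExponential(
            sub.duration_thresholds, sub.duration_exceedance
        )
        durations = duration_dist.sample(rng, n)
        followups = _gamma_costs(rng, sub.followup_mean, sub.followup_sd, n)
        followups = np.maximum(followups, durations)
        # draw all visits of the subgroup at once, then slice per patient
        total_visits = int(n_visits.sum())
        all_states = rng.choice(len(STATE_ORDER), size=total_visits, p=sub.state_shares)
        per_cat = {
            cat: _gamma_costs_by_state(
                rng,
                sub.cost_categories[cat].means,
                sub.cost_categories[cat].sds,
                all_states,
            )
            for cat in COST_CATEGORIES
        }
        offsets = np.concatenate([[0], np.cumsum(n_visits)])
        for i in range(n):
            lo, hi = int(offsets[i]), int(offsets[i + 1])
            visits = tuple(
                Visit(
                    state=STATE_ORDER[all_states[j]],
                    ics_cost=float(per_cat["ics"][j]),
                    tcm_cost=float(per_cat["tcm"][j]),
                    other_cost=float(per_cat["other_chemical"][j]),
                    non_medication_cost=float(per_cat["non_medication"][j]),
                )
                for j in range(lo, hi)
            )
            records.append(
                PatientRecord(
                    patient_id=f"{sub.label}-{i:05d}",
                    subgroup=sub.label,
                    visits=visits,
                    longest_symptom_free=float(durations[i]),
                    followup=float(followups[i]),
                )
            )
    return records


@dataclass
class CohortAggregate:
    """Per-subgroup aggregates in the shape the decision tree consumes."""

    subgroup: str
    n_patients: int
    visit_counts: tuple[int, int, int]
    state_probs: tuple[float, float, float]
    mean_ics_costs: tuple[float, ...]          # per state; nan where unobserved
    mean_medication_costs: tuple[float, ...]
    effectiveness: EffectivenessTable
    cost_summary: pd.DataFrame = field(repr=False, default=None)

    def strategy_params(
        self, cost_basis: str = "medication", utility_model: UtilityModel | None = None
    ) -> StrategyParams:
        um = utility_model or UtilityModel()
        means = (
            self.mean_ics_costs if cost_basis == "ics" else self.mean_medication_costs
        )
        costs = tuple(0.0 if np.isnan(m) else float(m) for m in means)
        return StrategyParams(
            label=self.subgroup,
            state_costs=costs,
            state_probs=self.state_probs,
            state_utilities=tuple(float(u) for u in um.state_utilities()),
            cost_basis=cost_basis,
            prob_tol=1e-8,
        )


def aggregate_cohort(
    records: Iterable[PatientRecord],
    thresholds: Sequence[float] = (3, 6, 12, 24),
) -> dict[str, CohortAggregate]:
    """Aggregate patient records back into model inputs, per subgroup.

    State probabilities are visit-state shares; per-state costs are
    per-visit means on both cost bases (reported as NaN for a state with
    no visits, whose probability is then 0); effectiveness rates come
    from the longest symptom-free durations.
    """
    by_sub: dict[str, list[PatientRecord]] = {}
    for rec in records:
        by_sub.setdefault(rec.subgroup, []).append(rec)
    if not by_sub:
        raise ValueError("no records to aggregate")
    out: dict[str, CohortAggregate] = {}
    for sub, recs in by_sub.items():
        visits = [v for r in recs for v in r.visits]
        counts = tuple(
            sum(1 for v in visits if v.state is s) for s in STATE_ORDER
        )
        total = sum(counts)
        probs = tuple(c / total for c in counts)
        ics_means, med_means = [], []
        rows = []
        for s, c in zip(STATE_ORDER, counts):
            sv = [v for v in visits if v.state is s]
            if not sv:
                ics_means.append(float("nan"))
                med_means.append(float("nan"))
                continue
            ics = float(np.mean([v.ics_cost for v in sv]))
            med = float(np.mean([v.medication_cost for v in sv]))
            ics_means.append(ics)
            med_means.append(med)
            rows.append(
                {
                    "subgroup": sub,
                    "state": s.value,
                    "n_visits": c,
                    "mean_ics": ics,
                    "mean_tcm": float(np.mean([v.tcm_cost for v in sv])),
                    "mean_other": float(np.mean([v.other_cost for v in sv])),
                    "mean_non_medication": float(
                        np.mean([v.non_medication_cost for v in sv])
                    ),
                    "mean_medication": med,
                }
            )
        eff = effectiveness_rates([r.longest_symptom_free for r in recs], thresholds)
        out[sub] = CohortAggregate(
            subgroup=sub,
            n_patients=len(recs),
            visit_counts=counts,
            state_probs=probs,
            mean_ics_costs=tuple(ics_means),
            mean_medication_costs=tuple(med_means),
            effectiveness=eff,
            cost_summary=pd.DataFrame(rows),
        )
    return out


def study_cohort_config(
    n_patients: dict[str, int] | int | None = None, seed: int = 0
) -> CohortConfig:
    """Cohort configuration calibrated to the bundled study aggregates.

    Defaults reproduce the study conditions: the four leaf subgroups at
    their observed sizes, visit counts at the published per-patient
    moments, state shares equal to the observed visit shares, per-visit
    cost categories at the published (mean, sd), and symptom-free
    duration exceedance targets equal to the published rates.  Pass
    ``n_patients`` to scale the subgroups (an int applies to all four).
    """
    subs = []
    for label in datasets.SUBGROUPS:
        if n_patients is None:
            n = datasets.EFFECTIVENESS_N[label]
        elif isinstance(n_patients, int):
            n = n_patients
        else:
            n = n_patients[label]
        shares = datasets.study_probabilities(label)
        vm, vs = datasets.VISITS_PER_PATIENT[label]
        fm, fs = datasets.FOLLOWUP_MONTHS[label]
        n_pat = datasets.EFFECTIVENESS_N[label]
        exceed = tuple(
            c / n_pat for c in datasets.EFFECTIVENESS_COUNTS[label]
        )
        cats = {
            cat: CostCategoryConfig(
                means=datasets.CATEGORY_COSTS[cat][label],
                sds=datasets.CATEGORY_COST_SDS[cat][label],
            )
            for cat in COST_CATEGORIES
        }
        subs.append(
            SubgroupConfig(
                label=label,
                n_patients=n,
                visit_mean=vm,
                visit_sd=vs,
                state_shares=tuple(float(p) for p in shares),
                cost_categories=cats,
                duration_exceedance=exceed,
                followup_mean=fm,
                followup_sd=fs,
            )
        )
    return CohortConfig(subgroups=tuple(subs), seed=seed)


# ---------------------------------------------------------------------------
# CSV round-trip

_VISIT_COLS = [
    "patient_id", "subgroup", "visit_index", "state",
    "ics_cost", "tcm_cost", "other_cost", "non_medication_cost",
]
_PATIENT_COLS = ["patient_id", "subgroup", "longest_symptom_free", "followup"]


def write_cohort_csv(
    records: Iterable[PatientRecord], visits_path: str | Path, patients_path: str | Path
) -> None:
    """Write the cohort as a visit-level and a patient-level CSV."""
    vrows, prows = [], []
    for r in records:
        prows.append(
            {
                "patient_id": r.patient_id,
                "subgroup": r.subgroup,
                "longest_symptom_free": r.longest_symptom_free,
                "followup": r.followup,
            }
        )
        for j, v in enumerate(r.visits):
            vrows.append(
                {
                    "patient_id": r.patient_id,
                    "subgroup": r.subgroup,
                    "visit_index": j,
                    "state": v.state.value,
                    "ics_cost": v.ics_cost,
                    "tcm_cost": v.tcm_cost,
                    "other_cost": v.other_cost,
                    "non_medication_cost": v.non_medication_cost,
                }
            )
    pd.DataFrame(vrows, columns=_VISIT_COLS).to_csv(visits_path, index=False)
    pd.DataFrame(prows, columns=_PATIENT_COLS).to_csv(patients_path, index=False)


def read_cohort_csv(
    visits_path: str | Path, patients_path: str | Path
) -> list[PatientRecord]:
    """Read a cohort back from the two-CSV representation."""
    vdf = pd.read_csv(visits_path).sort_values(["patient_id", "visit_index"])
    pdf = pd.read_csv(patients_path)
    visits_by_pid: dict[str, list[Visit]] = {}
    for row in vdf.itertuples(index=False):
        visits_by_pid.setdefault(row.patient_id, []).append(
            Visit(
                state=HealthState(row.state),
                ics_cost=row.ics_cost,
                tcm_cost=row.tcm_cost,
                other_cost=row.other_cost,
                non_medication_cost=row.non_medication_cost,
            )
        )
    records = []
    for row in pdf.itertuples(index=False):
        records.append(
            PatientRecord(
                patient_id=row.patient_id,
                subgroup=row.subgroup,
                visits=tuple(visits_by_pid.get(row.patient_id, ())),
                longest_symptom_free=row.longest_symptom_free,
                followup=row.followup,
            )
        )
    return records
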