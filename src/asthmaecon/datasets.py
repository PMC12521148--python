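"""Bundled example dataset: a retrospective pediatric ICS-LABA asthma cohort.

59 children treated with inhaled corticosteroid / long-acting beta-agonist
(ICS-LABA) regimens, grouped by inhaler strategy:

* ``A1`` — single inhaler, salmeterol-fluticasone (SF), n = 8;
* ``A2`` — single inhaler, budesonide-formoterol (BF), n = 22;
* ``A``  — all single-inhaler patients, n = 30;
* ``B1`` — two inhalers (SF+FP, SF+BF or FP+BF), n = 21;
* ``B2`` — three inhalers (SF+BF+FP), n = 8;
* ``B``  — all multiple-inhaler patients, n = 29.

The tables below are the published group-level aggregates of that cohort:
per-state visit counts, per-state mean costs on the ICS-only and the
total-medication cost bases (with standard deviations where published),
longest symptom-free duration exceedance counts, and per-patient visit /
follow-up moments.  The patient-level records themselves are not public;
:mod:`asthmaecon.cohort` generates synthetic stand-ins calibrated to these
aggregates.
"""

from __future__ import annotations

import numpy as np

from .parameters import StrategyParams, UtilityModel, probabilities_from_visit_counts

__all__ = [
    "SUBGROUPS",
    "GROUPS",
    "VISIT_COUNTS",
    "STATE_COSTS",
    "STATE_COST_SDS",
    "AVERAGE_COSTS",
    "EFFECTIVENESS_N",
    "EFFECTIVENESS_COUNTS",
    "EFFECTIVENESS_THRESHOLDS",
    "VISITS_PER_PATIENT",
    "FOLLOWUP_MONTHS",
    "COMPARISON_PAIRS",
    "study_strategies",
    "study_probabilities",
    "study_params_path",
]

#: Leaf subgroups with patient-level identity.
SUBGROUPS = ("A1", "A2", "B1", "B2")
#: All analysis groups, including the pooled A and B columns.
GROUPS = ("A1", "A2", "A", "B1", "B2", "B")

#: Visits per health state (hospitalization, outpatient exacerbation,
#: symptom-free outpatient follow-up), per group.
VISIT_COUNTS: dict[str, tuple[int, int, int]] = {
    "A1": (8, 8, 30),
    "A2": (28, 34, 128),
    "A": (36, 42, 158),
    "B1": (22, 47, 275),
    "B2": (8, 25, 170),
    "B": (30, 72, 445),
}

#: Mean cost per state (CNY) on each cost basis, state order as above.
STATE_COSTS: dict[str, dict[str, tuple[float, float, float]]] = {
    "ics": {
        "A1": (132.26, 44.09, 247.99),
        "A2": (197.40, 141.00, 502.23),
        "A": (180.03, 106.80, 432.09),
        "B1": (145.31, 159.81, 857.25),
        "B2": (143.68, 327.08, 1881.11),
        "B": (144.86, 215.56, 1139.70),
    },
    "medication": {
        "A1": (1989.60, 242.69, 1652.40),
        "A2": (1979.70, 573.70, 1124.17),
        "A": (1982.34, 456.87, 1269.89),
        "B1": (1746.83, 627.79, 3066.38),
        "B2": (1839.83, 1002.77, 5923.50),
        "B": (1772.49, 752.78, 3854.55),
    },
}

#: Published standard deviations of the per-state costs (CNY), where a
#: mapping to the inpatient/outpatient cost tables exists.  A zero sd means
#: the cost was constant in the cohort (single fixed-price inhaler).
STATE_COST_SDS: dict[str, dict[str, tuple[float, float, float]]] = {
    "ics": {
        "A1": (0.00, 68.30, 148.92),
        "A2": (136.91, 213.28, 702.08),
        "A": (120.13, 179.35, 609.10),
        "B1": (11.58, 125.69, 1337.13),
        "B2": (12.21, 285.20, 1188.74),
        "B": (11.56, 203.83, 1359.14),
    },
    "medication": {
        "A1": (977.39, 142.37, 2924.12),
        "A2": (2115.36, 543.66, 1546.75),
        "A": (1863.04, 466.53, 1975.91),
        "B1": (892.26, 424.47, 4076.71),
        "B2": (910.64, 1263.44, 5123.06),
        "B": (881.91, 797.45, 4220.19),
    },
}

#: Per-patient average treatment cost (CNY) used by the cost-effectiveness
#: analysis, per cost basis.
AVERAGE_COSTS: dict[str, dict[str, float]] = {
    "medication": {
        "A1": 3824.02,
        "A2": 3339.63,
        "A": 3468.8,
        "B1": 5291.53,
        "B2": 8766.09,
        "B": 6250.03,
    },
    "ics": {
        "A1": 413.31,
        "A2": 747.30,
        "A": 658.24,
        "B1": 1124.32,
        "B2": 2351.86,
        "B": 1462.96,
    },
}

#: Symptom-free duration thresholds (months) defining E3, E6, E12, E24.
EFFECTIVENESS_THRESHOLDS = (3.0, 6.0, 12.0, 24.0)

#: Cohort size per group.
EFFECTIVENESS_N: dict[str, int] = {"A1": 8, "A2": 22, "A": 30, "B1": 21, "B2": 8, "B": 29}

#: Patients whose longest symptom-free duration reached each threshold.
EFFECTIVENESS_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "A1": (6, 5, 3, 1),
    "A2": (11, 8, 8, 3),
    "A": (17, 13, 11, 4),
    "B1": (18, 16, 14, 6),
    "B2": (8, 7, 6, 5),
    "B": (26, 23, 20, 11),
}

#: Visits per patient, mean and sd, per leaf subgroup.
VISITS_PER_PATIENT: dict[str, tuple[float, float]] = {
    "A1": (5.8, 3.8),
    "A2": (8.6, 9.2),
    "B1": (16.4, 15.5),
    "B2": (25.6, 13.1),
}

#: Outpatient follow-up duration in months, mean and sd, per leaf subgroup.
FOLLOWUP_MONTHS: dict[str, tuple[float, float]] = {
    "A1": (16.3, 16.1),
    "A2": (20.5, 26.7),
    "B1": (35.4, 24.9),
    "B2": (50.3, 17.8),
}

#: Mean per-visit cost (CNY) by category and state, per leaf subgroup.
#: Categories: ICS inhalers, traditional Chinese medicine, other chemical
#: medicines, non-medication services.  The three medication categories sum
#: to the total-medication state costs above.
CATEGORY_COSTS: dict[str, dict[str, tuple[float, float, float]]] = {
    "ics": {
        "A1": (132.26, 44.09, 247.99),
        "A2": (197.40, 141.00, 502.23),
        "B1": (145.31, 159.81, 857.25),
        "B2": (143.68, 327.08, 1881.11),
    },
    "tcm": {
        "A1": (20.72, 84.59, 87.70),
        "A2": (15.97, 85.83, 188.41),
        "B1": (17.23, 94.41, 422.80),
        "B2": (21.32, 18.66, 614.13),
    },
    "other_chemical": {
        "A1": (1836.62, 114.01, 1316.71),
        "A2": (1766.34, 346.87, 433.53),
        "B1": (1584.29, 373.57, 1786.33),
        "B2": (1674.82, 657.03, 3428.26),
    },
    "non_medication": {
        "A1": (8135.29, 521.27, 931.50),
        "A2": (10184.09, 1117.77, 1143.78),
        "B1": (6892.96, 667.30, 2500.68),
        "B2": (6816.33, 1406.77, 4332.94),
    },
}

#: Published standard deviations matching :data:`CATEGORY_COSTS`.
CATEGORY_COST_SDS: dict[str, dict[str, tuple[float, float, float]]] = {
    "ics": {
        "A1": (0.00, 68.30, 148.92),
        "A2": (136.91, 213.28, 702.08),
        "B1": (11.58, 125.69, 1337.13),
        "B2": (12.21, 285.20, 1188.74),
    },
    "tcm": {
        "A1": (58.60, 142.01, 100.91),
        "A2": (51.02, 132.06, 437.03),
        "B1": (39.81, 147.26, 483.44),
        "B2": (39.75, 40.08, 466.06),
    },
    "other_chemical": {
        "A1": (990.70, 156.17, 2833.15),
        "A2": (1973.44, 326.61, 602.72),
        "B1": (904.82, 293.07, 3237.53),
        "B2": (931.19, 964.31, 3982.17),
    },
    "non_medication": {
        "A1": (2839.74, 642.63, 862.73),
        "A2": (11012.27, 1107.85, 1181.99),
        "B1": (2128.60, 536.32, 2107.01),
        "B2": (3033.16, 1751.37, 1583.35),
    },
}

#: Comparator pairs analysed in the study, as (reference, alternative).
#: The reference is the cheaper arm in each pair.
COMPARISON_PAIRS: dict[str, tuple[tuple[str, str], ...]] = {
    "ics": (("A1", "A2"), ("B1", "B2"), ("A", "B")),
    "medication": (("A2", "A1"), ("B1", "B2"), ("A", "B")),
}


def study_params_path(cost_basis: str = "medication"):
    """Path of the packaged table-verbatim strategy parameter CSV.

    The file stores the published 4-decimal probabilities and printed
    costs/utilities exactly as tabulated; :func:`study_strategies` is the
    full-precision alternative.
    """
    from importlib.resources import files

    if cost_basis not in STATE_COSTS:
        raise ValueError(f"unknown cost basis {cost_basis!r}")
    return files("asthmaecon") / "data" / f"study_params_{cost_basis}.csv"


def study_probabilities(group: str) -> np.ndarray:
    """Per-state visit-share probabilities for one group, at full precision."""
    return probabilities_from_visit_counts(VISIT_COUNTS[group])


def study_strategies(
    cost_basis: str = "medication", utility_model: UtilityModel | None = None
) -> list[StrategyParams]:
    """Decision-tree parameter sets for all six groups on one cost basis.

    Probabilities are derived from the visit counts at full precision and
    utilities from the closed form of the utility model, so downstream
    expected values carry no table-rounding error.
    """
    if cost_basis not in STATE_COSTS:
        raise ValueError(f"unknown cost basis {cost_basis!r}")
    um = utility_model or UtilityModel()
    return [
        StrategyParams.from_visit_counts(
            label=g,
            counts=VISIT_COUNTS[g],
            state_costs=STATE_COSTS[cost_basis][g],
            utility_model=um,
            cost_basis=cost_basis,
        )
        for g in GROUPS
    ]
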