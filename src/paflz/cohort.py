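"""Case/control selection and age/sex matching on PTB-XL-style metadata.

Cases are the sinus-rhythm (SR) records of patients who have an earlier
AFIB record — the analysis runs on SR signals only, the AFIB record just
establishes the paroxysmal-AF history.  Controls are comorbidity-free SR
records from AF-free patients, matched to the cases per (sex, age-group)
cell.  Age groups follow the dataset-table convention: <20, 20-29, ...,
80-89, >=90.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_AGE_EDGES = tuple(range(20, 100, 10))

REQUIRED_COLUMNS = (
    "record_id",
    "patient_id",
    "age",
    "sex",
    "acquisition_index",
    "rhythm_label",
)

__all__ = [
    "CohortSpec",
    "CohortAssignment",
    "CohortShortfallError",
    "age_group",
    "select_cases",
    "match_controls",
    "build_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Age-grouping and ordering conventions for cohort construction."""

    age_edges: tuple = DEFAULT_AGE_EDGES
    order_column: str = "acquisition_index"

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.age_edges, self.age_edges[1:])):
            raise ValueError("age edges must be strictly increasing")


@dataclass(frozen=True)
class CohortAssignment:
    record_id: str
    patient_id: str
    arm: str  # "case" or "control"
    sex: str
    age_group: str


class CohortShortfallError(ValueError):
    """A (sex, age-group) cell cannot be filled from the control pool."""

    def __init__(self, shortfalls: dict):
        self.shortfalls = shortfalls
        cells = ", ".join(
            f"{cell}: need {need}, have {have}"
            for cell, (need, have) in sorted(shortfalls.items())
        )
        super().__init__(f"insufficient control pool in cells -- {cells}")


def age_group(age: float, spec: CohortSpec = CohortSpec()) -> str:
    """Deterministic age bucket label, e.g. 20 -> '20-29', 95 -> '>=90'."""
    if age < 0:
        raise ValueError("age must be non-negative")
    edges = spec.age_edges
    if age < edges[0]:
        return f"<{edges[0]}"
    if age >= edges[-1]:
        return f">={edges[-1]}"
    i = int(np.searchsorted(np.asarray(edges), age, side="right")) - 1
    return f"{edges[i]}-{edges[i + 1] - 1}"


def _check_columns(meta: pd.DataFrame, spec: CohortSpec) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in meta.columns]
    if spec.order_column not in meta.columns:
        missing.append(spec.order_column)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(set(missing))}")


def _has_comorbidity(value) -> bool:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    return bool(str(value).strip())


def select_cases(meta: pd.DataFrame, spec: CohortSpec = CohortSpec()) -> list:
    """SR record ids of patients with a strictly earlier AFIB record.

    All qualifying SR records of such a patient are returned (not just the
    first); the AFIB records themselves are excluded — classification runs
    on sinus-rhythm signals.
    """
    _check_columns(meta, spec)
    order = spec.order_column
    out = []
    for _, grp in meta.groupby("patient_id", sort=True):
        af = grp.loc[grp["rhythm_label"] == "AFIB", order]
        if af.empty:
            continue
        first_af = af.min()
        sr_after = grp[(grp["rhythm_label"] == "SR") & (grp[order] > first_af)]
        out.extend(sr_after.sort_values(order)["record_id"].tolist())
    return out


def _assignments(meta: pd.DataFrame, record_ids, arm: str, spec: CohortSpec):
    sub = meta.set_index("record_id").loc[list(record_ids)]
    return [
        CohortAssignment(
            record_id=rid,
            patient_id=row["patient_id"],
            arm=arm,
            sex=row["sex"],
            age_group=age_group(row["age"], spec),
        )
        for rid, row in sub.iterrows()
    ]


def match_controls(
    cases: list,
    pool: pd.DataFrame,
    seed: int = 0,
    spec: CohortSpec = CohortSpec(),
) -> list:
    """Select comorbidity-free SR control records matching the case cells.

    For every (sex, age-group) cell the same number of control records as
    case records is drawn, each from a distinct AF-free control patient,
    uniformly at random under ``seed``.  A cell that cannot be filled
    raises :class:`CohortShortfallError` — matching is never silently
    relaxed.
    """
    _check_columns(pool, spec)
    case_patients = {c.patient_id for c in cases}
    af_patients = set(pool.loc[pool["rhythm_label"] == "AFIB", "patient_id"])
    eligible = pool[
        (pool["rhythm_label"] == "SR")
        & ~pool["patient_id"].isin(case_patients | af_patients)
        & ~pool["comorbidity_codes"].map(_has_comorbidity)
    ].copy()
    eligible["age_group"] = eligible["age"].map(lambda a: age_group(a, spec))

    need: dict = {}
    for c in cases:
        need[(c.sex, c.age_group)] = need.get((c.sex, c.age_group), 0) + 1

    rng = np.random.default_rng(seed)
    chosen: list[CohortAssignment] = []
    used_patients: set = set()
    shortfalls: dict = {}
    for cell in sorted(need):
        sex, grp = cell
        cell_pool = eligible[
            (eligible["sex"] == sex) & (eligible["age_group"] == grp)
        ]
        # one record per distinct patient: the earliest eligible record
        per_patient = (
            cell_pool.sort_values(spec.order_column)
            .groupby("patient_id", sort=True)
            .first()
            .reset_index()
        )
        per_patient = per_patient[~per_patient["patient_id"].isin(used_patients)]
        if len(per_patient) < need[cell]:
            shortfalls[cell] = (need[cell], len(per_patient))
            continue
        pick = rng.choice(len(per_patient), size=need[cell], replace=False)
        for _, row in per_patient.iloc[np.sort(pick)].iterrows():
            used_patients.add(row["patient_id"])
            chosen.append(
                CohortAssignment(
                    record_id=row["record_id"],
                    patient_id=row["patient_id"],
                    arm="control",
                    sex=sex,
                    age_group=grp,
                )
            )
    if shortfalls:
        raise CohortShortfallError(shortfalls)
    return chosen


def build_cohort(
    meta: pd.DataFrame, seed: int = 0, spec: CohortSpec = CohortSpec()
) -> pd.DataFrame:
    """Full case selection + control matching; returns the cohort table.

    Columns: record_id, patient_id, arm, sex, age_group.  Deterministic
    under ``seed``; arms are balanced overall and per (sex x age-group)
    cell by construction.
    """
    case_ids = select_cases(meta, spec)
    if not case_ids:
        raise ValueError("no case records found (no AFIB-then-SR patients)")
    cases = _assignments(meta, case_ids, "case", spec)
    controls = match_controls(cases, meta, seed=seed, spec=spec)
    rows = [vars(a) for a in cases + controls]
    return pd.DataFrame(rows, columns=list(CohortAssignment.__dataclass_fields__))
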