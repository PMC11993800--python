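"""Full evaluation grid: enumerate, run, aggregate and rank.

The default grid crosses 13 lead configurations (12 single leads plus all
leads combined), 4 coarse-graining methods, 3 complexity algorithms, 4
sampling frequencies and 2 classifier families — 1248 cases.  Complexity
features are computed once per (record, lead, cg, cx, fs) and reused
across classifier axes; each grid cell then runs feature-table assembly,
Bayesian hyperparameter optimization and hyperparameter-mode resolution.
Aggregations (median/max across the 12 single leads per combination, and
a top-k ranking) are recomputable from the stored per-cell results alone.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import complexity as cx_mod
from . import signal_prep as sp
from .harness import (
    FeatureSelector,
    KnnSpace,
    SvmSpace,
    bayes_optimize,
    build_feature_table,
)
from .synth import LEAD_NAMES

COARSE_GRAININGS = ("TC", "KM", "FD", "BD")
ALGORITHMS = ("LZ76", "LZ78", "Ti")
FREQUENCIES = (125, 250, 375, 500)
FAMILIES = ("KNN", "SVM")

__all__ = [
    "GridCase",
    "GridConfig",
    "GridResult",
    "count_grid_cases",
    "compute_features",
    "run_grid",
    "aggregate_median",
    "aggregate_max",
    "rank_top",
]


class GridCase(NamedTuple):
    lead: str  # a lead name or "ALL"
    cg: str
    cx: str
    fs: int
    family: str


@dataclass(frozen=True)
class GridConfig:
    """Axes of the evaluation grid plus per-family optimizer budgets."""

    leads: tuple = LEAD_NAMES + ("ALL",)
    cgs: tuple = COARSE_GRAININGS
    cxs: tuple = ALGORITHMS
    fss: tuple = FREQUENCIES
    families: tuple = FAMILIES
    n_iter: dict = field(default_factory=lambda: {"KNN": 300, "SVM": 50})

    def cases(self) -> list:
        return [
            GridCase(lead, cg, cx, fs, fam)
            for lead in self.leads
            for cg in self.cgs
            for cx in self.cxs
            for fs in self.fss
            for fam in self.families
        ]


@dataclass
class GridResult:
    case: GridCase
    accuracy: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    params: dict = field(default_factory=dict)
    error: str | None = None


def count_grid_cases(config: GridConfig = GridConfig()) -> int:
    """Cardinality of the configured Cartesian product of grid axes."""
    return (
        len(config.leads)
        * len(config.cgs)
        * len(config.cxs)
        * len(config.fss)
        * len(config.families)
    )


# ---------------------------------------------------------------------------
# feature computation


def _binarize(lead_signal: np.ndarray, cg: str, fs: int) -> str:
    if cg == "TC":
        return sp.threshold_crossing(lead_signal)
    if cg == "KM":
        return sp.kmeans_binarize(lead_signal)
    fid = sp.detect_fiducials(lead_signal, fs)
    n = lead_signal.size
    if cg == "FD":
        return sp.feature_detection_binarize(fid, n)
    if cg == "BD":
        return sp.beat_detection_binarize(fid, n)
    raise ValueError(f"unknown coarse graining {cg!r}")


def compute_features(
    records,
    leads=LEAD_NAMES,
    cgs=COARSE_GRAININGS,
    cxs=ALGORITHMS,
    fss=FREQUENCIES,
    cache_path=None,
) -> pd.DataFrame:
    """Normalized complexity features, tidy: record_id, lead, cg, cx, fs, value.

    Binary strings are built once per (record, lead, cg, fs) and scored by
    every requested algorithm.  With ``cache_path`` the table round-trips
    through a CSV keyed by a content hash of the request, so a repeated
    grid run reuses features.
    """
    if cache_path is not None:
        key = hashlib.sha256(
            repr(
                (
                    sorted(r.record_id for r in records),
                    tuple(leads), tuple(cgs), tuple(cxs), tuple(fss),
                )
            ).encode()
        ).hexdigest()[:16]
        cache_file = Path(cache_path) / f"features_{key}.csv"
        if cache_file.exists():
            return pd.read_csv(cache_file)
    rows = []
    for rec in records:
        if rec.fs != 500:
            raise ValueError(
                f"record {rec.record_id!r} must be at 500 Hz before decimation"
            )
        for fs in fss:
            sig = sp.decimate(rec.signal, fs)
            for lead in leads:
                x = sig[LEAD_NAMES.index(lead)]
                for cg in cgs:
                    s = _binarize(x, cg, fs)
                    for cxname in cxs:
                        rows.append(
                            {
                                "record_id": rec.record_id,
                                "lead": lead,
                                "cg": cg,
                                "cx": cxname,
                                "fs": fs,
                                "value": cx_mod.score(s, cxname),
                            }
                        )
    out = pd.DataFrame(rows)
    if cache_path is not None:
        Path(cache_path).mkdir(parents=True, exist_ok=True)
        out.to_csv(cache_file, index=False)
    return out


# ---------------------------------------------------------------------------
# grid execution


def _case_seed(seed: int, case: GridCase) -> int:
    digest = hashlib.sha256(f"{seed}:{case}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def run_grid(
    records,
    cohort: pd.DataFrame,
    config: GridConfig = GridConfig(),
    seed: int = 0,
    features: pd.DataFrame | None = None,
    cache_path=None,
) -> list:
    """Run every configured grid case; failures are recorded, never skipped."""
    cohort_ids = set(cohort["record_id"])
    analysis_records = [r for r in records if r.record_id in cohort_ids]
    if features is None:
        single_leads = tuple(l for l in config.leads if l != "ALL")
        need_leads = LEAD_NAMES if "ALL" in config.leads else single_leads
        features = compute_features(
            analysis_records,
            leads=need_leads,
            cgs=config.cgs,
            cxs=config.cxs,
            fss=config.fss,
            cache_path=cache_path,
        )
    results = []
    for case in config.cases():
        try:
            selector = FeatureSelector(
                leads="all" if case.lead == "ALL" else (case.lead,),
                cg=(case.cg,),
                cx=(case.cx,),
                fs=case.fs,
            )
            table = build_feature_table(features, cohort, selector)
            space = KnnSpace() if case.family == "KNN" else SvmSpace()
            res = bayes_optimize(
                table,
                space,
                n_iter=config.n_iter[case.family],
                seed=_case_seed(seed, case),
            )
            results.append(
                GridResult(
                    case=case,
                    accuracy=res.accuracy,
                    sensitivity=res.sensitivity,
                    specificity=res.specificity,
                    params=res.params,
                )
            )
        except Exception as exc:  # noqa: BLE001 - recorded, never silent
            results.append(GridResult(case=case, error=f"{type(exc).__name__}: {exc}"))
    return results


def results_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "lead": r.case.lead,
                "cg": r.case.cg,
                "cx": r.case.cx,
                "fs": r.case.fs,
                "family": r.case.family,
                "accuracy": r.accuracy,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "error": r.error,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aggregation


def _single_lead_frame(results) -> pd.DataFrame:
    df = results_frame(results)
    df = df[df["error"].isna()]
    single = df[df["lead"] != "ALL"]
    counts = single.groupby(["cg", "cx", "fs", "family"])["lead"].nunique()
    if (counts != len(LEAD_NAMES)).any():
        bad = counts[counts != len(LEAD_NAMES)].index.tolist()
        raise ValueError(f"incomplete single-lead coverage for keys {bad}")
    return single


def aggregate_median(results) -> pd.DataFrame:
    """Median accuracy over the 12 single leads per (cg, cx, fs, family)."""
    single = _single_lead_frame(results)
    return (
        single.groupby(["cg", "cx", "fs", "family"])["accuracy"]
        .median()
        .reset_index()
    )


def aggregate_max(results) -> pd.DataFrame:
    """Max accuracy over the 12 single leads; ties break by lead order I..V6."""
    single = _single_lead_frame(results).copy()
    single["lead_order"] = single["lead"].map(
        {name: i for i, name in enumerate(LEAD_NAMES)}
    )
    single = single.sort_values(
        ["cg", "cx", "fs", "family", "accuracy", "lead_order"],
        ascending=[True, True, True, True, False, True],
    )
    top = single.groupby(["cg", "cx", "fs", "family"], as_index=False).first()
    return top[["cg", "cx", "fs", "family", "accuracy", "lead"]]


def rank_top(results, k: int = 10) -> pd.DataFrame:
    """Top-k grid cells by accuracy (ties: specificity, sensitivity, key)."""
    df = results_frame(results)
    df = df[df["error"].isna()].copy()
    df["case_key"] = (
        df["lead"] + "|" + df["cg"] + "|" + df["cx"] + "|"
        + df["fs"].astype(str) + "|" + df["family"]
    )
    df = df.sort_values(
        ["accuracy", "specificity", "sensitivity", "case_key"],
        ascending=[False, False, False, True],
    ).drop(columns="case_key")
    return df.head(k).reset_index(drop=True)
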