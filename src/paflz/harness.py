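"""Patient-grouped LOOCV, hyperparameter spaces and Bayesian optimization.

Evaluation is leave-one-patient-out: each fold withholds *all* records of
one patient and scores them with a model trained on everyone else's
records, so no patient's data ever leaks into its own training set.
Accuracy, sensitivity and specificity are computed over the pooled
per-record predictions with PAF as the positive class (a patient-level
majority-vote accuracy is stored alongside).

Hyperparameters are tuned by minimizing ``1 - accuracy``.  Whenever the
discrete search space is small enough to enumerate within the iteration
budget it is evaluated exhaustively; otherwise a sequential model-based
optimizer (random-forest surrogate, expected-improvement acquisition,
seeded 10-point initial design) proposes candidates.  When several
hyperparameter sets tie at the optimum, the componentwise mode is taken
and verified to be one of the tied optima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import norm
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import NuSVC

POSITIVE = "PAF"
NEGATIVE = "control"
META_COLUMNS = ("record_id", "patient_id", "label")

# ten distance options for KNN; "minkowski3" is Minkowski with p = 3
DEFAULT_KNN_METRICS = (
    "euclidean",
    "cityblock",
    "chebyshev",
    "minkowski3",
    "cosine",
    "correlation",
    "canberra",
    "braycurtis",
    "hamming",
    "jaccard",
)

__all__ = [
    "KnnSpace",
    "SvmSpace",
    "CvResult",
    "loocv_evaluate",
    "bayes_optimize",
    "resolve_hyperparameters",
    "build_feature_table",
    "FeatureSelector",
]


@dataclass(frozen=True)
class KnnSpace:
    """All odd neighbor counts in [1, 99] x 10 distance metrics (500 points)."""

    ks: tuple = tuple(range(1, 100, 2))
    metrics: tuple = DEFAULT_KNN_METRICS
    default_n_iter: int = 300

    @property
    def size(self) -> int:
        return len(self.ks) * len(self.metrics)

    def candidates(self) -> list:
        return [
            {"family": "knn", "k": k, "metric": m}
            for k in self.ks
            for m in self.metrics
        ]

    def encode(self, params: dict) -> list:
        onehot = [1.0 if m == params["metric"] else 0.0 for m in self.metrics]
        return [float(params["k"])] + onehot


@dataclass(frozen=True)
class SvmSpace:
    """Kernel in {linear, quadratic poly, Gaussian} x outlier fraction [0, 0.5].

    The outlier fraction maps to the nu parameter of a nu-SVM (floored at
    0.01 when fitting, since nu = 0 is infeasible); the fraction axis is
    discretized to 51 evenly spaced values so the space is finite.
    """

    kernels: tuple = ("linear", "poly2", "rbf")
    fractions: tuple = tuple(round(0.01 * i, 2) for i in range(51))
    default_n_iter: int = 50

    @property
    def size(self) -> int:
        return len(self.kernels) * len(self.fractions)

    def candidates(self) -> list:
        return [
            {"family": "svm", "kernel": k, "outlier_fraction": f}
            for k in self.kernels
            for f in self.fractions
        ]

    def encode(self, params: dict) -> list:
        onehot = [1.0 if k == params["kernel"] else 0.0 for k in self.kernels]
        return [float(params["outlier_fraction"])] + onehot


@dataclass
class CvResult:
    """Pooled LOOCV predictions plus summary metrics and optimizer trace."""

    predictions: pd.DataFrame  # record_id, patient_id, truth, predicted
    accuracy: float
    sensitivity: float
    specificity: float
    params: dict
    patient_accuracy: float = float("nan")
    trace: list = field(default_factory=list)


def _feature_columns(table: pd.DataFrame) -> list:
    return [c for c in table.columns if c not in META_COLUMNS]


def _zscore(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _knn_predict(Xtr, ytr, Xte, k: int, metric: str) -> np.ndarray:
    if metric == "minkowski3":
        d = cdist(Xte, Xtr, metric="minkowski", p=3)
    else:
        d = cdist(Xte, Xtr, metric=metric)
    d = np.nan_to_num(d, nan=np.inf, posinf=np.inf)
    k = min(k, Xtr.shape[0])
    nearest = np.argpartition(d, k - 1, axis=1)[:, :k]
    votes = ytr[nearest].sum(axis=1)
    return votes * 2 > k  # odd k and binary labels: no ties


def _svm_predict(Xtr, ytr, Xte, kernel: str, fraction: float) -> np.ndarray:
    nu = float(np.clip(fraction, 0.01, 0.5))
    kw = {"linear": dict(kernel="linear"),
          "poly2": dict(kernel="poly", degree=2),
          "rbf": dict(kernel="rbf")}[kernel]
    model = NuSVC(nu=nu, gamma="scale", **kw)
    try:
        model.fit(Xtr, ytr)
        return model.predict(Xte).astype(bool)
    except ValueError:
        # infeasible nu for this fold's class balance: majority fallback
        majority = ytr.mean() > 0.5
        return np.full(Xte.shape[0], majority, dtype=bool)


def loocv_evaluate(
    table: pd.DataFrame, model: dict, standardize: bool = True
) -> CvResult:
    """Leave-one-patient-out evaluation of one hyperparameter setting.

    ``model`` is ``{"family": "knn", "k": ..., "metric": ...}`` or
    ``{"family": "svm", "kernel": ..., "outlier_fraction": ...}``.
    Features are z-scored with training-fold statistics only.
    """
    feats = _feature_columns(table)
    if not feats:
        raise ValueError("feature table has no feature columns")
    if table[feats].isna().any().any():
        bad = table.loc[table[feats].isna().any(axis=1), "record_id"].tolist()
        raise ValueError(f"missing feature values for records {bad}")
    X = table[feats].to_numpy(dtype=float)
    y = (table["label"] == POSITIVE).to_numpy()
    patients = table["patient_id"].to_numpy()
    for label, name in ((True, POSITIVE), (False, NEGATIVE)):
        if len(np.unique(patients[y == label])) < 2:
            raise ValueError(f"need >= 2 patients in class {name!r}")
    preds = np.zeros_like(y)
    for pid in np.unique(patients):
        test = patients == pid
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValueError(
                f"fold for patient {pid!r} leaves a single-class training set"
            )
        Xtr, Xte = X[train], X[test]
        if standardize:
            Xtr, Xte = _zscore(Xtr, Xte)
        if model["family"] == "knn":
            p = _knn_predict(Xtr, y[train], Xte, model["k"], model["metric"])
        elif model["family"] == "svm":
            p = _svm_predict(
                Xtr, y[train], Xte, model["kernel"], model["outlier_fraction"]
            )
        else:
            raise ValueError(f"unknown model family {model['family']!r}")
        preds[test] = p

    tp = int(np.sum(preds & y))
    tn = int(np.sum(~preds & ~y))
    fp = int(np.sum(preds & ~y))
    fn = int(np.sum(~preds & y))
    acc = (tp + tn) / len(y)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    pred_df = pd.DataFrame(
        {
            "record_id": table["record_id"].to_numpy(),
            "patient_id": patients,
            "truth": np.where(y, POSITIVE, NEGATIVE),
            "predicted": np.where(preds, POSITIVE, NEGATIVE),
        }
    )
    # patient-level view: majority vote over a patient's records, tie -> control
    by_pat = pred_df.groupby("patient_id")
    pat_correct = 0
    for _, grp in by_pat:
        vote = (grp["predicted"] == POSITIVE).mean() > 0.5
        truth = (grp["truth"] == POSITIVE).iloc[0]
        pat_correct += int(vote == truth)
    return CvResult(
        predictions=pred_df,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        params=dict(model),
        patient_accuracy=pat_correct / by_pat.ngroups,
    )


# ---------------------------------------------------------------------------
# sequential model-based optimization


def _param_key(params: dict):
    return tuple(sorted(params.items()))


def _expected_improvement(mu, sigma, best):
    imp = best - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, imp / sigma, 0.0)
        ei = np.where(
            sigma > 0,
            imp * norm.cdf(z) + sigma * norm.pdf(z),
            np.maximum(imp, 0.0),
        )
    return ei


def bayes_optimize(
    table: pd.DataFrame,
    space,
    n_iter: int | None = None,
    seed: int = 0,
    standardize: bool = True,
    n_initial: int = 10,
) -> CvResult:
    """Minimize 1 - LOOCV accuracy over a discrete hyperparameter space.

    Exhaustive enumeration is used whenever ``space.size <= n_iter``;
    otherwise expected-improvement SMBO with a random-forest surrogate
    proposes points.  Defaults: 300 iterations for KNN, 50 for SVM.
    Returns the best :class:`CvResult` (tied optima resolved by
    :func:`resolve_hyperparameters`) with the full evaluation trace.
    """
    if n_iter is None:
        n_iter = space.default_n_iter
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    candidates = space.candidates()
    cache: dict = {}

    def _evaluate(params: dict) -> CvResult:
        key = _param_key(params)
        if key not in cache:
            cache[key] = loocv_evaluate(table, params, standardize=standardize)
        return cache[key]

    trace: list = []
    if len(candidates) <= n_iter:
        order = list(range(len(candidates)))
    else:
        rng = np.random.default_rng(seed)
        order = list(rng.choice(len(candidates), size=min(n_initial, n_iter),
                                replace=False))
    evaluated: list[int] = []
    for idx in order:
        res = _evaluate(candidates[idx])
        evaluated.append(idx)
        trace.append((len(trace), dict(candidates[idx]), 1.0 - res.accuracy))

    if len(candidates) > n_iter:
        X_all = np.asarray([space.encode(c) for c in candidates])
        while len(evaluated) < n_iter:
            y_obs = np.asarray([trace[i][2] for i in range(len(trace))])
            X_obs = X_all[evaluated]
            forest = RandomForestRegressor(
                n_estimators=30, random_state=seed, n_jobs=1
            )
            forest.fit(X_obs, y_obs)
            remaining = np.asarray(
                [i for i in range(len(candidates)) if i not in set(evaluated)]
            )
            tree_preds = np.stack(
                [t.predict(X_all[remaining]) for t in forest.estimators_]
            )
            mu = tree_preds.mean(axis=0)
            sigma = tree_preds.std(axis=0)
            ei = _expected_improvement(mu, sigma, y_obs.min())
            nxt = int(remaining[int(np.argmax(ei))])
            res = _evaluate(candidates[nxt])
            evaluated.append(nxt)
            trace.append((len(trace), dict(candidates[nxt]), 1.0 - res.accuracy))

    best_obj = min(t[2] for t in trace)
    optima = [t[1] for t in trace if t[2] == best_obj]
    resolved = resolve_hyperparameters(optima)
    result = _evaluate(resolved)
    result = CvResult(
        predictions=result.predictions,
        accuracy=result.accuracy,
        sensitivity=result.sensitivity,
        specificity=result.specificity,
        params=resolved,
        patient_accuracy=result.patient_accuracy,
        trace=trace,
    )
    return result


def resolve_hyperparameters(optima: list) -> dict:
    """Componentwise mode over tied optimal hyperparameter sets.

    If the mode combination is not itself one of the optima (which should
    not occur in practice) a diagnostic warning is issued and the first
    optimum in trace order is returned instead.
    """
    if not optima:
        raise ValueError("optima list is empty")
    keys = list(optima[0])
    mode_combo = {}
    for key in keys:
        values = [o[key] for o in optima]
        counts: dict = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        best = max(counts.values())
        # tie on the mode breaks to first appearance in trace order
        mode_combo[key] = next(v for v in values if counts[v] == best)
    if any(_param_key(o) == _param_key(mode_combo) for o in optima):
        return mode_combo
    warnings.warn(
        "componentwise hyperparameter mode is not among the tied optima; "
        "falling back to the first optimum in trace order",
        stacklevel=2,
    )
    return dict(optima[0])


# ---------------------------------------------------------------------------
# feature-table assembly


@dataclass(frozen=True)
class FeatureSelector:
    """Which (lead, coarse-graining, algorithm) columns enter the table.

    ``leads`` is either ``"all"`` (the 12 single leads become 12 columns)
    or a tuple of lead names; ``cg`` / ``cx`` are tuples of method names,
    crossed with each other.  ``fs`` fixes the sampling frequency.
    """

    leads: object = "all"
    cg: tuple = ("TC",)
    cx: tuple = ("LZ76",)
    fs: int = 500

    def __post_init__(self):
        if isinstance(self.cg, str):
            object.__setattr__(self, "cg", (self.cg,))
        if isinstance(self.cx, str):
            object.__setattr__(self, "cx", (self.cx,))
        if isinstance(self.leads, str) and self.leads != "all":
            object.__setattr__(self, "leads", (self.leads,))


def build_feature_table(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    selector: FeatureSelector,
    include_demographics: bool = False,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pivot tidy complexity features into one row per cohort record.

    ``features`` has columns record_id, lead, cg, cx, fs, value.  Labels
    come from the cohort arm (case -> PAF).  With ``include_demographics``
    two extra columns (age; sex encoded 0 = M, 1 = F) are appended from
    ``metadata``.  A record missing any selected feature raises an error
    naming it.
    """
    from .synth import LEAD_NAMES

    leads = LEAD_NAMES if selector.leads == "all" else tuple(selector.leads)
    sub = features[
        features["lead"].isin(leads)
        & features["cg"].isin(selector.cg)
        & features["cx"].isin(selector.cx)
        & (features["fs"] == selector.fs)
    ]
    wanted = [
        (lead, cg, cx)
        for lead in leads
        for cg in selector.cg
        for cx in selector.cx
    ]
    rows = []
    indexed = sub.set_index(["record_id", "lead", "cg", "cx"])["value"]
    for _, crow in cohort.iterrows():
        rid = crow["record_id"]
        row = {
            "record_id": rid,
            "patient_id": crow["patient_id"],
            "label": POSITIVE if crow["arm"] == "case" else NEGATIVE,
        }
        for lead, cg, cx in wanted:
            try:
                row[f"{cx}({cg})_{lead}_{selector.fs}Hz"] = float(
                    indexed.loc[(rid, lead, cg, cx)]
                )
            except KeyError:
                raise ValueError(
                    f"record {rid!r} is missing feature "
                    f"({lead}, {cg}, {cx}, {selector.fs} Hz)"
                ) from None
        rows.append(row)
    out = pd.DataFrame(rows)
    if include_demographics:
        if metadata is None:
            raise ValueError("metadata table required for demographics columns")
        demo = metadata.drop_duplicates("patient_id").set_index("patient_id")
        out["age"] = out["patient_id"].map(demo["age"]).astype(float)
        out["sex"] = (
            out["patient_id"].map(demo["sex"]).map({"M": 0.0, "F": 1.0})
        )
        if out[["age", "sex"]].isna().any().any():
            raise ValueError("demographics missing for some cohort patients")
    return out
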