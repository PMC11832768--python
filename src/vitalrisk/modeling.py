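"""Patient-level splitting, hyperparameter search, training and risk fusion.

The unit of inference is the patient, not the window sample: the train /
holdout split is stratified by outcome at the patient level, cross-validation
folds are grouped by patient id (no patient ever spans folds, the
conservative extension of train/test patient disjointness), and a patient's
30-day mortality risk is the arithmetic mean of their window-sample
probabilities.

Backends: random forest and logistic regression (scikit-learn), gradient
boosted trees (xgboost, lightgbm).  A stacking combiner fits a logistic
meta-model on out-of-fold base-model predictions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .config import ModelSpec
from .evaluation import roc_auc

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "TrainedModel",
    "PatientRisk",
    "split_patients",
    "tune_and_train",
    "predict_patient_risk",
    "fuse_patient_risks",
    "stack_models",
    "SEARCH_SPACES",
]

#: Default random-search spaces per backend.  Entries are either a list of
#: discrete choices or ("uniform"|"loguniform"|"int", low, high).
SEARCH_SPACES: dict[str, dict] = {
    "random_forest": {
        "n_estimators": ("int", 100, 400),
        "max_depth": [None, 4, 6, 8, 12, 16],
        "min_samples_leaf": ("int", 1, 8),
        "max_features": ["sqrt", 0.3, 0.5, 0.8],
    },
    "logistic_regression": {
        "C": ("loguniform", 1e-3, 1e2),
    },
    "xgboost": {
        "n_estimators": ("int", 100, 400),
        "max_depth": ("int", 2, 8),
        "learning_rate": ("loguniform", 0.01, 0.3),
        "subsample": ("uniform", 0.6, 1.0),
        "reg_lambda": ("loguniform", 0.1, 10.0),
    },
    "lightgbm": {
        "n_estimators": ("int", 100, 400),
        "num_leaves": ("int", 8, 64),
        "learning_rate": ("loguniform", 0.01, 0.3),
        "min_child_samples": ("int", 5, 50),
    },
}


@dataclass
class SplitPlan:
    """Patient-level train/holdout partition, stratified by outcome."""

    train_ids: list[str]
    holdout_ids: list[str]
    seed: int
    train_death_rate: float
    holdout_death_rate: float

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.holdout_ids):
            raise ValueError("train and holdout patient sets overlap")


@dataclass
class PatientRisk:
    """Fused 30-day mortality risk for one patient."""

    patient_id: str
    risk: float
    n_samples: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.risk <= 1.0:
            raise ValueError("risk must be in [0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class TrainedModel:
    """A fitted backend plus its feature-ordering contract and metadata."""

    backend: str
    estimator: object
    params: dict
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)

    def _matrix(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"feature contract violated; missing columns {missing[:5]}")
        return X[self.feature_names].to_numpy(dtype=float)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of 30-day death per window sample."""
        return self.estimator.predict_proba(self._matrix(X))[:, 1]

    def predict_proba_array(self, X: np.ndarray) -> np.ndarray:
        """Same, on a raw array already in contract order (used by the
        Shapley attributor, which perturbs features positionally)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise ValueError("feature contract violated: wrong width")
        return self.estimator.predict_proba(X)[:, 1]

    def save(self, directory) -> None:
        """Serialise to a directory: contract + params as JSON, backend state
        via joblib."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "backend": self.backend,
            "params": {k: v for k, v in self.params.items()},
            "feature_names": self.feature_names,
            "metadata": self.metadata,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2, default=str))
        joblib.dump(self.estimator, directory / "estimator.joblib")

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        estimator = joblib.load(directory / "estimator.joblib")
        return cls(
            backend=meta["backend"],
            estimator=estimator,
            params=meta["params"],
            feature_names=meta["feature_names"],
            metadata=meta.get("metadata", {}),
        )


def split_patients(
    ehr: pd.DataFrame,
    holdout_fraction: float = 0.10,
    seed: int = 0,
    label_col: str = "died_30d",
) -> SplitPlan:
    """Stratified patient-level train/holdout split.

    Each outcome class contributes ``round(class_size * holdout_fraction)``
    patients to the holdout (at least 1), so the death rate is preserved on
    both sides.  Deterministic given ``seed``.
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    holdout: list[str] = []
    for outcome, group in ehr.groupby(ehr[label_col].astype(bool)):
        ids = group["patient_id"].to_numpy()
        if ids.size < 2:
            raise ValueError(
                f"outcome class {outcome} has {ids.size} patient(s); need >= 2 "
                "to populate both sides of the split"
            )
        n_hold = int(round(ids.size * holdout_fraction))
        n_hold = min(max(n_hold, 1), ids.size - 1)
        perm = rng.permutation(ids)
        holdout.extend(perm[:n_hold])
        train.extend(perm[n_hold:])
    deaths = ehr.set_index("patient_id")[label_col].astype(bool)
    return SplitPlan(
        train_ids=sorted(train),
        holdout_ids=sorted(holdout),
        seed=seed,
        train_death_rate=float(deaths.loc[train].mean()),
        holdout_death_rate=float(deaths.loc[holdout].mean()),
    )


def _make_estimator(backend: str, params: dict, seed: int):
    if backend == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if backend == "logistic_regression":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed, **params)
        )
    if backend == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0, **params
        )
    if backend == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **params)
    raise ValueError(f"unknown backend: {backend}")


def _draw_params(space: dict, rng: np.random.Generator) -> dict:
    params = {}
    for name, rule in space.items():
        if isinstance(rule, list):
            params[name] = rule[rng.integers(len(rule))]
        else:
            kind, lo, hi = rule
            if kind == "int":
                params[name] = int(rng.integers(lo, hi + 1))
            elif kind == "uniform":
                params[name] = float(rng.uniform(lo, hi))
            elif kind == "loguniform":
                params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                raise ValueError(f"unknown search rule kind: {kind}")
    return params


def _feature_names(samples: pd.DataFrame) -> list[str]:
    return [c for c in samples.columns if c not in ("patient_id", "window_start_s", "label")]


def cv_fold_ids(
    samples: pd.DataFrame, cv_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Patient-grouped, outcome-stratified CV fold indices over samples."""
    y = samples["label"].to_numpy(dtype=int)
    groups = samples["patient_id"].to_numpy()
    cv = StratifiedGroupKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(len(y)), y, groups))


def tune_and_train(samples: pd.DataFrame, spec: ModelSpec | None = None) -> TrainedModel:
    """Random hyperparameter search with patient-grouped CV, then refit.

    For each of ``spec.n_search`` seeded draws from the backend's search
    space, the mean fold AUROC over ``spec.cv_folds`` patient-grouped folds
    is computed; the best configuration is refit on all training samples.
    """
    spec = spec or ModelSpec()
    y = samples["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training samples contain a single class")
    names = _feature_names(samples)
    X = samples[names].to_numpy(dtype=float)
    space = spec.search_space or SEARCH_SPACES[spec.backend]
    rng = np.random.default_rng(spec.seed)
    candidates = [_draw_params(space, rng) for _ in range(spec.n_search)]

    if spec.n_search == 1:
        # a single candidate needs no fold scoring: direct fit
        best_params, best_score = candidates[0], float("nan")
        folds = []
    else:
        folds = cv_fold_ids(samples, spec.cv_folds, spec.seed)
        best_params, best_score = None, -np.inf
    for params in candidates if spec.n_search > 1 else []:
        scores = []
        for tr, te in folds:
            if len(np.unique(y[te])) < 2:
                continue
            est = _make_estimator(spec.backend, params, spec.seed)
            est.fit(X[tr], y[tr])
            scores.append(roc_auc(y[te], est.predict_proba(X[te])[:, 1]))
        score = float(np.mean(scores)) if scores else -np.inf
        logger.info("candidate %s -> mean fold AUROC %.4f", params, score)
        if score > best_score:
            best_params, best_score = params, score

    final = _make_estimator(spec.backend, best_params, spec.seed)
    final.fit(X, y)
    return TrainedModel(
        backend=spec.backend,
        estimator=final,
        params=best_params,
        feature_names=names,
        metadata={
            "seed": spec.seed,
            "cv_folds": spec.cv_folds,
            "n_search": spec.n_search,
            "cv_auroc": best_score,
        },
    )


def predict_patient_risk(model: TrainedModel, samples: pd.DataFrame) -> PatientRisk:
    """Fuse one patient's window-sample probabilities by arithmetic mean."""
    if len(samples) == 0:
        raise ValueError("no usable windows for patient")
    pids = samples["patient_id"].unique()
    if len(pids) != 1:
        raise ValueError("samples must belong to a single patient")
    probs = model.predict_proba(samples)
    return PatientRisk(str(pids[0]), float(probs.mean()), int(len(probs)))


def fuse_patient_risks(model: TrainedModel, samples: pd.DataFrame) -> pd.DataFrame:
    """Patient-level fused risks for every patient in a sample table.

    Returns columns ``patient_id, risk, n_samples, label``.
    """
    probs = model.predict_proba(samples)
    df = pd.DataFrame(
        {
            "patient_id": samples["patient_id"].to_numpy(),
            "prob": probs,
            "label": samples["label"].to_numpy(dtype=int),
        }
    )
    agg = df.groupby("patient_id", sort=True).agg(
        risk=("prob", "mean"), n_samples=("prob", "size"), label=("label", "first")
    )
    return agg.reset_index()


class _StackedEstimator:
    """Applies base estimators then the logistic meta-model; predict_proba
    compatible with the backend estimators."""

    def __init__(self, base_estimators, meta):
        self.base_estimators = base_estimators
        self.meta = meta

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = np.column_stack([est.predict_proba(X)[:, 1] for est in self.base_estimators])
        return self.meta.predict_proba(Z)


def stack_models(
    base: list[TrainedModel],
    samples: pd.DataFrame,
    seed: int = 0,
    cv_folds: int = 5,
) -> TrainedModel:
    """Stack base models with a logistic meta-learner.

    The meta-model is fit on out-of-fold base predictions (patient-grouped
    folds) to avoid leaking training fit into the combiner; each base
    backend is refit per fold with its already-chosen hyperparameters.
    """
    if len(base) < 2:
        raise ValueError("stacking needs >= 2 base models")
    contract = base[0].feature_names
    for m in base[1:]:
        if m.feature_names != contract:
            raise ValueError("base models have mismatched feature contracts")
    y = samples["label"].to_numpy(dtype=int)
    X = samples[contract].to_numpy(dtype=float)
    folds = cv_fold_ids(samples, cv_folds, seed)
    oof = np.full((len(y), len(base)), np.nan)
    for tr, te in folds:
        for j, m in enumerate(base):
            est = _make_estimator(m.backend, m.params, seed)
            est.fit(X[tr], y[tr])
            oof[te, j] = est.predict_proba(X[te])[:, 1]
    ok = ~np.isnan(oof).any(axis=1)
    meta = LogisticRegression(max_iter=2000, random_state=seed)
    meta.fit(oof[ok], y[ok])
    stacked = _StackedEstimator([m.estimator for m in base], meta)
    return TrainedModel(
        backend="stacked:" + "+".join(m.backend for m in base),
        estimator=stacked,
        params={"meta_coef": meta.coef_.ravel().tolist(), "meta_intercept": float(meta.intercept_[0])},
        feature_names=list(contract),
        metadata={"seed": seed, "cv_folds": cv_folds},
    )
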