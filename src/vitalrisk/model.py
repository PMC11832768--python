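"""High-level modelling interface.

:class:`TransportMortalityModel` wraps the full pipeline behind a fit/results
API: build it from a featurised sample table (or straight from a cohort with
:meth:`TransportMortalityModel.from_cohort`), call :meth:`fit`, and read
estimates, uncertainties and diagnostics off the returned
:class:`TransportMortalityResults`.

Example
-------
>>> from vitalrisk import CohortConfig, generate_cohort, TransportMortalityModel
>>> ehr, vitals = generate_cohort(CohortConfig(n_patients=200, seed=3))
>>> model = TransportMortalityModel.from_cohort(ehr, vitals)
>>> results = model.fit(seed=3)
>>> print(results.summary())                         # doctest: +SKIP
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .config import ModelSpec, WindowSpec
from .evaluation import MetricsReport, compare_to_baseline, evaluate_risks, roc_auc
from .explain import RiskTrace, detect_transitions, risk_trace
from .features import build_samples, feature_columns
from .modeling import (
    SplitPlan,
    TrainedModel,
    fuse_patient_risks,
    split_patients,
    tune_and_train,
)
from .preprocessing import PatientZGrid, preprocess_cohort

logger = logging.getLogger(__name__)

__all__ = ["TransportMortalityModel", "TransportMortalityResults"]


class TransportMortalityModel:
    """Dynamic 30-day mortality model for transported critically ill children.

    Parameters
    ----------
    samples
        Window-sample table (``patient_id, window_start_s, label`` plus the
        112 feature columns) as produced by
        :func:`vitalrisk.features.build_samples`.
    ehr
        EHR table with one row per patient (used for splitting and the PIM3
        baseline).
    spec
        Backend and search settings; defaults to a random forest with a
        modest random search.
    grids
        Optional per-patient standardised streams; kept so results can
        produce per-window risk traces.
    """

    def __init__(
        self,
        samples: pd.DataFrame,
        ehr: pd.DataFrame,
        spec: ModelSpec | None = None,
        grids: dict[str, PatientZGrid] | None = None,
        window_spec: WindowSpec | None = None,
    ) -> None:
        if samples.empty:
            raise ValueError("sample table is empty")
        self.samples = samples
        self.ehr = ehr
        self.spec = spec or ModelSpec()
        self.grids = grids or {}
        self.window_spec = window_spec or WindowSpec()

    @classmethod
    def from_cohort(
        cls,
        ehr: pd.DataFrame,
        vitals: pd.DataFrame,
        spec: ModelSpec | None = None,
        window_spec: WindowSpec | None = None,
        bounds=None,
        refs=None,
        label_col: str = "died_30d",
    ) -> "TransportMortalityModel":
        """Run clean -> impute -> standardise -> featurise, then wrap the
        resulting sample table."""
        window_spec = window_spec or WindowSpec()
        grids = preprocess_cohort(vitals, ehr, bounds=bounds, refs=refs)
        samples = build_samples(ehr, grids, window_spec, label_col=label_col)
        return cls(samples, ehr, spec=spec, grids=grids, window_spec=window_spec)

    def fit(
        self,
        holdout_fraction: float = 0.10,
        seed: int | None = None,
    ) -> "TransportMortalityResults":
        """Split patients, tune with patient-grouped CV, train, and fuse
        holdout risks.  ``seed`` overrides ``spec.seed`` for both split and
        training."""
        seed = self.spec.seed if seed is None else seed
        spec = replace(self.spec, seed=seed)
        present = self.ehr[self.ehr["patient_id"].isin(self.samples["patient_id"])]
        split = split_patients(present, holdout_fraction, seed)
        train_mask = self.samples["patient_id"].isin(split.train_ids)
        train_samples = self.samples[train_mask].reset_index(drop=True)
        holdout_samples = self.samples[~train_mask].reset_index(drop=True)
        trained = tune_and_train(train_samples, spec)
        holdout_risks = fuse_patient_risks(trained, holdout_samples)
        pim3 = present.set_index("patient_id")["pim3_risk"]
        holdout_risks["pim3_risk"] = holdout_risks["patient_id"].map(pim3).to_numpy()
        return TransportMortalityResults(
            model=self,
            trained=trained,
            split=split,
            train_samples=train_samples,
            holdout_samples=holdout_samples,
            holdout_risks=holdout_risks,
        )


class TransportMortalityResults:
    """Fit artefacts: the trained backend, the split, fused holdout risks,
    and evaluation / explanation entry points."""

    def __init__(
        self,
        model: TransportMortalityModel,
        trained: TrainedModel,
        split: SplitPlan,
        train_samples: pd.DataFrame,
        holdout_samples: pd.DataFrame,
        holdout_risks: pd.DataFrame,
    ) -> None:
        self.model = model
        self.trained = trained
        self.split = split
        self.train_samples = train_samples
        self.holdout_samples = holdout_samples
        self.holdout_risks = holdout_risks
        self._metrics_cache: dict = {}
        self._threshold_cache: float | None = None

    # ---------------------------------------------------------------- metrics
    @property
    def holdout_auroc(self) -> float:
        return roc_auc(
            self.holdout_risks["label"].to_numpy(),
            self.holdout_risks["risk"].to_numpy(),
        )

    @property
    def pim3_auroc(self) -> float:
        return roc_auc(
            self.holdout_risks["label"].to_numpy(),
            self.holdout_risks["pim3_risk"].to_numpy(),
        )

    def metrics(
        self, threshold: float | None = None, n_boot: int = 1000, seed: int = 0
    ) -> MetricsReport:
        """Metric suite with bootstrap CIs on holdout patient-level risks.
        The default threshold is the Youden's J maximiser on the training
        patients' fused risks (recorded in the report)."""
        key = (threshold, n_boot, seed)
        if key not in self._metrics_cache:
            if threshold is None:
                threshold = self.training_threshold()
            self._metrics_cache[key] = evaluate_risks(
                self.holdout_risks["label"].to_numpy(),
                self.holdout_risks["risk"].to_numpy(),
                threshold=threshold,
                n_boot=n_boot,
                seed=seed,
            )
        return self._metrics_cache[key]

    def training_threshold(self, cv_folds: int = 5) -> float:
        """Youden's J-optimal threshold on *out-of-fold* training-patient
        fused risks.

        In-sample risks of a flexible backend are nearly separated, which
        would push the threshold far above anything a held-out patient
        reaches; out-of-fold predictions (patient-grouped folds, backend
        refit per fold with the chosen hyperparameters) estimate the risk
        scale the holdout actually sees.  Falls back to in-sample risks
        (logged) for backends that cannot be refit.
        """
        from .evaluation import youden_threshold
        from .modeling import _make_estimator, cv_fold_ids

        if self._threshold_cache is not None:
            return self._threshold_cache
        samples = self.train_samples
        y = samples["label"].to_numpy(dtype=int)
        X = samples[self.trained.feature_names].to_numpy(dtype=float)
        probs = np.full(len(y), np.nan)
        try:
            seed = int(self.trained.metadata.get("seed", 0))
            for tr, te in cv_fold_ids(samples, cv_folds, seed):
                est = _make_estimator(self.trained.backend, self.trained.params, seed)
                est.fit(X[tr], y[tr])
                probs[te] = est.predict_proba(X[te])[:, 1]
        except Exception:  # e.g. a stacked backend without a refit recipe
            logger.warning(
                "out-of-fold refit unavailable for backend %s; threshold "
                "falls back to in-sample training risks", self.trained.backend,
            )
            probs = self.trained.predict_proba(samples)
        frame = pd.DataFrame(
            {"patient_id": samples["patient_id"], "prob": probs, "label": y}
        ).dropna(subset=["prob"])
        fused = frame.groupby("patient_id").agg(
            risk=("prob", "mean"), label=("label", "first")
        )
        self._threshold_cache = youden_threshold(
            fused["label"].to_numpy(), fused["risk"].to_numpy()
        )
        return self._threshold_cache

    def compare_to_baseline(self, n_boot: int = 1000, seed: int = 0) -> dict:
        """Paired model-vs-PIM3 reports plus a per-patient scatter table."""
        model_part = self.holdout_risks[["patient_id", "risk", "label"]]
        pim3_part = self.holdout_risks[["patient_id", "pim3_risk", "label"]]
        return compare_to_baseline(
            model_part, pim3_part, threshold=self.training_threshold(),
            n_boot=n_boot, seed=seed,
        )

    # ------------------------------------------------------------ explanation
    def background(self, size: int = 100, seed: int = 0) -> np.ndarray:
        """Seeded subsample of training feature rows used as the Shapley
        background distribution."""
        cols = [c for c in feature_columns() if c in self.train_samples.columns]
        X = self.train_samples[cols].to_numpy(dtype=float)
        rng = np.random.default_rng(seed)
        idx = rng.choice(X.shape[0], size=min(size, X.shape[0]), replace=False)
        return X[idx]

    def risk_trace(
        self,
        patient_id: str,
        interval_minutes: float = 10.0,
        n_perms: int = 200,
        seed: int = 0,
        background_size: int = 100,
    ) -> RiskTrace:
        """Per-interval risk trace with Shapley attributions for one patient
        (requires the model to have been built from a cohort so the
        standardised streams are available)."""
        if patient_id not in self.model.grids:
            raise KeyError(f"no standardised stream for patient {patient_id}")
        record = (
            self.model.ehr.set_index("patient_id").loc[patient_id].to_dict()
            | {"patient_id": patient_id}
        )
        return risk_trace(
            self.trained,
            self.model.grids[patient_id],
            record,
            self.background(background_size, seed),
            interval_minutes=interval_minutes,
            n_perms=n_perms,
            seed=seed,
        )

    def transitions(self, patient_id: str, **kwargs) -> list:
        """Transition events of a patient's risk trace."""
        return detect_transitions(self.risk_trace(patient_id, **kwargs))

    # ---------------------------------------------------------------- display
    def plot_comparison(self, ax=None, n_boot: int = 200, seed: int = 0):
        """Scatter of fused model risk vs PIM3 risk, coloured by outcome."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        df = self.holdout_risks
        for outcome, colour, name in ((0, "tab:blue", "survived"), (1, "tab:orange", "died")):
            sub = df[df["label"] == outcome]
            ax.scatter(sub["pim3_risk"], sub["risk"], c=colour, label=name, alpha=0.7)
        ax.set_xlabel("PIM3 predicted risk")
        ax.set_ylabel("fused model risk")
        ax.legend()
        return ax

    def summary(self, n_boot: int = 1000, seed: int = 0) -> str:
        """Plain-text summary of the fit and holdout evaluation."""
        rep = self.metrics(n_boot=n_boot, seed=seed)
        lines = [
            "Transport mortality model (30-day outcome)",
            "=" * 58,
            f"backend:            {self.trained.backend}",
            f"hyperparameters:    {self.trained.params}",
            f"train patients:     {len(self.split.train_ids)}"
            f" (death rate {self.split.train_death_rate:.3f})",
            f"holdout patients:   {len(self.split.holdout_ids)}"
            f" (death rate {self.split.holdout_death_rate:.3f})",
            f"window samples:     {len(self.train_samples)} train"
            f" / {len(self.holdout_samples)} holdout",
            f"decision threshold: {rep.threshold:.3f}",
            "-" * 58,
            f"{'metric':<10}{'value':>8}{'95% CI':>20}",
        ]
        for name, (value, lo, hi) in rep.metrics.items():
            lines.append(f"{name:<10}{value:>8.3f}{f'({lo:.3f}, {hi:.3f})':>20}")
        lines.append("-" * 58)
        lines.append(f"PIM3 baseline AUROC: {self.pim3_auroc:.3f}")
        return "\n".join(lines)
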