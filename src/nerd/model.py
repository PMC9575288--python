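"""Model/Results facade over the training machinery.

:class:`DrugResponseModel` is constructed from a :class:`~nerd.core_data.Dataset`
(or a data manifest, or a synthetic scenario); :meth:`DrugResponseModel.fit`
trains the multichannel network on a split and returns a
:class:`DrugResponseResults` carrying the trained network, per-partition
metrics, the training history and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import Dataset, PreprocessReport, invert_labels, preprocess_responses
from .train_eval import (CVResult, MetricsReport, SplitSpec, TrainedModel,
                         TrainingConfig, data_reduction_experiment, five_fold_cv,
                         make_split, train_model)


class DrugResponseModel:
    """Multichannel drug-response prediction model bound to a dataset.

    Parameters
    ----------
    dataset:
        Drugs, cell lines and responses.  If the responses carry no labels
        yet, the preprocessing pipeline (drop non-positive, log, joint IQR
        outlier filter, min-max) is applied at construction.
    config:
        Training configuration; defaults are desk-scale (see docs/methods.md).
    """

    def __init__(self, dataset: Dataset, config: TrainingConfig | None = None):
        self.config = config or TrainingConfig()
        self.preprocess_report: PreprocessReport | None = None
        if any(r.label is None for r in dataset.responses):
            retained, report = preprocess_responses(dataset.responses)
            dataset.responses = retained
            dataset.label_bounds = report.bounds
            self.preprocess_report = report
        self.dataset = dataset

    @classmethod
    def from_manifest(cls, path, config: TrainingConfig | None = None
                      ) -> "DrugResponseModel":
        from .core_data import load_manifest
        return cls(load_manifest(path), config)

    @classmethod
    def from_synthetic(cls, scenario=None, config: TrainingConfig | None = None
                       ) -> "DrugResponseModel":
        from .synthetic import generate_scenario
        dataset, _ = generate_scenario(scenario)
        return cls(dataset, config)

    # ------------------------------------------------------------------ fit
    def fit(self, split: str | SplitSpec = "mixed", seed: int = 0,
            ratios: tuple[int, int, int] = (8, 1, 1)) -> "DrugResponseResults":
        if isinstance(split, str):
            split = make_split(self.dataset, mode=split, ratios=ratios, seed=seed)
        trained = train_model(self.dataset, split, self.config, seed=seed)
        metrics = {}
        for name, idx in (("train", split.train_idx), ("val", split.val_idx),
                          ("test", split.test_idx)):
            if len(idx) >= 2:
                metrics[name] = trained.evaluate(self.dataset, idx)
        return DrugResponseResults(self, trained, split, metrics)

    def fit_cv(self, seed: int = 0) -> CVResult:
        folds = five_fold_cv(self.dataset, seed=seed)
        reports = []
        for k, split in enumerate(folds):
            trained = train_model(self.dataset, split, self.config, seed=seed + k)
            reports.append(trained.evaluate(self.dataset, split.test_idx))
        return CVResult(reports)

    def fit_reduced(self, fractions=(0.5, 0.25, 0.125, 0.0625), seed: int = 0
                    ) -> dict[float, MetricsReport]:
        split = make_split(self.dataset, mode="mixed", seed=seed)
        return data_reduction_experiment(self.dataset, split, fractions,
                                         self.config, seed=seed)


class DrugResponseResults:
    """Fitted-model results: metrics, history, predictions, summary."""

    def __init__(self, model: DrugResponseModel, trained: TrainedModel,
                 split: SplitSpec, metrics: dict[str, MetricsReport]):
        self.model = model
        self.trained = trained
        self.split = split
        self.metrics = metrics
        self.history = trained.history

    @property
    def test_metrics(self) -> MetricsReport:
        return self.metrics["test"]

    def predict(self, drug_ids, cell_ids) -> np.ndarray:
        """Normalized-response predictions in (0, 1) for given pairs."""
        return self.trained.predict_pairs(list(drug_ids), list(cell_ids))

    def predict_ic50(self, drug_ids, cell_ids) -> np.ndarray:
        """Predictions mapped back to the raw IC50 concentration scale."""
        bounds = self.model.dataset.label_bounds
        if bounds is None:
            raise ValueError("dataset carries no label bounds")
        return np.exp(invert_labels(self.predict(drug_ids, cell_ids), bounds))

    def predictions_frame(self, partition: str = "test") -> pd.DataFrame:
        idx = {"train": self.split.train_idx, "val": self.split.val_idx,
               "test": self.split.test_idx}[partition]
        records = [self.model.dataset.responses[i] for i in idx]
        y_pred = self.trained.predict_responses(self.model.dataset, idx)
        return pd.DataFrame({
            "drug_id": [r.drug_id for r in records],
            "cell_id": [r.cell_id for r in records],
            "y_true": [r.label for r in records],
            "y_pred": y_pred,
        })

    def summary(self) -> str:
        spec = self.trained.config.network
        n_params = sum(p.data.size for p in self.trained.network.parameters())
        lines = [
            "Multichannel drug-response network",
            "=" * 54,
            f"channels:        {', '.join(spec.channels)}",
            f"parameters:      {n_params:,}",
            f"split mode:      {self.split.mode} (seed {self.split.seed})",
            f"pairs:           {len(self.split.train_idx)} train / "
            f"{len(self.split.val_idx)} val / {len(self.split.test_idx)} test",
            f"epochs:          {len(self.history)} "
            f"(best validation at epoch {self.trained.best_epoch})",
            "-" * 54,
            f"{'partition':<12}{'CCp':>9}{'CCs':>9}{'R2':>9}{'RMSE':>9}{'n':>6}",
        ]
        for name in ("train", "val", "test"):
            if name in self.metrics:
                m = self.metrics[name]
                lines.append(f"{name:<12}{m.cc_p:>9.3f}{m.cc_s:>9.3f}"
                             f"{m.r2:>9.3f}{m.rmse:>9.3f}{m.n:>6d}")
        lines.append("=" * 54)
        return "\n".join(lines)
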