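"""Model/Results front end over the calibration and evaluation machinery.

`FunctionalityModel` holds the data and the study design; `fit()` runs
the full training loop — stratified cross-validation, per-fold Youden
threshold calibration, exhaustive combination search, fold aggregation —
and returns a `FunctionalityResults` carrying the fitted consensus model,
its per-fold diagnostics and a printable summary, in the spirit of the
statsmodels Model/Results split.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .dataset import Dataset, dataset_from_frame, load_dataset
from .evaluate import PerformanceReport, evaluate, prediction_table
from .registry import AlgorithmSpec, default_registry
from .selection import (
    ConsensusModel,
    CrossValidationResult,
    cross_validate,
)


class FunctionalityModel:
    """Consensus functionality predictor calibrated on in-vitro activity data.

    Parameters
    ----------
    data
        A :class:`Dataset`, or a DataFrame in the annotated-score-table
        dialect (``variant_id``, ``activity``, one column per algorithm).
    registry
        Algorithm specifications; defaults to the 18-method registry when
        ``data`` is a DataFrame.

    Examples
    --------
    >>> from admeopt import FunctionalityModel, SyntheticConfig, simulate_dataset
    >>> data, _ = simulate_dataset(SyntheticConfig(seed=7))
    >>> res = FunctionalityModel(data).fit(k=5, seed=7)
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(self, data, registry: Optional[list[AlgorithmSpec]] = None):
        if isinstance(data, Dataset):
            self.dataset = data
        elif isinstance(data, pd.DataFrame):
            self.dataset = dataset_from_frame(data, registry or default_registry())
        else:
            raise TypeError("data must be a Dataset or a pandas DataFrame")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        registry: Optional[list[AlgorithmSpec]] = None,
        column_map: Optional[dict[str, str]] = None,
    ) -> "FunctionalityModel":
        reg = registry or default_registry()
        return cls(dataset_from_frame(df, reg, column_map))

    @classmethod
    def from_tsv(
        cls,
        path,
        registry: Optional[list[AlgorithmSpec]] = None,
        column_map: Optional[dict[str, str]] = None,
    ) -> "FunctionalityModel":
        dataset, _ = load_dataset(path, registry or default_registry(), column_map)
        return cls(dataset)

    def fit(
        self,
        k: int = 5,
        seed: int = 1,
        objective: str = "consensus_informedness",
        policy: str = "midpoints",
        step: Optional[float] = None,
        algorithms: Optional[Sequence[str]] = None,
        max_subset_size: Optional[int] = None,
    ) -> "FunctionalityResults":
        cv = cross_validate(
            self.dataset,
            k=k,
            seed=seed,
            policy=policy,
            step=step,
            objective=objective,
            algorithms=algorithms,
            max_subset_size=max_subset_size,
        )
        return FunctionalityResults(self, cv)


class FunctionalityResults:
    """Fitted consensus model plus cross-validation diagnostics."""

    def __init__(self, model: FunctionalityModel, cv: CrossValidationResult):
        self.model = model
        self.cv = cv

    # -- estimates ---------------------------------------------------------
    @property
    def consensus_model(self) -> ConsensusModel:
        return self.cv.model

    @property
    def selected_algorithms(self) -> tuple[str, ...]:
        return self.cv.modal_subset

    @property
    def thresholds(self) -> dict[str, float]:
        """Fold-averaged optimal thresholds, all calibrated algorithms."""
        return dict(self.cv.mean_thresholds)

    @property
    def threshold_cv(self) -> dict[str, float]:
        """|CV| of fold-optimal thresholds: the stability of calibration."""
        return dict(self.cv.threshold_cv)

    def params_frame(self) -> pd.DataFrame:
        """One row per calibrated algorithm: mean threshold, |CV|, mean delta-I."""
        rows = []
        for name, thr in self.cv.mean_thresholds.items():
            deltas = [
                fr.delta_informedness.get(name)
                for fr in self.cv.folds
                if fr.delta_informedness.get(name) is not None
            ]
            rows.append(
                {
                    "algorithm": name,
                    "mean_threshold": thr,
                    "threshold_abs_cv": self.cv.threshold_cv.get(name),
                    "mean_delta_informedness": (
                        sum(deltas) / len(deltas) if deltas else None
                    ),
                    "selected": name in self.cv.modal_subset,
                }
            )
        return pd.DataFrame(rows)

    def fold_frame(self) -> pd.DataFrame:
        rows = []
        for fr in self.cv.folds:
            rows.append(
                {
                    "fold": fr.fold,
                    "subset": "+".join(fr.subset),
                    "objective_value": fr.objective_value,
                    "train_sensitivity": fr.train_metrics["sensitivity"],
                    "train_specificity": fr.train_metrics["specificity"],
                    "val_sensitivity": fr.validation_metrics["sensitivity"],
                    "val_specificity": fr.validation_metrics["specificity"],
                    "val_informedness": fr.validation_metrics["informedness"],
                }
            )
        return pd.DataFrame(rows)

    # -- application -------------------------------------------------------
    def predict(self, dataset: Optional[Dataset] = None) -> pd.DataFrame:
        """Per-variant component calls, consensus score and call."""
        ds = dataset or self.model.dataset
        return prediction_table(ds, self.consensus_model)

    def evaluate(self, dataset: Optional[Dataset] = None) -> PerformanceReport:
        """Full stratified performance report on a dataset (default: training)."""
        ds = dataset or self.model.dataset
        return evaluate(ds, self.consensus_model)

    def save_model(self, path) -> None:
        self.consensus_model.save(
            path,
            provenance={
                "k": self.cv.k,
                "seed": self.cv.seed,
                "objective": self.cv.objective,
                "policy": self.cv.policy,
            },
        )

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        cv = self.cv
        lines = []
        title = "Consensus Functionality Model (Youden-calibrated)"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(
            f"variants: {len(self.model.dataset)}    folds: {cv.k}    "
            f"seed: {cv.seed}    objective: {cv.objective}    policy: {cv.policy}"
        )
        lines.append(f"selected components: {', '.join(cv.modal_subset)}")
        lines.append("")
        lines.append(f"{'algorithm':<24}{'threshold':>12}{'|CV|':>10}{'mean dI':>10}  sel")
        lines.append("-" * 62)
        for _, row in self.params_frame().iterrows():
            cvv = row["threshold_abs_cv"]
            di = row["mean_delta_informedness"]
            lines.append(
                f"{row['algorithm']:<24}{row['mean_threshold']:>12.4f}"
                f"{(f'{cvv:.3f}' if cvv is not None else 'NA'):>10}"
                f"{(f'{di:+.3f}' if di is not None else 'NA'):>10}"
                f"  {'*' if row['selected'] else ''}"
            )
        lines.append("")
        for which, summ in (
            ("training", cv.train_summary),
            ("validation", cv.validation_summary),
        ):
            s = summ["sensitivity"]
            p = summ["specificity"]
            j = summ["informedness"]
            lines.append(
                f"{which:<11} sensitivity {s[0] * 100:5.1f} +/- {s[1] * 100:4.1f} %   "
                f"specificity {p[0] * 100:5.1f} +/- {p[1] * 100:4.1f} %   "
                f"J {j[0]:5.3f} +/- {j[1]:5.3f}  (mean +/- SD over folds)"
            )
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<FunctionalityResults: {len(self.cv.modal_subset)} components, "
            f"k={self.cv.k}, seed={self.cv.seed}>"
        )
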