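"""Model building: stratified folds, exhaustive combination search, consensus.

The consensus model is an ordered set of (algorithm, threshold, direction)
components. Each component casts a binary call on a variant; the consensus
score is the mean of the available calls (deleterious = 1) and the variant
is flagged deleterious when the score reaches the call cutoff (default
0.5, ties flagged — the conservative choice for a screening tool).

Which algorithms to include is decided by exhaustive enumeration of all
2^m - 1 non-empty subsets of the threshold-calibrated algorithms. The
enumeration is vectorized over bit-mask blocks, so the full 18-method
panel (262,143 subsets) is searched in seconds. Three objectives are
offered: the informedness of the consensus calls (default), their
accuracy, and the mean per-component correctness (the literal
sum-of-agreement criterion, normalized by the number of available calls —
unnormalized it grows with every added component and would always select
the full panel).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .dataset import Dataset, Label
from .errors import (
    DegenerateInputError,
    ThresholdUnavailableError,
    ValidationError,
)
from .metrics import ConfusionCounts
from .registry import Direction
from .threshold import ThresholdScan, delta_informedness, optimize_threshold, threshold_stability

OBJECTIVES = ("consensus_informedness", "consensus_accuracy", "mean_component_correctness")

_TIE_TOL = 1e-12


@dataclass
class FoldAssignment:
    """A stratified k-fold partition of variant ids."""

    k: int
    fold_of: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [vid for vid, f in self.fold_of.items() if f == fold]

    def split(self, dataset: Dataset, fold: int) -> tuple[Dataset, Dataset]:
        """(train, validation) datasets for one fold."""
        val_ids = set(self.fold_ids(fold))
        train_ids = [vid for vid in self.fold_of if vid not in val_ids]
        return dataset.subset(train_ids), dataset.subset(val_ids)


def stratified_kfold(dataset: Dataset, k: int = 5, seed: int = 1) -> FoldAssignment:
    """Partition variants into k folds with near-equal class proportions.

    Within each label class the variants are shuffled (seeded) and dealt
    round-robin, so per-fold class counts differ by at most one.
    """
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    by_class: dict[Label, list[str]] = {Label.DELETERIOUS: [], Label.NEUTRAL: []}
    for rec in dataset.records:
        by_class[rec.label].append(rec.variant_id)
    fold_of: dict[str, int] = {}
    for label in (Label.DELETERIOUS, Label.NEUTRAL):
        ids = by_class[label]
        if len(ids) < k:
            raise ValidationError(
                f"class {label.value} has {len(ids)} variants, fewer than k={k}"
            )
        order = rng.permutation(len(ids))
        for pos, idx in enumerate(order):
            fold_of[ids[idx]] = pos % k
    # preserve dataset order in the mapping
    fold_of = {rec.variant_id: fold_of[rec.variant_id] for rec in dataset.records}
    return FoldAssignment(k=k, fold_of=fold_of, seed=seed)


@dataclass
class CallMatrix:
    """Binary calls of every algorithm on every variant, plus correctness.

    ``calls`` is an (m algorithms x n variants) int8 matrix: 1 deleterious,
    0 neutral, -1 missing. ``labels`` holds 1 for deleterious ground truth.
    Correctness s[l, i] = 1 iff algorithm l's call on variant i matches the
    label, 0 if it mismatches, and is undefined (masked) where the call is
    missing.
    """

    algorithms: list[str]
    variant_ids: list[str]
    calls: np.ndarray
    labels: np.ndarray

    @property
    def available(self) -> np.ndarray:
        return self.calls >= 0

    @property
    def correctness(self) -> np.ma.MaskedArray:
        s = (self.calls == self.labels[None, :]).astype(np.int8)
        return np.ma.masked_array(s, mask=~self.available)

    def call(self, algorithm: str, variant_id: str):
        c = self.calls[self.algorithms.index(algorithm),
                       self.variant_ids.index(variant_id)]
        if c < 0:
            return None
        return Label.DELETERIOUS if c == 1 else Label.NEUTRAL


def component_calls(
    dataset: Dataset,
    thresholds: dict[str, tuple[float, Direction] | float],
) -> CallMatrix:
    """Classify every variant by every thresholded algorithm.

    ``thresholds`` maps algorithm name to either (threshold, direction) or
    a bare threshold (direction taken from the registry). Calls are strict
    inequalities; a missing score yields a missing call.
    """
    algos = list(thresholds)
    resolved: list[tuple[str, float, Direction]] = []
    for name in algos:
        spec = dataset.spec(name)  # raises on unknown algorithm
        val = thresholds[name]
        if isinstance(val, tuple):
            thr, direction = val
        else:
            thr, direction = float(val), spec.direction
        resolved.append((name, float(thr), direction))
    n = len(dataset.records)
    calls = np.full((len(algos), n), -1, dtype=np.int8)
    labels = np.array(
        [1 if rec.label is Label.DELETERIOUS else 0 for rec in dataset.records],
        dtype=np.int8,
    )
    for li, (name, thr, direction) in enumerate(resolved):
        for i, rec in enumerate(dataset.records):
            s = rec.scores.get(name)
            if s is None:
                continue
            if direction is Direction.GREATER:
                calls[li, i] = 1 if s > thr else 0
            else:
                calls[li, i] = 1 if s < thr else 0
    return CallMatrix(
        algorithms=algos,
        variant_ids=[rec.variant_id for rec in dataset.records],
        calls=calls,
        labels=labels.astype(np.int8),
    )


@dataclass(frozen=True)
class CombinationResult:
    """Winner of the exhaustive subset search."""

    subset: tuple[str, ...]
    objective_name: str
    objective_value: float
    per_variant_correct: int
    n_subsets_evaluated: int


def _subset_masks(m: int, indices: np.ndarray) -> np.ndarray:
    """(len(indices), m) float32 membership matrix for subset bit-masks."""
    bits = (indices[:, None] >> np.arange(m)[None, :]) & 1
    return bits.astype(np.float64)


def _consensus_pred(masks, calls_f, avail_f):
    """Consensus deleterious calls for a block of subsets.

    Returns (pred, valid): pred[s, i] True where the subset flags variant i
    (mean call >= 0.5, ties flagged), valid[s, i] True where the subset has
    at least one available call.
    """
    num = masks @ calls_f     # deleterious votes
    den = masks @ avail_f     # available votes
    valid = den > 0
    pred = (2.0 * num >= den) & valid
    return pred, valid


def select_combination(
    calls: CallMatrix,
    objective: str = "consensus_informedness",
    max_subset_size: Optional[int] = None,
    block: int = 8192,
) -> CombinationResult:
    """Exhaustively search algorithm subsets for the best consensus model.

    Every non-empty subset (optionally capped at ``max_subset_size``
    members) is scored; ties are broken toward the smaller subset, then
    lexicographically by algorithm name.
    """
    if objective not in OBJECTIVES:
        raise ValidationError(f"unknown objective {objective!r}")
    m = len(calls.algorithms)
    if m == 0:
        raise ValidationError("no algorithms to combine")
    avail = calls.available
    if not avail.any():
        raise ValidationError("no valid calls in the call matrix")
    y = calls.labels.astype(np.float64)
    if y.min() == y.max():
        raise ValidationError("both classes must be present")

    calls_f = (calls.calls == 1).astype(np.float64)
    avail_f = avail.astype(np.float64)
    correct_f = ((calls.calls == calls.labels[None, :]) & avail).astype(np.float64)
    # per-algorithm totals for the normalized sum-of-agreement objective
    r_sum = correct_f.sum(axis=1)
    a_sum = avail_f.sum(axis=1)

    names = calls.algorithms
    sizes_cache = None

    best_idx = -1
    best_value = -np.inf
    best_key = None  # (size, sorted name tuple)
    n_evaluated = 0

    all_indices = np.arange(1, 2 ** m, dtype=np.int64)
    for start in range(0, all_indices.size, block):
        idx = all_indices[start : start + block]
        masks = _subset_masks(m, idx)
        sizes = masks.sum(axis=1)
        if max_subset_size is not None:
            keep = sizes <= max_subset_size
            idx, masks, sizes = idx[keep], masks[keep], sizes[keep]
            if idx.size == 0:
                continue
        n_evaluated += idx.size

        if objective == "mean_component_correctness":
            den = masks @ a_sum
            values = np.where(den > 0, (masks @ r_sum) / np.maximum(den, 1), -np.inf)
        else:
            pred, valid = _consensus_pred(masks, calls_f, avail_f)
            predf = pred.astype(np.float64)
            validf = valid.astype(np.float64)
            tp = predf @ y
            fp = predf @ (1.0 - y)
            pos = validf @ y
            neg = validf @ (1.0 - y)
            if objective == "consensus_informedness":
                with np.errstate(invalid="ignore", divide="ignore"):
                    sens = tp / pos
                    spec = (neg - fp) / neg
                values = np.where((pos > 0) & (neg > 0), sens + spec - 1.0, -np.inf)
            else:  # consensus_accuracy
                total = pos + neg
                with np.errstate(invalid="ignore", divide="ignore"):
                    values = np.where(total > 0, (tp + (neg - fp)) / total, -np.inf)

        # keep a single running champion; ties resolved by (size, names)
        block_max = values.max()
        if block_max < best_value - _TIE_TOL:
            continue
        tied = np.flatnonzero(values >= max(block_max, best_value) - _TIE_TOL)
        for t in tied:
            members = tuple(
                sorted(names[b] for b in range(m) if (int(idx[t]) >> b) & 1)
            )
            key = (len(members), members)
            if (
                values[t] > best_value + _TIE_TOL
                or (values[t] >= best_value - _TIE_TOL
                    and (best_key is None or key < best_key))
            ):
                best_value = float(values[t])
                best_key = key
                best_idx = int(idx[t])

    if best_idx < 0:
        raise ValidationError("no admissible subset found")

    # recompute the winner's per-variant correctness from scratch
    members_bits = [b for b in range(m) if (best_idx >> b) & 1]
    mask = np.zeros((1, m), dtype=np.float64)
    mask[0, members_bits] = 1.0
    pred, valid = _consensus_pred(mask, calls_f, avail_f)
    correct = int(((pred[0] == (y == 1)) & valid[0]).sum())

    return CombinationResult(
        subset=best_key[1],
        objective_name=objective,
        objective_value=best_value,
        per_variant_correct=correct,
        n_subsets_evaluated=n_evaluated,
    )


@dataclass(frozen=True)
class ModelComponent:
    algorithm: str
    threshold: float
    direction: Direction


@dataclass
class ConsensusModel:
    """An ordered set of thresholded algorithms voting on deleteriousness."""

    components: list[ModelComponent]
    call_cutoff: float = 0.5

    def __post_init__(self):
        names = [c.algorithm for c in self.components]
        if len(set(names)) != len(names):
            raise ValidationError("component algorithm names must be unique")
        for c in self.components:
            if not np.isfinite(c.threshold):
                raise ValidationError(f"{c.algorithm}: threshold must be finite")
        if not 0 < self.call_cutoff < 1:
            raise ValidationError("call_cutoff must be in (0, 1)")

    @property
    def algorithm_names(self) -> list[str]:
        return [c.algorithm for c in self.components]

    def to_dict(self, provenance: Optional[dict] = None) -> dict:
        d = {
            "call_cutoff": self.call_cutoff,
            "components": [
                {
                    "algorithm": c.algorithm,
                    "threshold": c.threshold,
                    "direction": c.direction.value,
                }
                for c in self.components
            ],
        }
        if provenance:
            d["provenance"] = provenance
        return d

    def save(self, path, provenance: Optional[dict] = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(provenance), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ConsensusModel":
        return cls(
            components=[
                ModelComponent(
                    algorithm=c["algorithm"],
                    threshold=float(c["threshold"]),
                    direction=Direction(c["direction"]),
                )
                for c in d["components"]
            ],
            call_cutoff=float(d.get("call_cutoff", 0.5)),
        )

    @classmethod
    def load(cls, path) -> "ConsensusModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def published_model() -> ConsensusModel:
    """The fixed five-component pharmacogenetic consensus model.

    LRT, MutationAssessor, PROVEAN, VEST3 and CADD at their
    ADME-optimized cutoffs, majority cutoff 0.5.
    """
    return ConsensusModel(
        components=[
            ModelComponent("LRT", 0.0025, Direction.LESS),
            ModelComponent("MutationAssessor", 2.0566, Direction.GREATER),
            ModelComponent("PROVEAN", -3.286, Direction.LESS),
            ModelComponent("VEST3", 0.4534, Direction.GREATER),
            ModelComponent("CADD", 19.19, Direction.GREATER),
        ],
        call_cutoff=0.5,
    )


def _model_confusion(dataset: Dataset, model: ConsensusModel) -> ConfusionCounts:
    """Confusion counts of consensus calls on a dataset (missing excluded)."""
    from .evaluate import consensus_call, consensus_score  # local: avoid cycle

    tp = fp = tn = fn = 0
    for rec in dataset.records:
        score = consensus_score(rec, model)
        call = consensus_call(score, model.call_cutoff)
        if call is None:
            continue
        if rec.label is Label.DELETERIOUS:
            if call is Label.DELETERIOUS:
                tp += 1
            else:
                fn += 1
        else:
            if call is Label.NEUTRAL:
                tn += 1
            else:
                fp += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class FoldResult:
    """Everything learned on one cross-validation fold."""

    fold: int
    thresholds: dict[str, float]
    scans: list[ThresholdScan]
    subset: tuple[str, ...]
    objective_value: float
    delta_informedness: dict[str, Optional[float]]
    train_metrics: dict[str, float]
    validation_metrics: dict[str, float]


@dataclass
class CrossValidationResult:
    """Per-fold diagnostics plus the fold-aggregated consensus model."""

    folds: list[FoldResult]
    model: ConsensusModel
    modal_subset: tuple[str, ...]
    mean_thresholds: dict[str, float]
    threshold_cv: dict[str, float]
    train_summary: dict[str, tuple[float, float]]       # metric -> (mean, sd)
    validation_summary: dict[str, tuple[float, float]]
    k: int
    seed: int
    objective: str
    policy: str


def _metric_dict(c: ConfusionCounts) -> dict[str, float]:
    from . import metrics as M

    out = {}
    for name, fn in (
        ("sensitivity", M.sensitivity),
        ("specificity", M.specificity),
        ("accuracy", M.accuracy),
        ("informedness", M.informedness),
    ):
        try:
            out[name] = fn(c)
        except Exception:
            out[name] = float("nan")
    out.update(tp=c.tp, fp=c.fp, tn=c.tn, fn=c.fn)
    return out


def cross_validate(
    dataset: Dataset,
    k: int = 5,
    seed: int = 1,
    policy: str = "midpoints",
    step: Optional[float] = None,
    objective: str = "consensus_informedness",
    algorithms: Optional[Sequence[str]] = None,
    max_subset_size: Optional[int] = None,
) -> CrossValidationResult:
    """Full training loop: k stratified folds, per-fold threshold
    calibration and exhaustive combination selection, held-out validation,
    and fold aggregation.

    Per fold the thresholds are optimized and the subset selected on the
    training split only; the resulting fold model is then scored on the
    held-out fold. The aggregated model uses per-algorithm thresholds
    averaged across folds and the modal chosen subset (ties toward the
    smaller subset, then lexicographic).
    """
    assignment = stratified_kfold(dataset, k=k, seed=seed)
    algo_names = list(algorithms) if algorithms else dataset.algorithm_names
    reg = {spec.name: spec for spec in dataset.registry}

    fold_results: list[FoldResult] = []
    all_scans: list[ThresholdScan] = []
    for fold in range(k):
        train, val = assignment.split(dataset, fold)
        thresholds: dict[str, float] = {}
        scans: list[ThresholdScan] = []
        deltas: dict[str, Optional[float]] = {}
        for name in algo_names:
            try:
                scan = optimize_threshold(train, name, policy=policy, step=step)
            except (DegenerateInputError, ValidationError):
                continue  # algorithm unusable on this training split
            thresholds[name] = scan.optimal_threshold
            scans.append(scan)
            try:
                deltas[name] = delta_informedness(scan, reg[name], train).delta
            except ThresholdUnavailableError:
                deltas[name] = None
        if not thresholds:
            raise ValidationError(f"fold {fold}: no algorithm could be optimized")

        matrix = component_calls(train, thresholds)
        combo = select_combination(
            matrix, objective=objective, max_subset_size=max_subset_size
        )
        fold_model = ConsensusModel(
            components=[
                ModelComponent(name, thresholds[name], reg[name].direction)
                for name in combo.subset
            ]
        )
        fold_results.append(
            FoldResult(
                fold=fold,
                thresholds=thresholds,
                scans=scans,
                subset=combo.subset,
                objective_value=combo.objective_value,
                delta_informedness=deltas,
                train_metrics=_metric_dict(_model_confusion(train, fold_model)),
                validation_metrics=_metric_dict(_model_confusion(val, fold_model)),
            )
        )
        all_scans.extend(scans)

    # fold aggregation
    subset_counts = Counter(fr.subset for fr in fold_results)
    top = max(subset_counts.values())
    modal_subset = min(
        (s for s, c in subset_counts.items() if c == top),
        key=lambda s: (len(s), s),
    )
    mean_thresholds: dict[str, float] = {}
    for name in algo_names:
        vals = [fr.thresholds[name] for fr in fold_results if name in fr.thresholds]
        if vals:
            mean_thresholds[name] = float(np.mean(vals))
    model = ConsensusModel(
        components=[
            ModelComponent(name, mean_thresholds[name], reg[name].direction)
            for name in modal_subset
        ]
    )
    cv_scans = [s for s in all_scans
                if sum(1 for t in all_scans if t.algorithm == s.algorithm) >= 2]
    threshold_cv = threshold_stability(cv_scans) if cv_scans else {}

    def _summary(which: str) -> dict[str, tuple[float, float]]:
        out = {}
        for metric in ("sensitivity", "specificity", "accuracy", "informedness"):
            vals = np.array(
                [getattr(fr, which)[metric] for fr in fold_results], dtype=float
            )
            out[metric] = (float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1)))
        return out

    return CrossValidationResult(
        folds=fold_results,
        model=model,
        modal_subset=modal_subset,
        mean_thresholds=mean_thresholds,
        threshold_cv=threshold_cv,
        train_summary=_summary("train_metrics"),
        validation_summary=_summary("validation_metrics"),
        k=k,
        seed=seed,
        objective=objective,
        policy=policy,
    )
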