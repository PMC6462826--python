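from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from admeopt import AlgorithmSpec, Category, Dataset, Direction, VariantRecord
from admeopt.registry import default_registry

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def registry():
    return default_registry()


@pytest.fixture
def fixture_path():
    return DATA_DIR / "variants6.tsv"


def make_single_algo_dataset(
    scores,
    labels,
    direction=Direction.GREATER,
    name="ALG",
    nominal_range=(-1e6, 1e6),
):
    """Dataset with one algorithm; labels given as 'D'/'N' strings.

    A score of None leaves the record without a score from this algorithm.
    """
    spec = AlgorithmSpec(
        name=name,
        direction=direction,
        nominal_range=nominal_range,
        input_column=name,
        category=Category.FUNCTIONALITY,
    )
    records = []
    for i, (s, lab) in enumerate(zip(scores, labels)):
        records.append(
            VariantRecord(
                variant_id=f"v{i}",
                activity=0.1 if lab == "D" else 1.0,
                scores={} if s is None else {name: float(s)},
            )
        )
    return Dataset(records=records, registry=[spec])


def make_multi_algo_dataset(score_matrix, labels, directions=None, names=None,
                            activities=None, mafs=None):
    """Dataset with several algorithms; score_matrix[i][j] scores variant i
    by algorithm j (None = missing)."""
    n = len(score_matrix)
    m = len(score_matrix[0])
    names = names or [f"A{j}" for j in range(m)]
    directions = directions or [Direction.GREATER] * m
    specs = [
        AlgorithmSpec(
            name=names[j],
            direction=directions[j],
            nominal_range=(-1e6, 1e6),
            input_column=names[j],
            category=Category.FUNCTIONALITY,
        )
        for j in range(m)
    ]
    records = []
    for i in range(n):
        scores = {
            names[j]: float(score_matrix[i][j])
            for j in range(m)
            if score_matrix[i][j] is not None
        }
        act = (
            activities[i]
            if activities is not None
            else (0.1 if labels[i] == "D" else 1.0)
        )
        records.append(
            VariantRecord(
                variant_id=f"v{i}",
                activity=act,
                maf=mafs[i] if mafs is not None else None,
                scores=scores,
            )
        )
    return Dataset(records=records, registry=specs)


def brute_force_threshold(scores, labels01, greater=True):
    """Independent exhaustive sweep over all achievable operating points.

    Returns (best_threshold, best_j) by naive counting at every candidate
    threshold (outside the extremes, at every observed score and between
    every adjacent pair).
    """
    scores = np.asarray(scores, dtype=float)
    labels01 = np.asarray(labels01)
    u = np.unique(scores)
    cands = np.concatenate(
        [[u[0] - 1.0], u, (u[:-1] + u[1:]) / 2.0 if u.size > 1 else [], [u[-1] + 1.0]]
    )
    best_j, best_t = -2.0, None
    for t in cands:
        calls = scores > t if greater else scores < t
        tp = int(np.sum(calls & (labels01 == 1)))
        fn = int(np.sum(~calls & (labels01 == 1)))
        fp = int(np.sum(calls & (labels01 == 0)))
        tn = int(np.sum(~calls & (labels01 == 0)))
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_t, best_j


def rank_statistic_auc(scores, labels01):
    """AUC as P(deleterious score > neutral score), ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels01 = np.asarray(labels01)
    pos = scores[labels01 == 1]
    neg = scores[labels01 == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
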