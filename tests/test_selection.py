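"""Stratified folds, exhaustive combination search, cross-validation."""

import itertools
from collections import Counter

import numpy as np
import pytest

from admeopt import (
    ConsensusModel,
    Direction,
    Label,
    SyntheticConfig,
    SyntheticAlgorithm,
    component_calls,
    cross_validate,
    published_model,
    select_combination,
    simulate_dataset,
    stratified_kfold,
)
from admeopt.errors import ValidationError
from admeopt.registry import default_registry, registry_by_name

from conftest import make_multi_algo_dataset, make_single_algo_dataset


class TestStratifiedKFold:
    def test_exact_split_when_divisible(self):
        ds = make_single_algo_dataset(range(20), ["D"] * 10 + ["N"] * 10)
        fa = stratified_kfold(ds, k=5, seed=1)
        for fold in range(5):
            ids = fa.fold_ids(fold)
            labels = Counter(
                "D" if int(v[1:]) < 10 else "N" for v in ids
            )
            assert labels["D"] == 2 and labels["N"] == 2

    def test_same_seed_identical(self):
        ds = make_single_algo_dataset(range(30), ["D"] * 13 + ["N"] * 17)
        assert stratified_kfold(ds, 5, seed=9).fold_of == \
            stratified_kfold(ds, 5, seed=9).fold_of

    def test_unbalanced_class_counts_within_one(self):
        """109 deleterious + 71 neutral over 5 folds: per-fold class counts
        stay within one of 21.8 and 14.2."""
        n_d, n_n = 109, 71
        ds = make_single_algo_dataset(
            range(n_d + n_n), ["D"] * n_d + ["N"] * n_n
        )
        fa = stratified_kfold(ds, k=5, seed=3)
        for fold in range(5):
            ids = fa.fold_ids(fold)
            d = sum(1 for v in ids if int(v[1:]) < n_d)
            n = len(ids) - d
            assert abs(d - n_d / 5) < 1
            assert abs(n - n_n / 5) < 1

    def test_folds_partition_dataset(self):
        ds = make_single_algo_dataset(range(23), ["D"] * 11 + ["N"] * 12)
        fa = stratified_kfold(ds, k=4, seed=2)
        all_ids = [v for f in range(4) for v in fa.fold_ids(f)]
        assert sorted(all_ids) == sorted(r.variant_id for r in ds.records)
        assert len(set(all_ids)) == len(all_ids)

    def test_class_smaller_than_k_rejected(self):
        ds = make_single_algo_dataset(range(6), ["D"] * 2 + ["N"] * 4)
        with pytest.raises(ValidationError):
            stratified_kfold(ds, k=3, seed=1)


class TestComponentCalls:
    def test_published_threshold_semantics(self):
        """A SIFT score of 0.01 under the optimized <0.0376 cutoff is
        deleterious; a CADD score of 10 under >19.19 is neutral."""
        registry = default_registry()
        by = registry_by_name(registry)
        from admeopt import Dataset, VariantRecord

        ds = Dataset(
            records=[
                VariantRecord("a", activity=0.1,
                              scores={"SIFT": 0.01, "CADD": 10.0}),
                VariantRecord("b", activity=1.0, scores={"CADD": 30.0}),
            ],
            registry=registry,
        )
        cm = component_calls(
            ds,
            {"SIFT": by["SIFT"].optimized_threshold,
             "CADD": by["CADD"].optimized_threshold},
        )
        assert cm.call("SIFT", "a") is Label.DELETERIOUS
        assert cm.call("CADD", "a") is Label.NEUTRAL
        assert cm.call("SIFT", "b") is None  # missing score -> missing call
        assert cm.call("CADD", "b") is Label.DELETERIOUS

    def test_missing_excluded_from_correctness(self):
        ds = make_single_algo_dataset([None, 2.0], ["D", "D"])
        cm = component_calls(ds, {"ALG": 1.0})
        s = cm.correctness
        assert s.mask[0, 0] and not s.mask[0, 1]
        assert s[0, 1] == 1  # call deleterious (2 > 1), label deleterious

    def test_unknown_algorithm_rejected(self):
        ds = make_single_algo_dataset([1.0], ["D"])
        with pytest.raises(ValidationError):
            component_calls(ds, {"NOPE": 0.5})


def naive_best_subset(cm, labels01, objective):
    """Independent re-scoring of every subset with plain python loops."""
    names = cm.algorithms
    best = None  # (value, size, subset)
    count = 0
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(sorted(names), r):
            count += 1
            num_correct = avail_pairs = correct_pairs = 0
            tp = fp = tn = fn = 0
            for i in range(len(cm.variant_ids)):
                votes = []
                for name in combo:
                    c = cm.calls[names.index(name), i]
                    if c < 0:
                        continue
                    votes.append(int(c))
                    avail_pairs += 1
                    if int(c) == int(labels01[i]):
                        correct_pairs += 1
                if not votes:
                    continue
                call = 1 if sum(votes) / len(votes) >= 0.5 else 0
                if labels01[i] == 1:
                    tp, fn = tp + (call == 1), fn + (call == 0)
                else:
                    fp, tn = fp + (call == 1), tn + (call == 0)
            if objective == "mean_component_correctness":
                value = correct_pairs / avail_pairs if avail_pairs else -np.inf
            elif objective == "consensus_accuracy":
                tot = tp + fp + tn + fn
                value = (tp + tn) / tot if tot else -np.inf
            else:
                if tp + fn == 0 or tn + fp == 0:
                    value = -np.inf
                else:
                    value = tp / (tp + fn) + tn / (tn + fp) - 1.0
            key = (len(combo), combo)
            if (
                best is None
                or value > best[0] + 1e-12
                or (abs(value - best[0]) <= 1e-12 and key < (best[1], best[2]))
            ):
                best = (value, len(combo), combo)
    return best[2], best[0], count


class TestSelectCombination:
    def test_single_perfect_algorithm_wins_alone(self):
        rng = np.random.default_rng(0)
        n = 30
        y = np.array([1] * 15 + [0] * 15)
        perfect = y * 10.0
        noisy1 = rng.normal(size=n)
        noisy2 = rng.normal(size=n)
        ds = make_multi_algo_dataset(
            np.column_stack([perfect, noisy1, noisy2]).tolist(),
            ["D" if v else "N" for v in y],
            names=["GOOD", "N1", "N2"],
        )
        cm = component_calls(ds, {"GOOD": 5.0, "N1": 0.0, "N2": 0.0})
        res = select_combination(cm)
        assert res.subset == ("GOOD",)
        assert res.objective_value == 1.0

    @pytest.mark.parametrize(
        "objective",
        ["consensus_informedness", "consensus_accuracy", "mean_component_correctness"],
    )
    def test_toy_matches_naive_re_scoring(self, objective):
        rng = np.random.default_rng(7)
        n, m = 12, 4
        y = np.array([1] * 6 + [0] * 6)
        mat = rng.normal(y[:, None] * 1.0, 1.0, size=(n, m)).tolist()
        mat[3][2] = None  # a missing call
        ds = make_multi_algo_dataset(mat, ["D" if v else "N" for v in y])
        cm = component_calls(ds, {f"A{j}": 0.5 for j in range(m)})
        res = select_combination(cm, objective=objective)
        subset, value, count = naive_best_subset(cm, y, objective)
        assert res.subset == subset
        assert res.objective_value == pytest.approx(value, abs=1e-9)
        assert res.n_subsets_evaluated == count == 2**m - 1

    @pytest.mark.parametrize("seed", range(8))
    def test_random_m6_matches_naive(self, seed):
        rng = np.random.default_rng(200 + seed)
        n, m = 25, 6
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        mat = rng.normal(y[:, None] * rng.uniform(0.3, 2.0, size=m), 1.0)
        miss = rng.random((n, m)) < 0.1
        matl = [
            [None if miss[i, j] else float(mat[i, j]) for j in range(m)]
            for i in range(n)
        ]
        ds = make_multi_algo_dataset(matl, ["D" if v else "N" for v in y])
        cm = component_calls(ds, {f"A{j}": 0.5 for j in range(m)})
        res = select_combination(cm)
        subset, value, _ = naive_best_subset(cm, y, "consensus_informedness")
        assert res.objective_value == pytest.approx(value, abs=1e-6)
        assert res.subset == subset

    def test_mean_correctness_hand_computed(self):
        # 2 algorithms, 3 variants, no missingness
        # labels:        D  D  N
        # A0 calls:      D  N  N   -> correct 1,0,1
        # A1 calls:      D  D  D   -> correct 1,1,0
        ds = make_multi_algo_dataset(
            [[1.0, 1.0], [0.0, 1.0], [0.0, 1.0]],
            ["D", "D", "N"],
        )
        cm = component_calls(ds, {"A0": 0.5, "A1": 0.5})
        res = select_combination(cm, objective="mean_component_correctness")
        # singleton {A0}: 2/3; {A1}: 2/3; pair: 4/6 = 2/3 -> tie, smaller
        # subset wins, then lexicographic: A0
        assert res.subset == ("A0",)
        assert res.objective_value == pytest.approx(2 / 3)

    def test_singleton_mean_correctness_equals_accuracy(self):
        ds = make_single_algo_dataset(
            [2.0, 0.0, 2.0, None], ["D", "D", "N", "N"]
        )
        cm = component_calls(ds, {"ALG": 1.0})
        res = select_combination(
            cm, objective="mean_component_correctness", max_subset_size=1
        )
        # calls: D, N, D on 3 available; correct: 1, 0, 0 -> 1/3
        assert res.objective_value == pytest.approx(1 / 3)

    def test_max_subset_size_respected(self):
        rng = np.random.default_rng(3)
        y = np.array([1] * 10 + [0] * 10)
        mat = rng.normal(y[:, None] * 1.0, 1.0, size=(20, 5)).tolist()
        ds = make_multi_algo_dataset(mat, ["D" if v else "N" for v in y])
        cm = component_calls(ds, {f"A{j}": 0.5 for j in range(5)})
        res = select_combination(cm, max_subset_size=2)
        assert len(res.subset) <= 2
        assert res.n_subsets_evaluated == 5 + 10  # C(5,1)+C(5,2)


class TestPublishedModel:
    def test_five_components(self):
        model = published_model()
        assert len(model.components) == 5
        assert model.algorithm_names == [
            "LRT", "MutationAssessor", "PROVEAN", "VEST3", "CADD"
        ]

    def test_component_parameters(self):
        by = {c.algorithm: c for c in published_model().components}
        assert by["VEST3"].threshold == 0.4534
        assert by["VEST3"].direction is Direction.GREATER
        assert by["LRT"].threshold == 0.0025
        assert by["LRT"].direction is Direction.LESS
        assert by["MutationAssessor"].threshold == 2.0566
        assert by["PROVEAN"].threshold == -3.286
        assert by["PROVEAN"].direction is Direction.LESS
        assert by["CADD"].threshold == 19.19
        assert published_model().call_cutoff == 0.5

    def test_yaml_round_trip(self, tmp_path):
        model = published_model()
        path = tmp_path / "model.yaml"
        model.save(path, provenance={"seed": 1})
        assert ConsensusModel.load(path) == model

    def test_duplicate_components_rejected(self):
        from admeopt.selection import ModelComponent

        with pytest.raises(ValidationError):
            ConsensusModel(
                components=[
                    ModelComponent("CADD", 1.0, Direction.GREATER),
                    ModelComponent("CADD", 2.0, Direction.GREATER),
                ]
            )


class TestCrossValidate:
    def _panel(self, aucs, seed, n=400):
        algos = [
            SyntheticAlgorithm(
                name=f"A{j}",
                direction=Direction.GREATER,
                nominal_range=(0.0, 1.0),
                target_auc=a,
            )
            for j, a in enumerate(aucs)
        ]
        cfg = SyntheticConfig(
            n_variants=n,
            bin_weights=(0.3, 0.2, 0.2, 0.3),
            algorithms=algos,
            latent_correlation=0.0,
            seed=seed,
        )
        return simulate_dataset(cfg)[0]

    def test_bit_reproducible(self):
        ds = self._panel([0.85, 0.7, 0.6], seed=5, n=150)
        r1 = cross_validate(ds, k=5, seed=5)
        r2 = cross_validate(ds, k=5, seed=5)
        assert r1.model == r2.model
        assert r1.mean_thresholds == r2.mean_thresholds
        assert [f.validation_metrics for f in r1.folds] == [
            f.validation_metrics for f in r2.folds
        ]

    def test_noise_free_separator_fold_average_equals_global_optimum(self):
        """With two point masses (score 0 neutral, 1 deleterious) every
        fold's midpoint optimum is 0.5, so the fold average equals the
        single-run optimum."""
        from admeopt import optimize_threshold

        ds = make_single_algo_dataset(
            [1.0] * 20 + [0.0] * 20, ["D"] * 20 + ["N"] * 20
        )
        res = cross_validate(ds, k=5, seed=1)
        assert res.mean_thresholds["ALG"] == 0.5
        assert optimize_threshold(ds, "ALG").optimal_threshold == 0.5

    def test_top_algorithms_dominate_selection(self):
        """With component AUCs (0.9, 0.85, 0.8, 0.6, 0.55) and independent
        errors, the aggregated subset contains the three strongest
        algorithms in most seeded replicates."""
        hits = 0
        for rep in range(10):
            ds = self._panel([0.9, 0.85, 0.8, 0.6, 0.55], seed=300 + rep)
            res = cross_validate(ds, k=5, seed=300 + rep)
            if {"A0", "A1", "A2"} <= set(res.modal_subset):
                hits += 1
        assert hits >= 8

    def test_validation_tracks_training_on_well_specified_data(self):
        """Held-out sensitivity/specificity stay within 3 fold-SDs of the
        training values when the generative model matches the fitted one."""
        for rep in range(10):
            ds = self._panel([0.85, 0.8, 0.75], seed=400 + rep, n=300)
            res = cross_validate(ds, k=5, seed=400 + rep)
            for metric in ("sensitivity", "specificity"):
                t_mean, t_sd = res.train_summary[metric]
                v_mean, v_sd = res.validation_summary[metric]
                sd = max(t_sd, v_sd, 0.02)
                assert abs(v_mean - t_mean) <= 3 * sd

    def test_fold_union_is_dataset(self):
        ds = self._panel([0.8, 0.7], seed=6, n=100)
        res = cross_validate(ds, k=5, seed=6)
        seen = []
        fa = stratified_kfold(ds, k=5, seed=6)
        for f in range(5):
            seen.extend(fa.fold_ids(f))
        assert sorted(seen) == sorted(r.variant_id for r in ds.records)
        assert res.k == 5
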