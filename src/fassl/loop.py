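"""The active semi-supervised learning loop and its experiment harness.

Per repetition: split the dataset, min-max scale on the learning set,
cluster the candidate pool once, prepare the strategy's structures once,
then iterate select -> annotate -> retrain -> test.  Iteration 1 always
annotates the cluster roots (cold start); from iteration 2 on, the chosen
query strategy proposes batches of ``labeled_budget = budget_mult * nc``
candidates, and every iteration additionally draws
``round(unlabeled_fraction * labeled_budget)`` fresh rows from the
unlabeled reservoir into the semi-supervised training set.  Accuracy is
measured on the held-out test set after every retrain.  Repetitions differ
only by their derived seeds; aggregates are mean +/- sd per iteration.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from . import clustering
from .data import AnnotationOracle, ConfigurationError, FeatureTable, TrainingState, split_dataset
from .strategies import STRATEGIES, initial_selection, make_strategy
from .yatsi import make_classifier

logger = logging.getLogger(__name__)

CLASSIFIER_TOKENS = ("svm", "rf", "knn", "yatsi-svm", "yatsi-rf", "yatsi-knn")


@dataclass
class RunConfig:
    """Fully resolved configuration of one experiment."""

    strategy: str = "rdbs"
    classifier: str = "yatsi-knn"
    k_multiplier: int = 2                 # k = k_multiplier * nc clusters
    labeled_budget_multiplier: int = 2    # labeled batch = mult * nc per iteration
    unlabeled_fraction: float = 0.5       # unlabeled batch = round(frac * labeled batch)
    max_iterations: int = 10
    repetitions: int = 10
    seed: int = 0
    split_seed: int | None = None         # share across strategies for fair comparison
    test_fraction: float = 0.2
    pool_fraction: float = 0.5
    scale: bool = True
    stratify: bool = False
    n_neighbors: int = 5                  # boundary-detection neighbor count
    yatsi_f: float = 1.0
    yatsi_k: int = 10
    balanced_accuracy: bool = False
    target_accuracy: float | None = None  # optional "specialist satisfied" stop
    rdbs_fallback: bool = True            # farthest-sample fallback on agreeing lists

    def validate(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")
        if self.classifier not in CLASSIFIER_TOKENS:
            raise ConfigurationError(f"unknown classifier {self.classifier!r}")
        if self.k_multiplier < 1 or self.labeled_budget_multiplier < 1:
            raise ConfigurationError("multipliers must be >= 1")
        if not (0.0 <= self.unlabeled_fraction <= 1.0):
            raise ConfigurationError("unlabeled_fraction must lie in [0, 1]")
        if self.repetitions < 1 or self.max_iterations < 1:
            raise ConfigurationError("repetitions and max_iterations must be >= 1")


@dataclass
class IterationRecord:
    """Per-iteration trace: budgets spent, accuracy, phase timings (ms)."""

    iteration: int
    n_labeled_cumulative: int
    n_unlabeled_cumulative: int
    test_accuracy: float
    n_selection_predictions: int = 0
    selection_ms: float = 0.0
    train_ms: float = 0.0
    test_ms: float = 0.0


@dataclass
class RepetitionResult:
    repetition: int
    seed: int
    split_seed: int
    records: list[IterationRecord] = field(default_factory=list)
    annotation_count: int = 0
    n_labeled_final: int = 0
    test_idx: np.ndarray | None = None


@dataclass
class RunResult:
    config: RunConfig
    repetitions: list[RepetitionResult] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return aggregate_runs(self)


def compute_accuracy(predicted, truth, balanced: bool = False) -> float:
    """Fraction of exact matches; ``balanced`` averages per-class recalls."""
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.shape != truth.shape or len(truth) == 0:
        raise ValueError("predicted and truth must be equal-length, non-empty")
    if not balanced:
        return float(np.mean(predicted == truth))
    classes = list(dict.fromkeys(truth.tolist()))
    recalls = [float(np.mean(predicted[truth == cls] == cls)) for cls in classes]
    return float(np.mean(recalls))


def _run_repetition(table: FeatureTable, config: RunConfig, repetition: int) -> RepetitionResult:
    rep_seed = config.seed + repetition
    split_base = config.split_seed if config.split_seed is not None else config.seed
    split_seed = split_base + repetition
    split = split_dataset(table, config.test_fraction, config.pool_fraction,
                          seed=split_seed, stratify=config.stratify)

    X = table.features
    if config.scale:
        scaler = MinMaxScaler().fit(X[split.learning_idx])
        Xs = scaler.transform(X)
    else:
        Xs = X
    pool = split.labeled_pool_idx            # global indices of Z2'
    pool_X = Xs[pool]
    nc = table.nc
    k = min(config.k_multiplier * nc, len(pool))
    budget_labeled = config.labeled_budget_multiplier * nc
    budget_unlabeled = int(math.floor(config.unlabeled_fraction * budget_labeled + 0.5))

    ss = np.random.SeedSequence(rep_seed)
    strat_rng, unlab_rng = (np.random.default_rng(c) for c in ss.spawn(2))

    # reduce & organize ONCE per repetition
    model = clustering.cluster_pool(pool_X, k, seed=rep_seed)
    clustering.find_roots(model, pool_X)
    strategy = make_strategy(config.strategy)
    if hasattr(strategy, "fallback"):
        strategy.fallback = config.rdbs_fallback
    strategy.prepare(model, pool_X, config.n_neighbors, strat_rng)

    oracle = AnnotationOracle(table, candidate_idx=pool)
    state = TrainingState()
    unlabeled_remaining = list(split.unlabeled_pool_idx)
    unlab_order = unlab_rng.permutation(len(unlabeled_remaining))
    unlabeled_queue = [unlabeled_remaining[i] for i in unlab_order]

    classifier = None
    root_labels: dict[int, object] = {}
    result = RepetitionResult(repetition=repetition, seed=rep_seed, split_seed=split_seed,
                              test_idx=split.test_idx)
    test_truth = table.labels[split.test_idx]
    test_X = Xs[split.test_idx]

    for it in range(1, config.max_iterations + 1):
        state.iteration = it
        t0 = time.perf_counter()
        n_pred = 0
        if it == 1 and strategy.cold_start_roots:
            batch = initial_selection(model)
        elif it == 1:
            batch = strategy.select(budget_labeled, None)
        else:
            def predict_one(local_idx: int, _clf=classifier):
                nonlocal n_pred
                n_pred += 1
                return _clf.predict(pool_X[local_idx][None, :])[0]

            batch = strategy.select(budget_labeled, predict_one if strategy.needs_classifier else None)
        sel_ms = (time.perf_counter() - t0) * 1e3

        global_sel = [int(pool[i]) for i in batch.chosen_idx]
        annotations = oracle.annotate(global_sel)
        if it == 1 and strategy.cold_start_roots:
            root_labels = {cid: annotations[int(pool[r])] for cid, r in model.roots.items()}
            strategy.set_root_labels(root_labels)
        state.add_labeled(annotations)
        strategy.mark_consumed(batch.chosen_idx)

        n_draw = min(budget_unlabeled, len(unlabeled_queue))
        if n_draw:
            state.add_unlabeled(unlabeled_queue[:n_draw])
            unlabeled_queue = unlabeled_queue[n_draw:]

        t1 = time.perf_counter()
        classifier = make_classifier(config.classifier, seed=rep_seed,
                                     F=config.yatsi_f, K=config.yatsi_k,
                                     class_order=table.class_names)
        unlabeled_X = Xs[state.unlabeled_idx] if state.unlabeled_idx else None
        classifier.fit(Xs[state.labeled_idx], np.asarray(state.labeled_labels, dtype=object),
                       unlabeled_X=unlabeled_X)
        train_ms = (time.perf_counter() - t1) * 1e3

        t2 = time.perf_counter()
        acc = compute_accuracy(classifier.predict(test_X), test_truth,
                               balanced=config.balanced_accuracy)
        test_ms = (time.perf_counter() - t2) * 1e3

        result.records.append(IterationRecord(
            iteration=it, n_labeled_cumulative=state.n_labeled,
            n_unlabeled_cumulative=state.n_unlabeled, test_accuracy=acc,
            n_selection_predictions=n_pred, selection_ms=sel_ms,
            train_ms=train_ms, test_ms=test_ms))

        if config.target_accuracy is not None and acc >= config.target_accuracy:
            logger.info("target accuracy reached at iteration %d", it)
            break
        if it > 1 and (batch.exhausted or not batch.chosen_idx):
            logger.info("strategy exhausted at iteration %d", it)
            break

    result.annotation_count = oracle.annotation_count
    result.n_labeled_final = state.n_labeled
    return result


def run_experiment(table: FeatureTable, config: RunConfig) -> RunResult:
    """Run the full experiment: ``repetitions`` independent repetitions on
    freshly drawn splits, each seeded as ``seed + repetition`` (splits from
    ``split_seed + repetition`` when a shared split seed is given, so that
    different strategies see identical splits)."""
    config.validate()
    result = RunResult(config=config)
    for r in range(config.repetitions):
        try:
            result.repetitions.append(_run_repetition(table, config, r))
        except Exception:
            logger.exception("repetition %d aborted", r)
    if not result.repetitions:
        raise RuntimeError("every repetition failed")
    return result


def aggregate_runs(result: RunResult, ddof: int = 1) -> pd.DataFrame:
    """Per-iteration learning-curve table aggregated across repetitions.

    Iterations some repetitions never reached (early exhaustion) aggregate
    over the surviving repetitions only; ``support`` reports how many.
    """
    rows = [asdict(rec) | {"repetition": rep.repetition}
            for rep in result.repetitions for rec in rep.records]
    df = pd.DataFrame(rows)
    grouped = df.groupby("iteration")
    out = pd.DataFrame({
        "mean_acc": grouped["test_accuracy"].mean(),
        "std_acc": grouped["test_accuracy"].std(ddof=ddof).fillna(0.0),
        "mean_n_labeled": grouped["n_labeled_cumulative"].mean(),
        "mean_n_unlabeled": grouped["n_unlabeled_cumulative"].mean(),
        "mean_selection_ms": grouped["selection_ms"].mean(),
        "mean_train_ms": grouped["train_ms"].mean(),
        "mean_test_ms": grouped["test_ms"].mean(),
        "support": grouped.size(),
    }).reset_index()
    return out


def run_comparison(table: FeatureTable, strategies: list[str], base_config: RunConfig) -> dict[str, RunResult]:
    """Run several strategies on identical per-repetition splits."""
    shared = base_config.split_seed if base_config.split_seed is not None else base_config.seed
    out: dict[str, RunResult] = {}
    for strat in strategies:
        cfg = RunConfig(**{**asdict(base_config), "strategy": strat, "split_seed": shared})
        out[strat] = run_experiment(table, cfg)
    return out
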