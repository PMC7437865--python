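"""Dataset containers, the learning/test split protocol, and the annotation oracle.

The learning protocol partitions a dataset ``Z`` into a held-out test set
``Z3`` and a learning set ``Z2``, and subdivides ``Z2`` into an annotation
candidate pool ``Z2'`` (samples the active learner may ask the oracle to
label) and an unlabeled reservoir ``Z2''`` (samples fed, without labels, to
the semi-supervised classifier).  Ground-truth labels stay hidden from the
learner: strategies and classifiers only ever see labels that passed through
the oracle, plus the test labels used by the final evaluator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """An option value outside its documented domain."""


class ContractViolationError(RuntimeError):
    """A caller broke an interface precondition (e.g. querying the oracle
    for a sample outside the candidate pool)."""


@dataclass
class FeatureTable:
    """n x d numeric feature matrix with per-sample class labels.

    Parameters
    ----------
    sample_ids : sequence of hashable
        Unique, opaque sample identifiers (row order defines index order).
    features : (n, d) array of finite floats
    labels : length-n sequence of class tokens
        Ground truth; reachable only through :class:`AnnotationOracle` and
        the evaluator.
    class_names : sequence of class tokens, optional
        Ordered class universe.  Defaults to first-appearance order of
        ``labels``.
    """

    sample_ids: list
    features: np.ndarray
    labels: np.ndarray
    class_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ConfigurationError("features must be a 2-D matrix")
        self.labels = np.asarray(self.labels, dtype=object)
        self.sample_ids = list(self.sample_ids)
        n, d = self.features.shape
        if n < 1 or d < 1:
            raise ConfigurationError("need at least one sample and one feature")
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ConfigurationError("sample_ids/labels length must match features")
        if len(set(self.sample_ids)) != n:
            raise ConfigurationError("sample_ids must be unique")
        if not np.all(np.isfinite(self.features)):
            raise ConfigurationError("features contain non-finite values")
        if not self.class_names:
            seen: dict = {}
            for lab in self.labels:
                seen.setdefault(lab, None)
            self.class_names = list(seen)
        missing = set(self.labels) - set(self.class_names)
        if missing:
            raise ConfigurationError(f"labels {missing!r} not in class_names")
        if len(self.class_names) < 2:
            raise ConfigurationError("need at least two classes")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    @property
    def nc(self) -> int:
        return len(self.class_names)


@dataclass(frozen=True)
class DatasetSplit:
    """Index partition: test set Z3, candidate pool Z2' and unlabeled pool Z2''."""

    learning_idx: np.ndarray      # Z2 = Z2' u Z2''
    test_idx: np.ndarray          # Z3
    labeled_pool_idx: np.ndarray  # Z2'
    unlabeled_pool_idx: np.ndarray  # Z2''
    seed: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_dataset(
    table: FeatureTable,
    test_fraction: float = 0.2,
    pool_fraction: float = 0.5,
    seed: int = 0,
    stratify: bool = False,
) -> DatasetSplit:
    """Randomly partition a table into Z3 / Z2' / Z2''.

    ``|Z3| = round(test_fraction * n)`` (half-up) and
    ``|Z2''| = floor(|Z2| * pool_fraction)``.  Sampling is uniform without
    replacement and fully determined by ``seed``.  ``stratify=True`` draws
    the test set per class (off by default; the protocol is unstratified).
    """
    for name, frac in (("test_fraction", test_fraction), ("pool_fraction", pool_fraction)):
        if not (0.0 < frac < 1.0):
            raise ConfigurationError(f"{name} must lie in (0, 1), got {frac}")
    n = table.n
    if n < 5:
        raise ConfigurationError("need at least 5 samples to split")
    rng = np.random.default_rng(seed)
    if stratify:
        test_parts = []
        labels = table.labels
        for cls in table.class_names:
            cls_idx = np.flatnonzero(labels == cls)
            n_cls_test = _round_half_up(test_fraction * len(cls_idx))
            test_parts.append(rng.permutation(cls_idx)[:n_cls_test])
        test = np.sort(np.concatenate(test_parts))
        learn = rng.permutation(np.setdiff1d(np.arange(n), test))
    else:
        perm = rng.permutation(n)
        n_test = _round_half_up(test_fraction * n)
        test = np.sort(perm[:n_test])
        learn = perm[n_test:]
    n_unlabeled = int(math.floor(len(learn) * pool_fraction))
    unlabeled_pool = np.sort(learn[:n_unlabeled])
    labeled_pool = np.sort(learn[n_unlabeled:])
    learn = np.sort(learn)

    pool_classes = set(table.labels[learn])
    absent = set(table.class_names) - pool_classes
    if absent:
        logger.warning("classes %s absent from the learning set after split", sorted(map(str, absent)))
    return DatasetSplit(
        learning_idx=learn,
        test_idx=test,
        labeled_pool_idx=labeled_pool,
        unlabeled_pool_idx=unlabeled_pool,
        seed=seed,
    )


@dataclass
class TrainingState:
    """Cumulative training sets of one repetition (all indices global)."""

    labeled_idx: list = field(default_factory=list)       # Z1
    labeled_labels: list = field(default_factory=list)    # oracle labels, aligned
    unlabeled_idx: list = field(default_factory=list)     # drawn from Z2''
    consumed_candidates: set = field(default_factory=set)
    iteration: int = 0

    def add_labeled(self, index_to_label: Mapping[int, object]) -> None:
        for idx, lab in index_to_label.items():
            if idx in self.consumed_candidates:
                continue
            self.labeled_idx.append(idx)
            self.labeled_labels.append(lab)
            self.consumed_candidates.add(idx)

    def add_unlabeled(self, indices: Iterable[int]) -> None:
        self.unlabeled_idx.extend(int(i) for i in indices)

    @property
    def n_labeled(self) -> int:
        return len(self.labeled_idx)

    @property
    def n_unlabeled(self) -> int:
        return len(self.unlabeled_idx)


class AnnotationOracle:
    """Annotation source; ``simulated`` mode answers from ground truth.

    The oracle is the only component allowed to look at the hidden labels of
    learning samples.  ``annotation_count`` tracks specialist effort.
    ``interactive`` mode reads one label per queried index from a text
    stream (a stub for a human-in-the-loop front end).
    """

    def __init__(self, table: FeatureTable, candidate_idx: Iterable[int] | None = None,
                 mode: str = "simulated", stream=None):
        if mode not in ("simulated", "interactive"):
            raise ConfigurationError(f"unknown oracle mode {mode!r}")
        self.mode = mode
        self._truth = table.labels if mode == "simulated" else None
        self._stream = stream
        self._allowed = None if candidate_idx is None else set(int(i) for i in candidate_idx)
        self.annotation_count = 0
        self.queried: list[int] = []

    def annotate(self, indices: Sequence[int]) -> dict[int, object]:
        """Return the (confirmed/corrected) label for each queried index."""
        out: dict[int, object] = {}
        seen = set(self.queried)
        for idx in indices:
            idx = int(idx)
            if self._allowed is not None and idx not in self._allowed:
                raise ContractViolationError(f"index {idx} outside the candidate pool")
            if idx in seen:
                logger.warning("index %d queried more than once (strategy bug?)", idx)
            if self.mode == "simulated":
                out[idx] = self._truth[idx]
            else:
                out[idx] = self._stream.readline().strip()
            self.queried.append(idx)
            self.annotation_count += 1
        return out


def oracle_annotate(oracle: AnnotationOracle, indices: Sequence[int]) -> dict[int, object]:
    """Functional alias for :meth:`AnnotationOracle.annotate`."""
    return oracle.annotate(indices)
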