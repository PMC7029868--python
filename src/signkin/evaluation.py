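"""User-independent nested cross-validation, majority voting and metrics.

The protocol guards against subject-identity leakage: every subject
appears in exactly one of train/validation/test at any point.  An outer
loop rotates a held-out test group of subjects (each subject is tested
exactly once across loops); for each outer loop an inner k-fold rotates
the remaining subjects between training and validation.  The K
fold-trained models of one outer loop are ensembled on the test subjects
by majority vote (ties broken by the highest mean softmax probability
among the tied labels).  Feature standardisation statistics are fitted
per inner fold on that fold's (augmented) training samples only, and
augmentation is applied to training samples only.

``holdout_eval`` implements the contrasting naive protocol — repeated
stratified 80/20 splits of the pooled samples that ignore subject
identity — used to demonstrate how much accuracy such evaluation inflates
when subjects carry identifiable signatures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedShuffleSplit

from .augmentation import AugmentationConfig, augment
from .containers import FeatureMatrix, SubjectDataset, stack_features
from .classifiers import TrainConfig, NeuralSequenceClassifier, make_classifier
from .errors import ConfigError, LeakageError, SignkinError
from .preprocessing import fit_group_stats, standardize

ModelSpec = Union[str, Callable[[int], object]]


# ---------------------------------------------------------------------------
# split plan


@dataclass
class SplitPlan:
    """Nested assignment of subjects to outer test groups and inner folds."""

    outer_loops: list[dict]
    seed: int

    def validate(self) -> None:
        all_tested: list[str] = []
        for loop in self.outer_loops:
            test = set(loop["test_subjects"])
            rest: set[str] = set()
            val_union: list[str] = []
            for fold in loop["inner_folds"]:
                train, val = set(fold["train"]), set(fold["val"])
                if train & val:
                    raise LeakageError(f"train/val overlap: {sorted(train & val)}")
                if (train | val) & test:
                    raise LeakageError(
                        f"test subjects reappear in inner folds: "
                        f"{sorted((train | val) & test)}"
                    )
                rest |= train | val
                val_union.extend(fold["val"])
            if sorted(val_union) != sorted(rest):
                raise SignkinError(
                    "inner validation sets must partition the non-test subjects"
                )
            all_tested.extend(loop["test_subjects"])
        if len(all_tested) != len(set(all_tested)):
            raise SignkinError("outer test groups overlap")

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "outer_loops": self.outer_loops}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        data = json.loads(text)
        plan = cls(outer_loops=data["outer_loops"], seed=data["seed"])
        plan.validate()
        return plan


def make_nested_splits(
    subject_ids: Sequence[str],
    test_group_size: int = 5,
    K: int = 4,
    seed: int = 0,
) -> SplitPlan:
    """Seeded random nested split plan.

    The subject count must be divisible by ``test_group_size`` and the
    remaining count by ``K``; each subject is tested in exactly one outer
    loop, and within a loop the K validation sets partition the non-test
    subjects.
    """
    subjects = [str(s) for s in subject_ids]
    n = len(subjects)
    if n == 0 or n % test_group_size != 0:
        valid = [d for d in range(1, n + 1) if n % d == 0]
        raise ConfigError(
            f"{n} subjects not divisible by test_group_size={test_group_size}; "
            f"valid sizes: {valid}"
        )
    rest = n - test_group_size
    if rest % K != 0:
        valid = [d for d in range(1, rest + 1) if rest % d == 0]
        raise ConfigError(
            f"{rest} non-test subjects not divisible by K={K}; valid K: {valid}"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(subjects))
    n_outer = n // test_group_size
    outer_loops = []
    for i in range(n_outer):
        test = order[i * test_group_size : (i + 1) * test_group_size]
        rest_subjects = [s for s in order if s not in test]
        rotated = list(rng.permutation(rest_subjects))
        val_size = rest // K
        folds = []
        for k in range(K):
            val = rotated[k * val_size : (k + 1) * val_size]
            train = [s for s in rotated if s not in val]
            folds.append({"train": train, "val": val})
        outer_loops.append({"test_subjects": test, "inner_folds": folds})
    plan = SplitPlan(outer_loops=outer_loops, seed=seed)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# majority vote


def majority_vote(
    fold_predictions: Sequence[Sequence],
    fold_probabilities: Optional[Sequence[np.ndarray]] = None,
    classes: Optional[Sequence] = None,
) -> np.ndarray:
    """Per-sample majority label across the K fold models.

    Ties are broken by the highest mean softmax probability among the tied
    labels (requires ``fold_probabilities`` + ``classes``); without
    probabilities, ties fall back to the first tied label in sorted order.
    """
    lengths = {len(p) for p in fold_predictions}
    if len(lengths) != 1:
        raise SignkinError("fold_predictions must be K equal-length lists")
    preds = np.asarray(fold_predictions)
    K, n = preds.shape
    if fold_probabilities is not None:
        probs = np.stack(fold_probabilities)  # (K, n, C)
        if probs.shape[:2] != (K, n):
            raise SignkinError("fold_probabilities shape mismatch")
        mean_probs = probs.mean(axis=0)
        classes = np.asarray(classes)
    final = []
    for j in range(n):
        labels, counts = np.unique(preds[:, j], return_counts=True)
        tied = labels[counts == counts.max()]
        if len(tied) == 1 or fold_probabilities is None:
            final.append(sorted(tied)[0] if len(tied) > 1 else tied[0])
        else:
            tied_idx = [int(np.where(classes == lab)[0][0]) for lab in tied]
            final.append(tied[int(np.argmax(mean_probs[j, tied_idx]))])
    return np.asarray(final)


def confusion_matrix(
    true_labels: Sequence,
    predicted_labels: Sequence,
    labels: Optional[Sequence] = None,
    normalize: Optional[str] = "row",
) -> np.ndarray:
    """Row-indexed-by-true-label confusion matrix, optionally row-normalised."""
    if len(true_labels) != len(predicted_labels):
        raise SignkinError("label sequences must have equal length")
    if labels is None:
        labels = sorted(set(true_labels) | set(predicted_labels))
    matrix = _sk_confusion(true_labels, predicted_labels, labels=list(labels))
    if normalize == "row":
        sums = matrix.sum(axis=1, keepdims=True)
        return np.divide(
            matrix, sums, out=np.zeros(matrix.shape, dtype=float),
            where=sums > 0,
        )
    if normalize is None:
        return matrix
    raise ConfigError(f"unknown normalize mode {normalize!r}")


# ---------------------------------------------------------------------------
# report


@dataclass
class EvaluationReport:
    """Nested-CV outcome: per-loop test accuracies and pooled confusion."""

    model: str
    loop_accuracies: list[float]
    val_accuracies: list[float]
    labels: tuple[str, ...]
    confusion: np.ndarray
    n_test_samples: int
    plan_seed: int
    per_loop: list[dict] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.loop_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.loop_accuracies, ddof=1)) \
            if len(self.loop_accuracies) > 1 else 0.0

    @property
    def mean_val_accuracy(self) -> float:
        return float(np.mean(self.val_accuracies)) if self.val_accuracies else np.nan

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "loop_accuracies": self.loop_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "val_accuracies": self.val_accuracies,
            "mean_val_accuracy": self.mean_val_accuracy,
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
            "n_test_samples": self.n_test_samples,
            "plan_seed": self.plan_seed,
        }

    def misclassification_flows(self):
        """Long-format (true, predicted, rate) rows for off-diagonal flows."""
        rows = []
        for i, true in enumerate(self.labels):
            for j, pred in enumerate(self.labels):
                if i != j and self.confusion[i, j] > 0:
                    rows.append((true, pred, float(self.confusion[i, j])))
        return rows


# ---------------------------------------------------------------------------
# nested cross-validation harness


def _collect(cohort: Sequence[SubjectDataset], subjects: Sequence[str], role: str):
    wanted = set(subjects)
    matrices: list[FeatureMatrix] = []
    labels: list[str] = []
    subject_tags: list[str] = []
    for ds in cohort:
        if ds.subject_id in wanted:
            for matrix, label in ds.samples:
                matrices.append(matrix.with_role(role))
                labels.append(label)
                subject_tags.append(ds.subject_id)
    return matrices, labels, subject_tags


def _make_model(model: ModelSpec, seed: int, train_config: Optional[TrainConfig],
                **overrides):
    if callable(model):
        return model(seed)
    kwargs = dict(overrides)
    if train_config is not None:
        kwargs.update(
            learning_rate=train_config.learning_rate,
            decay=train_config.decay,
            decay_every=train_config.decay_every,
            batch_size=train_config.batch_size,
            keep_prob=train_config.keep_prob,
            max_epochs=train_config.max_epochs,
            patience=train_config.patience,
        )
    try:
        return make_classifier(model, random_state=seed, **kwargs)
    except TypeError:
        # baselines take no training-regime parameters
        return make_classifier(model, random_state=seed)


def run_nested_cv(
    cohort: Sequence[SubjectDataset],
    model: ModelSpec,
    train_config: Optional[TrainConfig] = None,
    augmentation_config: Optional[AugmentationConfig] = None,
    test_group_size: int = 5,
    K: int = 4,
    seed: int = 0,
    plan: Optional[SplitPlan] = None,
    **model_overrides,
) -> EvaluationReport:
    """Run the full user-independent nested k-fold protocol.

    Per outer loop: K models are trained (fresh seeded initialisation
    each) on the inner folds, with group statistics fitted on each fold's
    training samples (after augmentation, which touches training samples
    only), and ensembled by majority vote on the held-out test subjects.
    """
    subjects = [ds.subject_id for ds in cohort]
    if len(set(subjects)) != len(subjects):
        raise SignkinError("duplicate subject datasets in cohort")
    if plan is None:
        plan = make_nested_splits(subjects, test_group_size, K, seed)
    label_set = tuple(cohort[0].label_set) if cohort[0].label_set else tuple(
        sorted({lab for ds in cohort for lab in ds.labels()})
    )

    loop_accuracies: list[float] = []
    val_accuracies: list[float] = []
    per_loop: list[dict] = []
    all_true: list[str] = []
    all_pred: list[str] = []

    for oi, loop in enumerate(plan.outer_loops):
        test_subjects = loop["test_subjects"]
        test_mats, test_labels, test_tags = _collect(cohort, test_subjects, "test")
        fold_preds, fold_probs = [], []
        classes_ref = None
        for ki, fold in enumerate(loop["inner_folds"]):
            train_subjects, val_subjects = fold["train"], fold["val"]
            leak = (set(train_subjects) | set(val_subjects)) & set(test_subjects)
            if leak:
                raise LeakageError(
                    f"outer loop {oi}: test subjects {sorted(leak)} leak into "
                    f"inner fold {ki}"
                )
            train_mats, train_labels, train_tags = _collect(
                cohort, train_subjects, "train"
            )
            val_mats, val_labels, _ = _collect(cohort, val_subjects, "val")
            if not train_mats or not val_mats or not test_mats:
                raise ConfigError("a fold has an empty train/val/test set")

            fold_seed = (seed * 100_003 + oi * 103 + ki * 7) % (2**31 - 1)
            if augmentation_config is not None:
                aug_rng = np.random.default_rng(fold_seed + 1)
                augmented = []
                for matrix in train_mats:
                    augmented.extend(
                        augment(matrix, augmentation_config, aug_rng)
                    )
                n_copies = augmentation_config.repeats
                train_labels = [
                    lab for lab in train_labels for _ in range(n_copies + 1)
                ]
                merged = []
                for orig, start in zip(train_mats, range(0, len(augmented), n_copies)):
                    merged.append(orig)
                    merged.extend(augmented[start : start + n_copies])
                train_mats = merged

            stats = fit_group_stats(train_mats)
            X_train = stack_features([standardize(m, stats) for m in train_mats])
            X_val = stack_features([standardize(m, stats) for m in val_mats])
            X_test = stack_features([standardize(m, stats) for m in test_mats])

            estimator = _make_model(model, fold_seed, train_config,
                                    **model_overrides)
            if isinstance(estimator, NeuralSequenceClassifier):
                estimator.fit(
                    X_train, np.asarray(train_labels),
                    X_val=X_val, y_val=np.asarray(val_labels),
                    train_subjects=train_subjects, val_subjects=val_subjects,
                )
                val_accuracies.append(float(max(estimator.history_["val_acc"])))
            else:
                estimator.fit(X_train, np.asarray(train_labels),
                              train_subjects=train_subjects,
                              val_subjects=val_subjects)
                val_acc = float(
                    np.mean(estimator.predict(X_val) == np.asarray(val_labels))
                )
                val_accuracies.append(val_acc)
            fold_preds.append(estimator.predict(X_test))
            probs = estimator.predict_proba(X_test)
            if classes_ref is None:
                classes_ref = np.asarray(estimator.classes_)
            fold_probs.append(probs)

        final = majority_vote(fold_preds, fold_probs, classes=classes_ref)
        acc = float(np.mean(final == np.asarray(test_labels)))
        loop_accuracies.append(acc)
        all_true.extend(test_labels)
        all_pred.extend(final.tolist())
        per_loop.append(
            {"test_subjects": list(test_subjects), "accuracy": acc,
             "n_test": len(test_labels)}
        )

    matrix = confusion_matrix(all_true, all_pred, labels=label_set)
    return EvaluationReport(
        model=model if isinstance(model, str) else getattr(
            model, "__name__", "custom"),
        loop_accuracies=loop_accuracies,
        val_accuracies=val_accuracies,
        labels=label_set,
        confusion=matrix,
        n_test_samples=len(all_true),
        plan_seed=plan.seed,
        per_loop=per_loop,
    )


# ---------------------------------------------------------------------------
# holdout (leakage demonstration)


def holdout_eval(
    cohort: Sequence[SubjectDataset],
    model: ModelSpec,
    train_fraction: float = 0.8,
    repeats: int = 10,
    seed: int = 0,
    train_config: Optional[TrainConfig] = None,
    **model_overrides,
) -> list[float]:
    """Repeated stratified holdout ignoring subject identity.

    Pools all samples across subjects, draws ``repeats`` stratified
    train/test splits, and returns the per-split test accuracies.  With
    subject-identifiable data this inflates accuracy relative to
    :func:`run_nested_cv` — which is the point of the demonstration.
    """
    matrices: list[FeatureMatrix] = []
    labels: list[str] = []
    for ds in cohort:
        for matrix, label in ds.samples:
            matrices.append(matrix)
            labels.append(label)
    y = np.asarray(labels)
    counts = {lab: int(np.sum(y == lab)) for lab in set(labels)}
    thin = [lab for lab, c in counts.items() if c < 2]
    if thin:
        raise ConfigError(f"stratification impossible; classes with < 2 "
                          f"samples: {sorted(thin)}")
    splitter = StratifiedShuffleSplit(
        n_splits=repeats, train_size=train_fraction, random_state=seed
    )
    accuracies = []
    for rep, (train_idx, test_idx) in enumerate(splitter.split(y, y)):
        train_mats = [matrices[i] for i in train_idx]
        stats = fit_group_stats(train_mats)
        X_train = stack_features([standardize(m, stats) for m in train_mats])
        X_test = stack_features(
            [standardize(matrices[i], stats) for i in test_idx]
        )
        y_train, y_test = y[train_idx], y[test_idx]
        estimator = _make_model(model, (seed * 911 + rep) % (2**31 - 1),
                                train_config, **model_overrides)
        if isinstance(estimator, NeuralSequenceClassifier):
            # carve a stratified slice of the training data for early stopping
            inner = StratifiedShuffleSplit(n_splits=1, train_size=0.85,
                                           random_state=seed + rep)
            (tr, va), = inner.split(y_train, y_train)
            estimator.fit(X_train[tr], y_train[tr],
                          X_val=X_train[va], y_val=y_train[va])
        else:
            estimator.fit(X_train, y_train)
        accuracies.append(float(np.mean(estimator.predict(X_test) == y_test)))
    return accuracies
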