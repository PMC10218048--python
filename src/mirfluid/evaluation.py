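"""Stratified cross-validation, rate tables and end-to-end orchestration.

The headline evaluation of the classifier is a stratified 10-fold
cross-validation in which, per fold, *everything* downstream of the raw
profiles — the pooled Gaussian used for imputation, the imputed training
rows, the synthetic Other class, and the per-class QDA components — is
recomputed from the training fold only. Held-out samples are imputed with
the training fold's pooled fit and then classified, so no information leaks
from validation to training. (A deliberately leaky variant, imputing once on
the full dataset before splitting, is available for comparison via
``impute_before_split=True``.)

Results aggregate into a :class:`RateTable`: per true fluid, the fractions
of samples called correctly, called as another body fluid, rejected into
Other, or gated as inconclusive.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FoldError, ValidationError
from .mvn import (
    DEFAULT_OTHER_INFLATION,
    DEFAULT_OTHER_RADIUS,
    DEFAULT_RIDGE,
    MVNParams,
    fit_mvn,
    generate_other,
    impute_all,
)
from .panel_io import DeltaCqProfile, MarkerPanel, read_profiles
from .qda import (
    DEFAULT_THRESHOLD,
    ClassificationResult,
    QDAModel,
    classify_profiles,
    fit_qda,
)

logger = logging.getLogger(__name__)

DEFAULT_K = 10
DEFAULT_SEED = 7


# ---------------------------------------------------------------------------
# fold assignment
# ---------------------------------------------------------------------------


def kfold_split(
    labels: Sequence[str], k: int = DEFAULT_K, seed: int | None = None
) -> np.ndarray:
    """Stratified fold assignment: per-class fold counts differ by ≤ 1.

    Within each class, samples are shuffled and dealt to folds round-robin;
    the dealing counter carries across classes so overall fold sizes also
    stay balanced. Deterministic given ``seed``.
    """
    labels = list(labels)
    n = len(labels)
    if k < 2:
        raise ValidationError("k must be at least 2")
    if k > n:
        raise ValidationError(f"k={k} exceeds sample count {n}")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    counter = 0
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(np.asarray(labels, dtype=object) == cls)
        if idx.size < k:
            warnings.warn(
                f"class {cls!r} has {idx.size} < k={k} members; "
                "stratification is best-effort",
                stacklevel=2,
            )
        rng.shuffle(idx)
        for i in idx:
            folds[i] = counter % k
            counter += 1
    return folds


# ---------------------------------------------------------------------------
# rate table
# ---------------------------------------------------------------------------


@dataclass
class RateTable:
    """Per-fluid classification summary in the standard three/four-way layout."""

    classes: tuple[str, ...]
    n: dict[str, int]
    correct: dict[str, float]
    other_bf: dict[str, float]
    other: dict[str, float]
    inconclusive: dict[str, float]

    @property
    def overall_accuracy(self) -> float:
        total = sum(self.n.values())
        return sum(self.n[c] * self.correct[c] for c in self.classes) / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fluid": list(self.classes),
                "n": [self.n[c] for c in self.classes],
                "correct": [self.correct[c] for c in self.classes],
                "other_bf": [self.other_bf[c] for c in self.classes],
                "other": [self.other[c] for c in self.classes],
                "inconclusive": [self.inconclusive[c] for c in self.classes],
            }
        )

    def to_csv_text(self) -> str:
        """Rate table as CSV text with fractions at 4 decimal places."""
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["fluid", "n", "correct", "other_bf", "other", "inconclusive"])
        for c in self.classes:
            writer.writerow(
                [
                    c,
                    self.n[c],
                    f"{self.correct[c]:.4f}",
                    f"{self.other_bf[c]:.4f}",
                    f"{self.other[c]:.4f}",
                    f"{self.inconclusive[c]:.4f}",
                ]
            )
        writer.writerow(["overall", sum(self.n.values()),
                        f"{self.overall_accuracy:.4f}", "", "", ""])
        return buf.getvalue()

    def write_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write(self.to_csv_text())


def build_rate_table(
    true_labels: Sequence[str],
    results: Sequence[ClassificationResult],
    panel: MarkerPanel,
) -> RateTable:
    """Tabulate per-fluid outcome fractions from classification results."""
    if len(true_labels) != len(results):
        raise ValidationError("labels and results must align")
    classes = tuple(c for c in panel.fluid_classes if c in set(true_labels))
    counts = {c: {"n": 0, "correct": 0, "other_bf": 0, "other": 0, "inconclusive": 0}
              for c in classes}
    for truth, res in zip(true_labels, results):
        row = counts[truth]
        row["n"] += 1
        if res.predicted == truth:
            row["correct"] += 1
        elif res.predicted == panel.other_label:
            row["other"] += 1
        elif res.predicted == panel.inconclusive_label:
            row["inconclusive"] += 1
        else:
            row["other_bf"] += 1
    return RateTable(
        classes=classes,
        n={c: counts[c]["n"] for c in classes},
        correct={c: counts[c]["correct"] / counts[c]["n"] for c in classes},
        other_bf={c: counts[c]["other_bf"] / counts[c]["n"] for c in classes},
        other={c: counts[c]["other"] / counts[c]["n"] for c in classes},
        inconclusive={c: counts[c]["inconclusive"] / counts[c]["n"] for c in classes},
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class FoldDiagnostics:
    """Per-fold parameters retained so leakage can be audited afterwards."""

    fold: int
    train_idx: np.ndarray
    pooled: MVNParams
    other_seed: int
    other_vectors: np.ndarray
    model: QDAModel


@dataclass
class CVResult:
    rate_table: RateTable
    true_labels: list[str]
    results: list[ClassificationResult]
    fold_of: np.ndarray
    folds: list[FoldDiagnostics] = field(repr=False, default_factory=list)

    def predictions_csv_text(self, classes: Sequence[str]) -> str:
        return predictions_csv_text(self.results, classes, self.true_labels,
                                    self.fold_of)


def predictions_csv_text(
    results: Sequence[ClassificationResult],
    classes: Sequence[str],
    true_labels: Sequence[str] | None = None,
    fold_of: Sequence[int] | None = None,
) -> str:
    """Per-sample predictions as CSV text (floats via full-precision repr)."""
    buf = io.StringIO()
    writer = csv.writer(buf)
    header = ["sample_id"]
    if true_labels is not None:
        header.append("fluid_label")
    if fold_of is not None:
        header.append("fold")
    header += ["predicted", "max_posterior"] + [f"p_{c}" for c in classes]
    writer.writerow(header)
    for i, res in enumerate(results):
        row: list = [res.sample_id]
        if true_labels is not None:
            row.append(true_labels[i])
        if fold_of is not None:
            row.append(int(fold_of[i]))
        row += [res.predicted, repr(float(res.max_posterior))]
        row += [repr(float(p)) for p in res.posteriors]
        writer.writerow(row)
    return buf.getvalue()


def _default_other_n(labels: Sequence[str]) -> int:
    counts = pd.Series(list(labels)).value_counts()
    return int(round(counts.mean()))


def _train_model(
    train: Sequence[DeltaCqProfile],
    panel: MarkerPanel,
    *,
    ridge: float,
    threshold: float,
    priors_mode: str,
    other_n: int | None,
    other_radius: float,
    other_inflation: float,
    other_seed: int,
    pooled: MVNParams | None = None,
    pre_imputed: bool = False,
) -> tuple[QDAModel, MVNParams, np.ndarray]:
    """Shared training path: pooled fit → impute → augment → QDA."""
    labels = [p.fluid_label for p in train]
    if pooled is None:
        pooled = fit_mvn(list(train), ridge=ridge)
    complete = list(train) if pre_imputed else impute_all(train, pooled)
    n_other = _default_other_n([l for l in labels if l is not None]) \
        if other_n is None else other_n
    other_vecs = generate_other(
        pooled, n_other, radius=other_radius, inflation=other_inflation,
        seed=other_seed,
    )
    other_profiles = [
        DeltaCqProfile(
            sample_id=f"other_{i + 1:03d}",
            values=v,
            mask=np.ones(panel.n_targets, dtype=bool),
            fluid_label=panel.other_label,
        )
        for i, v in enumerate(other_vecs)
    ]
    model = fit_qda(
        complete + other_profiles, panel,
        priors_mode=priors_mode, ridge=ridge, threshold=threshold,
    )
    return model, pooled, other_vecs


def cross_validate(
    profiles: Sequence[DeltaCqProfile],
    panel: MarkerPanel,
    k: int = DEFAULT_K,
    seed: int = DEFAULT_SEED,
    *,
    ridge: float = DEFAULT_RIDGE,
    threshold: float = DEFAULT_THRESHOLD,
    priors_mode: str = "uniform",
    other_n: int | None = None,
    other_radius: float = DEFAULT_OTHER_RADIUS,
    other_inflation: float = DEFAULT_OTHER_INFLATION,
    gate: bool = True,
    impute_before_split: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation of the full pipeline.

    Per fold, the pooled imputation Gaussian, the imputed training rows, the
    Other augmentation and the QDA model are all functions of the training
    fold only; held-out rows are imputed with the training pooled fit before
    classification. ``gate=False`` disables the confidence gate so every
    held-out sample receives an argmax call.
    """
    profiles = list(profiles)
    labels = [p.fluid_label for p in profiles]
    if any(l is None for l in labels):
        raise ValidationError("cross-validation requires labeled profiles")
    present = {l for l in labels}
    missing = [c for c in panel.fluid_classes if c not in present]
    if missing:
        raise ValidationError(f"profiles are missing fluid class(es): {missing}")

    master = np.random.default_rng(seed)
    split_seed = int(master.integers(2**31))
    other_seeds = [int(master.integers(2**31)) for _ in range(k)]

    fold_of = kfold_split(labels, k=k, seed=split_seed)

    global_pooled: MVNParams | None = None
    if impute_before_split:
        global_pooled = fit_mvn(profiles, ridge=ridge)
        profiles = impute_all(profiles, global_pooled)

    results: list[ClassificationResult | None] = [None] * len(profiles)
    diagnostics: list[FoldDiagnostics] = []
    for f in range(k):
        train_idx = np.flatnonzero(fold_of != f)
        test_idx = np.flatnonzero(fold_of == f)
        train = [profiles[i] for i in train_idx]
        train_classes = {profiles[i].fluid_label for i in train_idx}
        lost = [c for c in panel.fluid_classes if c not in train_classes]
        if lost:
            raise FoldError(
                f"training fold {f} lost class(es): {', '.join(lost)}"
            )
        logger.info(
            "fold %d: train=%d test=%d classes=%s", f, train_idx.size,
            test_idx.size, sorted(train_classes),
        )
        model, pooled, other_vecs = _train_model(
            train, panel,
            ridge=ridge, threshold=threshold, priors_mode=priors_mode,
            other_n=other_n, other_radius=other_radius,
            other_inflation=other_inflation, other_seed=other_seeds[f],
            pooled=global_pooled, pre_imputed=impute_before_split,
        )
        test = impute_all([profiles[i] for i in test_idx],
                          global_pooled if impute_before_split else pooled)
        for i, res in zip(test_idx, classify_profiles(model, test, gate=gate)):
            results[i] = res
        diagnostics.append(
            FoldDiagnostics(
                fold=f, train_idx=train_idx, pooled=pooled,
                other_seed=other_seeds[f], other_vectors=other_vecs, model=model,
            )
        )
    final_results = [r for r in results if r is not None]
    assert len(final_results) == len(profiles)
    rate_table = build_rate_table(labels, final_results, panel)
    return CVResult(
        rate_table=rate_table,
        true_labels=list(labels),
        results=final_results,
        fold_of=fold_of,
        folds=diagnostics,
    )


# ---------------------------------------------------------------------------
# deployment path
# ---------------------------------------------------------------------------


def train_model(
    profiles: Sequence[DeltaCqProfile],
    panel: MarkerPanel,
    seed: int = DEFAULT_SEED,
    *,
    ridge: float = DEFAULT_RIDGE,
    threshold: float = DEFAULT_THRESHOLD,
    priors_mode: str = "uniform",
    other_n: int | None = None,
    other_radius: float = DEFAULT_OTHER_RADIUS,
    other_inflation: float = DEFAULT_OTHER_INFLATION,
) -> tuple[QDAModel, MVNParams]:
    """Train a deployable model on all labeled profiles (no held-out data)."""
    master = np.random.default_rng(seed)
    other_seed = int(master.integers(2**31))
    model, pooled, _ = _train_model(
        list(profiles), panel,
        ridge=ridge, threshold=threshold, priors_mode=priors_mode,
        other_n=other_n, other_radius=other_radius,
        other_inflation=other_inflation, other_seed=other_seed,
    )
    return model, pooled


def predict_profiles(
    model: QDAModel,
    pooled: MVNParams,
    profiles: Sequence[DeltaCqProfile],
    gate: bool = True,
) -> list[ClassificationResult]:
    """Impute queries with the training pooled fit, then classify."""
    return classify_profiles(model, impute_all(profiles, pooled), gate=gate)


def train_and_predict(
    train_path,
    query_path,
    panel: MarkerPanel | None = None,
    seed: int = DEFAULT_SEED,
    *,
    out_path=None,
    gate: bool = True,
    **train_kwargs,
):
    """File-level pipeline: train on one profile CSV, classify another.

    Returns ``(results, rate_table_or_None, model)``; the rate table is
    produced when every query row carries a fluid label. With ``out_path``
    set, per-sample predictions are written as CSV (byte-identical across
    reruns at a fixed seed).
    """
    if panel is None:
        panel = MarkerPanel()
    train = read_profiles(train_path, panel)
    queries = read_profiles(query_path, panel)
    model, pooled = train_model(train, panel, seed=seed, **train_kwargs)
    results = predict_profiles(model, pooled, queries, gate=gate)
    rate_table = None
    if queries and all(q.fluid_label is not None for q in queries):
        rate_table = build_rate_table(
            [q.fluid_label for q in queries], results, panel
        )
    if out_path is not None:
        text = predictions_csv_text(results, model.classes)
        with open(out_path, "w", newline="", encoding="utf-8") as fh:
            fh.write(text)
    return results, rate_table, model
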