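"""Quadratic discriminant analysis over body fluids plus an open-set class.

Each class k (seven body fluids and, when augmentation rows are present, the
synthetic "Other" class) is modelled as a Gaussian N(μ_k, Σ_k) with its own
covariance, giving quadratic decision boundaries. The posterior for a
complete ΔCq vector x is

    p(k | x) ∝ π_k · N(x; μ_k, Σ_k)

evaluated entirely in log space (log-determinants from a Cholesky
factorization, max-subtraction before exponentiation) so that points far
from every class mean still yield finite, normalized posteriors.

A confidence gate turns low-confidence calls into "inconclusive": if no
class posterior reaches the threshold (default 50%), no body fluid is
reported. The gate can be disabled to reproduce the three-way rate-table
layout (correct / another body fluid / Other) that has no inconclusive
column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_solve
from scipy.special import logsumexp

from .exceptions import TrainingError, ValidationError
from .mvn import DEFAULT_RIDGE, MVNParams, _factor, fit_mvn
from .panel_io import DeltaCqProfile, MarkerPanel

DEFAULT_THRESHOLD = 0.5

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class QDAModel:
    """A trained quadratic discriminant model.

    ``classes`` lists the body fluids in panel order, with the Other label
    appended when the training data contained augmentation rows. ``priors``
    must be a probability vector; the default training choice is uniform,
    since forensic casework has no defensible class prevalence.
    """

    panel: MarkerPanel
    classes: tuple[str, ...]
    components: tuple[MVNParams, ...]
    priors: np.ndarray
    ridge: float = DEFAULT_RIDGE
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "components", tuple(self.components))
        priors = np.asarray(self.priors, dtype=float)
        object.__setattr__(self, "priors", priors)
        if len(self.classes) != len(self.components) or len(self.classes) != priors.size:
            raise ValidationError("classes, components and priors must align")
        if np.any(priors < 0) or abs(priors.sum() - 1.0) > 1e-12:
            raise ValidationError("priors must be non-negative and sum to 1")
        dims = {c.dim for c in self.components}
        if len(dims) > 1:
            raise ValidationError(f"components have inconsistent dimensions: {dims}")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValidationError("threshold must lie in [0, 1]")

    @property
    def dim(self) -> int:
        return self.components[0].dim


@dataclass
class ClassificationResult:
    """Posterior vector and gated call for one sample."""

    sample_id: str
    posteriors: np.ndarray
    predicted: str
    max_posterior: float


def fit_qda(
    profiles: Sequence[DeltaCqProfile],
    panel: MarkerPanel,
    priors_mode: str = "uniform",
    ridge: float = DEFAULT_RIDGE,
    threshold: float = DEFAULT_THRESHOLD,
) -> QDAModel:
    """Fit per-class Gaussians to labeled, complete ΔCq profiles.

    Classes are the panel's fluids (in panel order) plus the Other label if
    any row carries it. Every class must have at least d+1 complete rows.
    ``priors_mode`` is "uniform" or "empirical" (proportional to class
    counts).
    """
    if priors_mode not in ("uniform", "empirical"):
        raise ValidationError(f"unknown priors_mode {priors_mode!r}")
    by_class: dict[str, list[DeltaCqProfile]] = {}
    for p in profiles:
        if not p.is_complete:
            raise TrainingError(
                f"profile {p.sample_id!r} is incomplete; impute before training"
            )
        if p.fluid_label is None:
            raise TrainingError(f"profile {p.sample_id!r} has no fluid label")
        if p.fluid_label not in panel.fluid_classes and p.fluid_label != panel.other_label:
            raise TrainingError(
                f"profile {p.sample_id!r} has label {p.fluid_label!r} outside the panel"
            )
        by_class.setdefault(p.fluid_label, []).append(p)

    classes = [c for c in panel.fluid_classes if c in by_class]
    missing = [c for c in panel.fluid_classes if c not in by_class]
    if missing:
        raise TrainingError(f"no training rows for class(es): {', '.join(missing)}")
    if panel.other_label in by_class:
        classes.append(panel.other_label)

    d = profiles[0].values.size
    components = []
    counts = []
    for cls in classes:
        rows = by_class[cls]
        if len(rows) < d + 1:
            raise TrainingError(
                f"class {cls!r} has {len(rows)} rows; need at least {d + 1}"
            )
        components.append(fit_mvn(rows, ridge=ridge))
        counts.append(len(rows))
    if priors_mode == "uniform":
        priors = np.full(len(classes), 1.0 / len(classes))
    else:
        priors = np.asarray(counts, dtype=float) / sum(counts)
    return QDAModel(
        panel=panel,
        classes=tuple(classes),
        components=tuple(components),
        priors=priors,
        ridge=ridge,
        threshold=threshold,
    )


def _log_joint(model: QDAModel, X: np.ndarray) -> np.ndarray:
    """log(π_k) + log N(x; μ_k, Σ_k) for every row of X and class k."""
    X = np.atleast_2d(X)
    n, d = X.shape
    out = np.empty((n, len(model.classes)))
    log_priors = np.log(model.priors)
    for k, comp in enumerate(model.components):
        factor = _factor(comp.covariance)
        # log|Σ| from the Cholesky factor's diagonal
        logdet = 2.0 * float(np.sum(np.log(np.diag(factor[0]))))
        dX = X - comp.mean
        maha2 = np.einsum("ij,ji->i", dX, cho_solve(factor, dX.T))
        out[:, k] = log_priors[k] - 0.5 * (d * _LOG_2PI + logdet + maha2)
    return out


def posterior(model: QDAModel, x: np.ndarray) -> np.ndarray:
    """Per-class posterior probabilities for one complete ΔCq vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.dim,):
        raise ValidationError(f"expected a complete vector of length {model.dim}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("input vector contains non-finite entries")
    lj = _log_joint(model, x[None, :])[0]
    lj -= lj.max()
    p = np.exp(lj - logsumexp(lj))
    return p / p.sum()


def posterior_many(model: QDAModel, X: np.ndarray) -> np.ndarray:
    """Row-wise posteriors for an (n, d) matrix of complete vectors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValidationError("input matrix contains non-finite entries")
    lj = _log_joint(model, X)
    lj -= lj.max(axis=1, keepdims=True)
    p = np.exp(lj - logsumexp(lj, axis=1, keepdims=True))
    return p / p.sum(axis=1, keepdims=True)


def classify(
    model: QDAModel, x: np.ndarray, sample_id: str = "", gate: bool = True
) -> ClassificationResult:
    """Posterior-gated class call for one complete vector.

    The argmax class is reported when its posterior reaches the model's
    confidence threshold; otherwise the call is "inconclusive". Exact ties
    resolve to the earlier class in canonical (panel) order. ``gate=False``
    always reports the argmax class.
    """
    p = posterior(model, x)
    idx = int(np.argmax(p))  # first maximum wins on ties
    max_post = float(p[idx])
    if gate and max_post < model.threshold:
        predicted = model.panel.inconclusive_label
    else:
        predicted = model.classes[idx]
    return ClassificationResult(
        sample_id=sample_id, posteriors=p, predicted=predicted, max_posterior=max_post
    )


def classify_profiles(
    model: QDAModel, profiles: Sequence[DeltaCqProfile], gate: bool = True
) -> list[ClassificationResult]:
    """Classify a collection of complete profiles."""
    return [classify(model, p.values, sample_id=p.sample_id, gate=gate) for p in profiles]
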