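"""Multivariate-normal estimation, Mahalanobis geometry and the Other class.

This module houses the distributional machinery shared by imputation and
classification:

* :func:`fit_mvn` — pooled or per-class Gaussian fit on complete cases, with
  a relative ridge on the diagonal to keep covariances invertible;
* :func:`mahalanobis` — covariance-scaled distance, whose level set at
  radius *r* is the "*r*-standard-deviation ellipsoid" of the fit;
* :func:`conditional_impute` — single imputation of missing markers by the
  conditional multivariate mean given the sample's observed markers;
* :func:`generate_other` — rejection sampling of synthetic "Other" training
  points outside the 3.5-SD ellipsoid of the pooled fit, so that extreme
  observations are rejected into an open-set class instead of being forced
  into the nearest body-fluid label.

All solves go through a symmetric (Cholesky) factorization; a factorization
failure is reported with advice to raise the ridge, never papered over with
a pseudo-inverse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve, cholesky

from .exceptions import EstimationError, GenerationError, ImputationError, ValidationError
from .panel_io import DeltaCqProfile

#: Relative ridge added to covariance diagonals: ridge × (trace/d).
DEFAULT_RIDGE = 1e-6

#: Mahalanobis radius of the Other-class exclusion ellipsoid.
DEFAULT_OTHER_RADIUS = 3.5

#: Covariance scale factor of the Other-class proposal distribution.
DEFAULT_OTHER_INFLATION = 2.0

_PSD_RTOL = 1e-8


@dataclass(frozen=True)
class MVNParams:
    """Mean vector and symmetric positive-semidefinite covariance (cycles²)."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        if mean.ndim != 1 or cov.shape != (mean.size, mean.size):
            raise ValidationError(
                f"dimension mismatch: mean {mean.shape}, covariance {cov.shape}"
            )
        if not np.allclose(cov, cov.T, rtol=0, atol=1e-8 * max(1.0, np.abs(cov).max())):
            raise ValidationError("covariance is not symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        scale = max(1.0, float(eigvals[-1]))
        if eigvals[0] < -_PSD_RTOL * scale:
            raise ValidationError(
                f"covariance is not positive semidefinite (min eigenvalue {eigvals[0]:.3g})"
            )

    @property
    def dim(self) -> int:
        return self.mean.size


def _complete_matrix(data) -> np.ndarray:
    """Extract the fully observed rows of profiles or an array as a matrix."""
    if isinstance(data, np.ndarray):
        X = np.asarray(data, dtype=float)
        if X.ndim != 2:
            raise ValidationError("expected a 2-D data matrix")
        return X[np.isfinite(X).all(axis=1)]
    profiles = list(data)
    rows = [p.values for p in profiles if p.is_complete]
    if not rows:
        d = profiles[0].values.size if profiles else 0
        return np.empty((0, d))
    return np.vstack(rows)


def fit_mvn(data, ridge: float = DEFAULT_RIDGE) -> MVNParams:
    """Fit a multivariate normal to the fully observed rows of ``data``.

    ``data`` is either a sequence of :class:`DeltaCqProfile` or an (n, d)
    array (rows containing NaN count as incomplete). The covariance is the
    unbiased sample covariance with ``ridge × (trace/d)`` added to the
    diagonal; at least d+1 complete rows are required.
    """
    if ridge < 0:
        raise ValidationError("ridge must be non-negative")
    X = _complete_matrix(data)
    n, d = X.shape
    if n < d + 1:
        raise EstimationError(
            f"need at least {d + 1} fully observed rows to fit a {d}-dimensional "
            f"Gaussian, got {n}"
        )
    mean = X.mean(axis=0)
    centered = X - mean
    cov = centered.T @ centered / (n - 1)
    cov = (cov + cov.T) / 2.0
    if ridge > 0:
        cov = cov + ridge * (np.trace(cov) / d) * np.eye(d)
    return MVNParams(mean=mean, covariance=cov)


def _factor(cov: np.ndarray):
    try:
        return cho_factor(cov, lower=True)
    except (LinAlgError, np.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            "covariance is singular or not positive definite; refit with a "
            "larger ridge"
        ) from exc


def mahalanobis(x: np.ndarray, params: MVNParams) -> float:
    """sqrt((x−μ)ᵀ Σ⁻¹ (x−μ)) — distance in SD units along every axis."""
    x = np.asarray(x, dtype=float)
    dx = x - params.mean
    factor = _factor(params.covariance)
    d2 = float(dx @ cho_solve(factor, dx))
    return float(np.sqrt(max(d2, 0.0)))


def mahalanobis_many(X: np.ndarray, params: MVNParams) -> np.ndarray:
    """Vectorized Mahalanobis distances for the rows of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    dX = X - params.mean
    factor = _factor(params.covariance)
    d2 = np.einsum("ij,ji->i", dX, cho_solve(factor, dX.T))
    return np.sqrt(np.maximum(d2, 0.0))


def conditional_impute(profile: DeltaCqProfile, params: MVNParams) -> DeltaCqProfile:
    """Fill a profile's missing markers with the conditional multivariate mean.

    With observed block *o* and missing block *m*, the imputed values are

        μ_m + Σ_mo Σ_oo⁻¹ (x_o − μ_o),

    so every imputed marker depends on all the observed markers of that
    sample. Observed entries are untouched; the returned profile is complete.
    """
    if profile.values.size != params.dim:
        raise ValidationError(
            f"profile dimension {profile.values.size} does not match "
            f"parameters ({params.dim})"
        )
    if profile.is_complete:
        return DeltaCqProfile(
            sample_id=profile.sample_id,
            values=profile.values,
            mask=profile.mask,
            fluid_label=profile.fluid_label,
        )
    obs = profile.mask
    if not obs.any():
        raise ImputationError(
            f"profile {profile.sample_id!r} has no observed markers; cannot "
            "condition on nothing"
        )
    mis = ~obs
    mu_o = params.mean[obs]
    mu_m = params.mean[mis]
    S_oo = params.covariance[np.ix_(obs, obs)]
    S_mo = params.covariance[np.ix_(mis, obs)]
    factor = _factor(S_oo)
    imputed = mu_m + S_mo @ cho_solve(factor, profile.values[obs] - mu_o)
    values = profile.values.copy()
    values[mis] = imputed
    return DeltaCqProfile(
        sample_id=profile.sample_id,
        values=values,
        mask=np.ones_like(obs),
        fluid_label=profile.fluid_label,
    )


def impute_all(
    profiles: Sequence[DeltaCqProfile], params: MVNParams
) -> list[DeltaCqProfile]:
    """Impute every profile in a collection (complete ones pass through)."""
    return [conditional_impute(p, params) for p in profiles]


def generate_other(
    params: MVNParams,
    n: int,
    radius: float = DEFAULT_OTHER_RADIUS,
    inflation: float = DEFAULT_OTHER_INFLATION,
    seed: int | None = None,
    max_proposals: int = 1_000_000,
) -> np.ndarray:
    """Draw ``n`` Other-class vectors outside the ``radius``-SD ellipsoid.

    Proposals come from a Gaussian centred at the fit's mean with covariance
    ``inflation² × Σ``; proposals whose Mahalanobis distance (under the
    original Σ) is ≤ ``radius`` are rejected. Inflating the proposal keeps
    acceptance workable while concentrating Other mass near the exclusion
    boundary, where the open-set decision actually happens. Deterministic
    given ``seed``.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    if radius <= 0 or inflation < 1:
        raise ValidationError("need radius > 0 and inflation ≥ 1")
    try:
        L = cholesky(params.covariance, lower=True)
    except (LinAlgError, np.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            "covariance is singular; refit with a larger ridge before "
            "generating Other samples"
        ) from exc
    rng = np.random.default_rng(seed)
    d = params.dim
    accepted: list[np.ndarray] = []
    n_accepted = 0
    proposals_used = 0
    while n_accepted < n:
        batch = min(max(2 * (n - n_accepted), 256), max_proposals - proposals_used)
        if batch <= 0:
            raise GenerationError(
                f"exhausted {max_proposals} proposals with only {n_accepted}/{n} "
                f"accepted; increase inflation (acceptance region too thin)"
            )
        Z = rng.standard_normal((batch, d))
        X = params.mean + inflation * (Z @ L.T)
        proposals_used += batch
        keep = mahalanobis_many(X, params) > radius
        if keep.any():
            accepted.append(X[keep])
            n_accepted += int(keep.sum())
    return np.vstack(accepted)[:n]
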