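"""Synthetic qPCR data emulating a body-fluid miRNA population study.

Real casework-scale ΔCq data for this panel are not redistributable, so the
generator produces datasets with the same *statistical shape* as the study
population the pipeline is designed for:

* seven body fluids with class sizes (51, 53, 50, 46, 53, 52, 50) — 355
  samples in total;
* per-fluid multivariate-normal ΔCq structure over the seven target markers,
  with deliberate overlap between menstrual and vaginal secretions (the
  hardest pair to separate in practice);
* missing markers, missing completely at random, with a per-marker rate
  chosen so that the expected fraction of fully observed samples is ≈ 71%
  (252 of 355);
* optional replicate-level Cq simulation: reference Cq values, duplicate
  technical replicates with Gaussian noise, and non-detects above the cycle
  limit;
* named "treatment" shifts — additive per-marker ΔCq offsets emulating
  marker degradation under heat, chemical or UV exposure, which raises the
  Cq of affected targets.

The per-fluid mean vectors are fixtures: they follow the qualitative
literature patterns (e.g. semen strongly expresses miR-891a, hence a low
ΔCq; feces and vaginal secretions separate on miR-141/miR-205) but are not
measurements from any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .panel_io import CqRecord, DeltaCqProfile, MarkerPanel

#: Class sizes of the emulated population study, in panel fluid order
#: (blood, menstrual, feces, urine, saliva, semen, vaginal).
STUDY_CLASS_SIZES = (51, 53, 50, 46, 53, 52, 50)

#: Expected fraction of fully observed samples in the emulated study.
STUDY_COMPLETE_FRACTION = 252 / 355

# Per-fluid ΔCq mean fixtures (rows: fluids in panel order; columns: targets
# miR-200b, -320c, -10b, -891a, -141, -412, -205). Lower = more expressed.
_DEFAULT_MEANS = {
    "blood": (6.0, 2.0, 3.0, 10.0, 8.0, 9.0, 9.0),
    "menstrual": (5.0, 3.0, 3.0, 9.0, 6.0, 5.0, 7.0),
    "feces": (4.0, 6.0, 7.0, 10.0, 2.0, 8.0, 5.0),
    "urine": (2.0, 5.0, 6.0, 9.0, 7.0, 8.0, 8.0),
    "saliva": (7.0, 4.0, 6.0, 9.0, 5.0, 4.0, 3.0),
    "semen": (8.0, 5.0, 5.0, 1.0, 6.0, 7.0, 6.0),
    "vaginal": (5.0, 4.0, 4.0, 9.0, 3.0, 4.0, 6.0),
}

# Per-fluid marginal SDs (cycles); exchangeable correlation 0.3 within fluid.
_DEFAULT_SDS = {
    "blood": 1.2,
    "menstrual": 1.5,
    "feces": 1.3,
    "urine": 1.4,
    "saliva": 1.3,
    "semen": 1.2,
    "vaginal": 1.5,
}
_DEFAULT_CORR = 0.3

# Degradation scenarios: additive ΔCq offsets on the markers most affected
# by each exposure (degraded target ⇒ later amplification ⇒ higher ΔCq).
_DEFAULT_TREATMENTS = {
    "none": {},
    "heat": {"miR-891a": 3.0, "miR-412": 2.0, "miR-205": 2.5},
    "chem_uv": {"miR-200b": 2.5, "miR-10b": 2.5, "miR-205": 3.0},
}


def _exchangeable_cov(d: int, sd: float, corr: float) -> np.ndarray:
    cov = np.full((d, d), corr * sd * sd)
    np.fill_diagonal(cov, sd * sd)
    return cov


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic dataset."""

    panel: MarkerPanel
    class_sizes: dict[str, int]
    class_means: dict[str, np.ndarray]
    class_covs: dict[str, np.ndarray]
    reference_cq_mean: float = 20.0
    reference_cq_sd: float = 1.5
    replicate_sd: float = 0.25
    missing_rates: np.ndarray = field(default_factory=lambda: np.zeros(7))
    nondetect_cq_limit: float = 40.0
    treatment_shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 7

    def __post_init__(self) -> None:
        d = self.panel.n_targets
        self.missing_rates = np.asarray(self.missing_rates, dtype=float)
        if self.missing_rates.shape != (d,):
            raise ValidationError(f"missing_rates must have length {d}")
        if np.any((self.missing_rates < 0) | (self.missing_rates > 1)):
            raise ValidationError("missing rates must lie in [0, 1]")
        for fluid in self.panel.fluid_classes:
            if fluid not in self.class_sizes:
                raise ValidationError(f"no class size for fluid {fluid!r}")
            if self.class_sizes[fluid] < 0:
                raise ValidationError(f"negative class size for fluid {fluid!r}")
            mean = np.asarray(self.class_means[fluid], dtype=float)
            cov = np.asarray(self.class_covs[fluid], dtype=float)
            if mean.shape != (d,) or cov.shape != (d, d):
                raise ValidationError(f"shape mismatch in parameters for {fluid!r}")
            if not np.allclose(cov, cov.T):
                raise ValidationError(f"covariance for {fluid!r} is not symmetric")
            if np.linalg.eigvalsh(cov)[0] < -1e-10:
                raise ValidationError(f"covariance for {fluid!r} is not PSD")
            self.class_means[fluid] = mean
            self.class_covs[fluid] = cov

    @property
    def total_samples(self) -> int:
        return sum(self.class_sizes[f] for f in self.panel.fluid_classes)


def default_config(seed: int = 7) -> SimulationConfig:
    """The default study-shaped configuration (355 samples, 7 fluids).

    The uniform per-marker missing rate r solves (1−r)⁷ = 252/355, so the
    expected complete-case fraction matches the emulated study.
    """
    panel = MarkerPanel()
    d = panel.n_targets
    missing_rate = 1.0 - STUDY_COMPLETE_FRACTION ** (1.0 / d)
    return SimulationConfig(
        panel=panel,
        class_sizes=dict(zip(panel.fluid_classes, STUDY_CLASS_SIZES)),
        class_means={f: np.asarray(_DEFAULT_MEANS[f]) for f in panel.fluid_classes},
        class_covs={
            f: _exchangeable_cov(d, _DEFAULT_SDS[f], _DEFAULT_CORR)
            for f in panel.fluid_classes
        },
        missing_rates=np.full(d, missing_rate),
        treatment_shifts={k: dict(v) for k, v in _DEFAULT_TREATMENTS.items()},
        seed=seed,
    )


def _draw_latent(config: SimulationConfig, rng: np.random.Generator):
    """Draw latent complete ΔCq vectors and MCAR masks for every sample."""
    rows = []
    for fluid in config.panel.fluid_classes:
        n = config.class_sizes[fluid]
        if n == 0:
            continue
        L = np.linalg.cholesky(
            config.class_covs[fluid]
            + 1e-12 * np.eye(config.panel.n_targets)  # guard exact PSD edge
        )
        Z = rng.standard_normal((n, config.panel.n_targets))
        X = config.class_means[fluid] + Z @ L.T
        masks = rng.random((n, config.panel.n_targets)) >= config.missing_rates
        for i in range(n):
            rows.append((f"{fluid}_{i + 1:03d}", fluid, X[i], masks[i]))
    return rows


def simulate_profiles(
    config: SimulationConfig, level: str = "profile", seed: int | None = None
):
    """Generate a synthetic dataset at profile or replicate-Cq level.

    ``level="profile"`` returns :class:`DeltaCqProfile` objects with MCAR
    masking applied. ``level="cq"`` returns replicate-level
    :class:`CqRecord` objects: reference Cq values are drawn per sample,
    each target's true Cq is the reference average plus the latent ΔCq,
    duplicate replicates get independent Gaussian noise (``replicate_sd``),
    values beyond ``nondetect_cq_limit`` become non-detects, and masked
    markers are simply not measured. Deterministic given the seed
    (``config.seed`` unless overridden).
    """
    if level not in ("profile", "cq"):
        raise ValidationError(f"unknown level {level!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = _draw_latent(config, rng)
    if level == "profile":
        profiles = []
        for sid, fluid, x, mask in rows:
            values = np.where(mask, x, np.nan)
            profiles.append(
                DeltaCqProfile(sample_id=sid, values=values, mask=mask, fluid_label=fluid)
            )
        return profiles

    records: list[CqRecord] = []
    panel = config.panel
    for sid, fluid, x, mask in rows:
        ref_cqs = rng.normal(config.reference_cq_mean, config.reference_cq_sd,
                             size=len(panel.reference_markers))
        ref_avg = float(np.mean(ref_cqs))
        for marker, ref_cq in zip(panel.reference_markers, ref_cqs):
            reps = ref_cq + rng.normal(0.0, config.replicate_sd, size=2)
            records.append(
                CqRecord(
                    sample_id=sid,
                    fluid_label=fluid,
                    marker=marker,
                    replicate_cqs=[_censor(v, config.nondetect_cq_limit) for v in reps],
                )
            )
        for j, marker in enumerate(panel.target_markers):
            if not mask[j]:
                continue  # untested marker: no well on the plate
            true_cq = ref_avg + x[j]
            reps = true_cq + rng.normal(0.0, config.replicate_sd, size=2)
            records.append(
                CqRecord(
                    sample_id=sid,
                    fluid_label=fluid,
                    marker=marker,
                    replicate_cqs=[_censor(v, config.nondetect_cq_limit) for v in reps],
                )
            )
    return records


def _censor(cq: float, limit: float) -> float | None:
    return None if cq > limit else float(max(cq, 0.0))


def apply_treatment(
    profiles, shift_name: str, config: SimulationConfig
) -> list[DeltaCqProfile]:
    """Apply a named degradation scenario's ΔCq offsets to observed values.

    Masks are unchanged: degradation shifts what was measured, it does not
    create or remove measurements here.
    """
    if shift_name not in config.treatment_shifts:
        raise ValidationError(
            f"unknown treatment {shift_name!r}; known: "
            f"{sorted(config.treatment_shifts)}"
        )
    shifts = config.treatment_shifts[shift_name]
    offset = np.zeros(config.panel.n_targets)
    for marker, delta in shifts.items():
        if marker not in config.panel.target_markers:
            raise ValidationError(f"treatment {shift_name!r} names unknown marker {marker!r}")
        offset[config.panel.marker_index(marker)] = delta
    out = []
    for p in profiles:
        values = p.values.copy()
        values[p.mask] = values[p.mask] + offset[p.mask]
        out.append(
            DeltaCqProfile(
                sample_id=p.sample_id, values=values, mask=p.mask, fluid_label=p.fluid_label
            )
        )
    return out
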