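"""Replicate aggregation and ΔCq profile construction.

qPCR targets are amplified in duplicate technical replicates; each marker's
replicates are averaged, and expression is normalized by subtracting the
mean Cq of the endogenous reference markers (let-7g, let-7i):

    ΔCq = Cq(target) − mean(Cq(references))

A lower ΔCq means higher expression relative to the references. Non-detect
target markers become *missing* values (masked, to be imputed downstream)
rather than being assigned a ceiling Cq, which would distort the Gaussian
class models. Samples lacking a numeric value for any reference marker have
no defined ΔCq and are excluded with a reason.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .panel_io import CqRecord, DeltaCqProfile, MarkerPanel

#: Replicates further apart than this (cycles) are flagged as discordant.
DEFAULT_CONCORDANCE_LIMIT = 1.0

FLAG_NONDETECT = "nondetect_replicate"
FLAG_DISCORDANT = "discordant_replicates"


def aggregate_replicates(
    record: CqRecord, concordance_limit: float = DEFAULT_CONCORDANCE_LIMIT
) -> tuple[float | None, frozenset[str]]:
    """Collapse a record's technical replicates to one Cq value plus QC flags.

    Returns ``(mean_cq, flags)``. If any replicate is a non-detect the result
    is a non-detect (``None``) carrying the ``nondetect_replicate`` flag. A
    numeric spread greater than ``concordance_limit`` cycles adds the
    ``discordant_replicates`` flag but the mean is still returned: flags
    report quality, they are not failures.
    """
    numeric = [cq for cq in record.replicate_cqs if cq is not None]
    flags: set[str] = set()
    if len(numeric) >= 2 and max(numeric) - min(numeric) > concordance_limit:
        flags.add(FLAG_DISCORDANT)
    if len(numeric) < len(record.replicate_cqs):
        flags.add(FLAG_NONDETECT)
        return None, frozenset(flags)
    return float(np.mean(numeric)), frozenset(flags)


def compute_delta_cq(target_cq: float, reference_cqs: Sequence[float]) -> float:
    """ΔCq = target Cq minus the mean reference Cq."""
    refs = list(reference_cqs)
    if not refs:
        raise ValidationError("reference Cq list is empty; ΔCq is undefined")
    return float(target_cq - np.mean(refs))


def build_profiles(
    records: Sequence[CqRecord],
    panel: MarkerPanel,
    concordance_limit: float = DEFAULT_CONCORDANCE_LIMIT,
) -> tuple[list[DeltaCqProfile], list[tuple[str, str]]]:
    """Turn replicate-level records into per-sample ΔCq profiles.

    Returns ``(profiles, exclusions)``. Target markers that are non-detect or
    absent are masked; samples missing a numeric value for any reference
    marker are excluded and listed in ``exclusions`` as (sample_id, reason).
    Sample order follows first appearance in ``records``.
    """
    by_sample: dict[str, dict[str, CqRecord]] = {}
    labels: dict[str, str | None] = {}
    order: list[str] = []
    for rec in records:
        if rec.sample_id not in by_sample:
            by_sample[rec.sample_id] = {}
            labels[rec.sample_id] = rec.fluid_label
            order.append(rec.sample_id)
        if rec.marker in by_sample[rec.sample_id]:
            raise ValidationError(
                f"sample {rec.sample_id!r}: duplicate record for marker {rec.marker!r}"
            )
        by_sample[rec.sample_id][rec.marker] = rec

    profiles: list[DeltaCqProfile] = []
    exclusions: list[tuple[str, str]] = []
    for sid in order:
        markers = by_sample[sid]
        ref_cqs: list[float] = []
        missing_refs: list[str] = []
        for ref in panel.reference_markers:
            rec = markers.get(ref)
            if rec is None:
                missing_refs.append(ref)
                continue
            cq, _ = aggregate_replicates(rec, concordance_limit)
            if cq is None:
                missing_refs.append(ref)
            else:
                ref_cqs.append(cq)
        if missing_refs:
            exclusions.append(
                (sid, f"no numeric Cq for reference marker(s): {', '.join(missing_refs)}")
            )
            continue
        values = np.full(panel.n_targets, np.nan)
        mask = np.zeros(panel.n_targets, dtype=bool)
        for j, marker in enumerate(panel.target_markers):
            rec = markers.get(marker)
            if rec is None:
                continue
            cq, _ = aggregate_replicates(rec, concordance_limit)
            if cq is None:
                continue
            values[j] = compute_delta_cq(cq, ref_cqs)
            mask[j] = True
        profiles.append(
            DeltaCqProfile(sample_id=sid, values=values, mask=mask, fluid_label=labels[sid])
        )
    return profiles, exclusions
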