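"""Data model and file I/O for miRNA qPCR panels.

Three tabular interchange formats are supported, all plain text:

* a **long Cq table** (CSV) with one row per technical replicate, as exported
  from a qPCR instrument run sheet: ``sample_id, fluid_label, marker, cq,
  replicate``;
* a **wide ΔCq profile table** (CSV) with one row per sample and one column
  per target marker, missing cells written as ``NA``;
* a **model file** (JSON) holding a trained quadratic-discriminant model with
  the marker panel embedded, so the file is self-describing.

Non-detect reactions ("Undetermined" wells that never crossed the
fluorescence threshold) are first-class values throughout: they are parsed to
``None`` / a masked entry and are never silently coerced to a number.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import FormatError, ModelLoadError, ValidationError

#: Cell contents treated as a non-detect / missing value on input.
NON_DETECT_TOKENS = frozenset({"", "NA", "N/A", "Undetermined", "undetermined", "nan", "NaN"})

#: Token written for missing / non-detect cells on output.
MISSING_TOKEN = "NA"

#: Largest valid Cq: the thermal protocol runs 40 amplification cycles, so a
#: reaction that has not crossed threshold by then is a non-detect.
DEFAULT_CYCLE_MAX = 40.0

_DEFAULT_TARGETS = (
    "miR-200b",
    "miR-320c",
    "miR-10b",
    "miR-891a",
    "miR-141",
    "miR-412",
    "miR-205",
)
_DEFAULT_REFERENCES = ("let-7g", "let-7i")
_DEFAULT_FLUIDS = ("blood", "menstrual", "feces", "urine", "saliva", "semen", "vaginal")


@dataclass(frozen=True)
class MarkerPanel:
    """The marker and class vocabulary of one assay design.

    The default panel is the seven-target body-fluid panel (miR-200b, -320c,
    -10b, -891a, -141, -412, -205) normalized to the endogenous references
    let-7g and let-7i, discriminating seven body fluids.
    """

    target_markers: tuple[str, ...] = _DEFAULT_TARGETS
    reference_markers: tuple[str, ...] = _DEFAULT_REFERENCES
    fluid_classes: tuple[str, ...] = _DEFAULT_FLUIDS
    other_label: str = "Other"
    inconclusive_label: str = "inconclusive"

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_markers", tuple(self.target_markers))
        object.__setattr__(self, "reference_markers", tuple(self.reference_markers))
        object.__setattr__(self, "fluid_classes", tuple(self.fluid_classes))
        if len(self.target_markers) < 1:
            raise ValidationError("panel needs at least one target marker")
        if len(self.reference_markers) < 1:
            raise ValidationError("panel needs at least one reference marker")
        if len(self.fluid_classes) < 2:
            raise ValidationError("panel needs at least two fluid classes")
        groups = [
            set(self.target_markers),
            set(self.reference_markers),
            set(self.fluid_classes),
            {self.other_label, self.inconclusive_label},
        ]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValidationError(
                "target markers, reference markers, fluid classes and reserved "
                "labels must be mutually disjoint"
            )

    @property
    def n_targets(self) -> int:
        return len(self.target_markers)

    @property
    def all_markers(self) -> tuple[str, ...]:
        return self.target_markers + self.reference_markers

    def marker_index(self, marker: str) -> int:
        return self.target_markers.index(marker)

    def to_dict(self) -> dict:
        return {
            "target_markers": list(self.target_markers),
            "reference_markers": list(self.reference_markers),
            "fluid_classes": list(self.fluid_classes),
            "other_label": self.other_label,
            "inconclusive_label": self.inconclusive_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerPanel":
        return cls(
            target_markers=tuple(d["target_markers"]),
            reference_markers=tuple(d["reference_markers"]),
            fluid_classes=tuple(d["fluid_classes"]),
            other_label=d.get("other_label", "Other"),
            inconclusive_label=d.get("inconclusive_label", "inconclusive"),
        )


@dataclass
class CqRecord:
    """All technical replicates of one marker in one sample.

    ``replicate_cqs`` holds floats for detected reactions and ``None`` for
    non-detects; at least one replicate must be present.
    """

    sample_id: str
    fluid_label: str | None
    marker: str
    replicate_cqs: list[float | None]
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.replicate_cqs:
            raise ValidationError(f"record {self.sample_id}/{self.marker}: no replicates")
        for cq in self.replicate_cqs:
            if cq is None:
                continue
            if not math.isfinite(cq):
                raise ValidationError(
                    f"record {self.sample_id}/{self.marker}: non-finite Cq {cq!r}"
                )


@dataclass
class DeltaCqProfile:
    """A sample's ΔCq vector over the panel's target markers.

    Entries where ``mask`` is False are missing and carry NaN as a sentinel;
    they are never valid data. ``fluid_label`` is None when the source fluid
    is unknown (casework queries).
    """

    sample_id: str
    values: np.ndarray
    mask: np.ndarray
    fluid_label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        self.mask = np.asarray(self.mask, dtype=bool).copy()
        if self.values.shape != self.mask.shape or self.values.ndim != 1:
            raise ValidationError(
                f"profile {self.sample_id}: values/mask shape mismatch "
                f"{self.values.shape} vs {self.mask.shape}"
            )
        # enforce the sentinel: masked-out entries are NaN, observed are finite
        self.values[~self.mask] = np.nan
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValidationError(
                f"profile {self.sample_id}: observed entries must be finite"
            )

    @property
    def is_complete(self) -> bool:
        return bool(self.mask.all())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DeltaCqProfile):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.fluid_label == other.fluid_label
            and np.array_equal(self.mask, other.mask)
            and np.array_equal(
                self.values[self.mask], other.values[other.mask]
            )
        )


def profiles_to_matrix(
    profiles: Sequence[DeltaCqProfile],
) -> tuple[np.ndarray, np.ndarray, list[str | None], list[str]]:
    """Stack profiles into (values, mask, labels, sample_ids) arrays."""
    if not profiles:
        raise ValidationError("empty profile collection")
    values = np.vstack([p.values for p in profiles])
    mask = np.vstack([p.mask for p in profiles])
    labels = [p.fluid_label for p in profiles]
    ids = [p.sample_id for p in profiles]
    return values, mask, labels, ids


# ---------------------------------------------------------------------------
# long Cq table
# ---------------------------------------------------------------------------

_CQ_COLUMNS = ("sample_id", "fluid_label", "marker", "cq", "replicate")


def _parse_label(token: str, panel: MarkerPanel, where: str) -> str | None:
    token = token.strip()
    if token in NON_DETECT_TOKENS or token.lower() == "unknown":
        return None
    if token in panel.fluid_classes or token == panel.other_label:
        return token
    raise ValidationError(f"{where}: unknown fluid label {token!r}")


def read_cq_table(
    path, panel: MarkerPanel, cycle_max: float = DEFAULT_CYCLE_MAX
) -> list[CqRecord]:
    """Read a long-format replicate-level Cq CSV into CqRecords.

    One record is produced per (sample, marker) pair with all replicates
    gathered in replicate order. Non-detect tokens are preserved as
    non-detects; unknown markers and out-of-range Cq values are rejected.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _CQ_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        known = set(panel.all_markers)
        grouped: dict[tuple[str, str], list[tuple[int, float | None]]] = {}
        labels: dict[str, str | None] = {}
        for lineno, row in enumerate(reader, start=2):
            marker = row["marker"].strip()
            if marker not in known:
                raise ValidationError(f"{path} line {lineno}: unknown marker {marker!r}")
            token = row["cq"].strip()
            if token in NON_DETECT_TOKENS:
                cq: float | None = None
            else:
                try:
                    cq = float(token)
                except ValueError as exc:
                    raise ValidationError(
                        f"{path} line {lineno}: unparseable Cq {token!r}"
                    ) from exc
                if not (0.0 <= cq <= cycle_max):
                    raise ValidationError(
                        f"{path} line {lineno}: Cq {cq} outside [0, {cycle_max}]"
                    )
            sid = row["sample_id"].strip()
            label = _parse_label(row["fluid_label"], panel, f"{path} line {lineno}")
            if sid in labels and labels[sid] != label:
                raise ValidationError(
                    f"{path} line {lineno}: sample {sid!r} has conflicting fluid labels"
                )
            labels[sid] = label
            try:
                rep = int(row["replicate"])
            except ValueError as exc:
                raise ValidationError(
                    f"{path} line {lineno}: unparseable replicate {row['replicate']!r}"
                ) from exc
            grouped.setdefault((sid, marker), []).append((rep, cq))
    records = []
    for (sid, marker), reps in grouped.items():
        reps.sort(key=lambda t: t[0])
        records.append(
            CqRecord(
                sample_id=sid,
                fluid_label=labels[sid],
                marker=marker,
                replicate_cqs=[cq for _, cq in reps],
            )
        )
    return records


def write_cq_table(records: Iterable[CqRecord], path) -> None:
    """Write CqRecords to the long-format replicate-level CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CQ_COLUMNS)
        for rec in records:
            label = rec.fluid_label if rec.fluid_label is not None else ""
            for i, cq in enumerate(rec.replicate_cqs, start=1):
                token = MISSING_TOKEN if cq is None else repr(float(cq))
                writer.writerow([rec.sample_id, label, rec.marker, token, i])


# ---------------------------------------------------------------------------
# wide ΔCq profile table
# ---------------------------------------------------------------------------


def write_profiles(
    profiles: Sequence[DeltaCqProfile], path, panel: MarkerPanel | None = None
) -> None:
    """Write profiles to a wide CSV (one marker column per target).

    Values are written with ``repr`` so the write→read round trip preserves
    every float bit-exactly. Masked entries become ``NA``. The panel supplies
    the marker column names (defaults to the standard seven-target panel).
    """
    if panel is None:
        panel = MarkerPanel()
    seen: set[str] = set()
    for p in profiles:
        if p.sample_id in seen:
            raise ValidationError(f"duplicate sample_id {p.sample_id!r}")
        seen.add(p.sample_id)
        if len(p.values) != panel.n_targets:
            raise ValidationError(
                f"profile {p.sample_id}: dimension {len(p.values)} does not "
                f"match panel ({panel.n_targets})"
            )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "fluid_label", *panel.target_markers])
        for p in profiles:
            label = p.fluid_label if p.fluid_label is not None else ""
            cells = [
                repr(float(v)) if m else MISSING_TOKEN
                for v, m in zip(p.values, p.mask)
            ]
            writer.writerow([p.sample_id, label, *cells])


def read_profiles(path, panel: MarkerPanel) -> list[DeltaCqProfile]:
    """Read a wide ΔCq profile CSV whose marker columns match the panel."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if header[:2] != ["sample_id", "fluid_label"]:
            raise FormatError(
                f"{path}: first columns must be sample_id, fluid_label"
            )
        marker_cols = header[2:]
        if tuple(marker_cols) != panel.target_markers:
            raise FormatError(
                f"{path}: marker columns {marker_cols} do not match panel "
                f"targets {list(panel.target_markers)}"
            )
        profiles = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            sid = row["sample_id"].strip()
            if sid in seen:
                raise ValidationError(f"{path} line {lineno}: duplicate sample_id {sid!r}")
            seen.add(sid)
            label = _parse_label(row["fluid_label"], panel, f"{path} line {lineno}")
            values = np.full(panel.n_targets, np.nan)
            mask = np.zeros(panel.n_targets, dtype=bool)
            for j, marker in enumerate(panel.target_markers):
                token = row[marker].strip()
                if token in NON_DETECT_TOKENS:
                    continue
                values[j] = float(token)
                mask[j] = True
            profiles.append(
                DeltaCqProfile(sample_id=sid, values=values, mask=mask, fluid_label=label)
            )
    return profiles


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

_MODEL_FORMAT = "mirfluid-qda"


def save_model(model, path) -> None:
    """Serialize a trained QDA model to self-describing JSON text.

    Floats are written with Python's shortest round-trip ``repr``, so the
    save→load cycle reproduces every parameter bit-identically.
    """
    payload = {
        "format": _MODEL_FORMAT,
        "version": 1,
        "panel": model.panel.to_dict(),
        "classes": list(model.classes),
        "priors": [float(p) for p in model.priors],
        "ridge": float(model.ridge),
        "threshold": float(model.threshold),
        "components": {
            cls: {
                "mean": [float(v) for v in comp.mean],
                "covariance": [[float(v) for v in row] for row in comp.covariance],
            }
            for cls, comp in zip(model.classes, model.components)
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path):
    """Load a model written by :func:`save_model`, validating every block."""
    from .mvn import MVNParams
    from .qda import QDAModel

    with open(path, encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelLoadError(f"{path}: not valid JSON ({exc})") from exc
    if payload.get("format") != _MODEL_FORMAT:
        raise ModelLoadError(f"{path}: missing or wrong 'format' field")
    for key in ("panel", "classes", "priors", "ridge", "threshold", "components"):
        if key not in payload:
            raise ModelLoadError(f"{path}: missing field {key!r}")
    panel = MarkerPanel.from_dict(payload["panel"])
    classes = list(payload["classes"])
    components = []
    for cls in classes:
        block = payload["components"].get(cls)
        if block is None:
            raise ModelLoadError(f"{path}: missing component block for class {cls!r}")
        for key in ("mean", "covariance"):
            if key not in block:
                raise ModelLoadError(
                    f"{path}: component {cls!r} missing field {key!r}"
                )
        components.append(
            MVNParams(
                mean=np.asarray(block["mean"], dtype=float),
                covariance=np.asarray(block["covariance"], dtype=float),
            )
        )
    return QDAModel(
        panel=panel,
        classes=tuple(classes),
        components=tuple(components),
        priors=np.asarray(payload["priors"], dtype=float),
        ridge=float(payload["ridge"]),
        threshold=float(payload["threshold"]),
    )


# ---------------------------------------------------------------------------
# small report writers
# ---------------------------------------------------------------------------


def write_exclusion_report(exclusions: Sequence[tuple[str, str]], path) -> None:
    """Write (sample_id, reason) exclusion pairs as CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "reason"])
        writer.writerows(exclusions)
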