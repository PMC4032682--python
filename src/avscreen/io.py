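"""CSV / JSON / YAML I/O: measurement tables, feature tables, model persistence.

Schemas
-------
Measurements CSV (one row per subject-site, header mandatory, UTF-8, '.'
decimal, optional ``#``-prefixed provenance comment lines):

    subject_id,site,V_p_cm_s,V_m_cm_s,V_ed_cm_s,heart_rate_hz,D_H_mm[,dos,dos_class]

Features CSV:

    subject_id,ratio_A,ratio_L,ratio_V,res_A,res_L,res_V[,dos_class]

Classification CSV (hue printed to 4 d.p.):

    subject_id,H_deg,S,HC,predicted_class[,true_class]

Model file: versioned JSON with xi, the hue/error conventions and the
embedded training patterns, so load(save(m)) classifies identically to m.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cra import CRAModel, ColorResult, TrainingSet
from .exceptions import (
    DomainError,
    IncompleteSubjectError,
    MeasurementValidationError,
    SchemaError,
    SchemaVersionError,
)
from .hemodynamics import (
    DOSClass,
    FeaturePattern,
    FluidProperties,
    Site,
    SiteMeasurement,
    Subject,
)

__all__ = [
    "MODEL_SCHEMA_VERSION",
    "read_measurements",
    "write_measurements",
    "read_features",
    "write_features",
    "write_classification",
    "save_model",
    "load_model",
    "load_config",
    "provenance_header",
]

MODEL_SCHEMA_VERSION = 1

MEASUREMENT_COLUMNS = [
    "subject_id",
    "site",
    "V_p_cm_s",
    "V_m_cm_s",
    "V_ed_cm_s",
    "heart_rate_hz",
    "D_H_mm",
]
_REQUIRED_MEASUREMENT_COLUMNS = [c for c in MEASUREMENT_COLUMNS if c != "V_ed_cm_s"]

FEATURE_COLUMNS = [
    "subject_id",
    "ratio_A",
    "ratio_L",
    "ratio_V",
    "res_A",
    "res_L",
    "res_V",
]


def provenance_header(seed=None, config: Optional[Mapping] = None) -> str:
    """Comment header recording tool version, seed and a config digest."""
    lines = [f"# avscreen v{__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        lines.append(f"# config_sha256={digest}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def read_measurements(path) -> list[Subject]:
    """Read and validate a measurements CSV into complete subjects.

    Row-level constraint violations are collected (with 1-based data-row
    numbers) into one :class:`MeasurementValidationError`; a subject missing
    one of the A/L/V sites raises :class:`IncompleteSubjectError` naming it.
    """
    try:
        frame = pd.read_csv(path, comment="#", dtype={"subject_id": str})
    except (ValueError, OSError) as exc:
        raise SchemaError(f"cannot read measurements CSV {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"measurements CSV missing column(s): {', '.join(missing)}")

    row_errors: list[tuple[int, str]] = []
    measurements: dict[tuple[str, Site], SiteMeasurement] = {}
    labels: dict[str, tuple] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            site = Site(str(row.site))
        except ValueError:
            row_errors.append((i, f"unknown site {row.site!r}"))
            continue
        ved = getattr(row, "V_ed_cm_s", None)
        if ved is not None and pd.isna(ved):
            ved = None
        try:
            m = SiteMeasurement(
                subject_id=str(row.subject_id),
                site=site,
                V_p=float(row.V_p_cm_s),
                V_m=float(row.V_m_cm_s),
                heart_rate=float(row.heart_rate_hz),
                D_H=float(row.D_H_mm),
                V_ed=None if ved is None else float(ved),
            )
        except (DomainError, TypeError, ValueError) as exc:
            row_errors.append((i, str(exc)))
            continue
        key = (m.subject_id, m.site)
        if key in measurements:
            row_errors.append(
                (i, f"duplicate measurement for subject {key[0]!r} site {key[1].value}")
            )
            continue
        measurements[key] = m
        dos = getattr(row, "dos", None)
        dos_class = getattr(row, "dos_class", None)
        labels.setdefault(
            m.subject_id,
            (
                None if dos is None or pd.isna(dos) else float(dos),
                None if dos_class is None or pd.isna(dos_class) else DOSClass(str(dos_class)),
            ),
        )
    if row_errors:
        raise MeasurementValidationError(row_errors)

    subject_ids = list(dict.fromkeys(sid for sid, _ in measurements))
    incomplete = [
        sid
        for sid in subject_ids
        if any((sid, s) not in measurements for s in Site)
    ]
    if incomplete:
        raise IncompleteSubjectError(
            f"subject(s) missing a measurement site: {', '.join(incomplete)}"
        )
    subjects = []
    for sid in subject_ids:
        dos, dos_class = labels.get(sid, (None, None))
        subjects.append(
            Subject(
                subject_id=sid,
                sites={s: measurements[(sid, s)] for s in Site},
                dos_value=dos,
                dos_class=dos_class,
            )
        )
    return subjects


def write_measurements(
    subjects: Iterable[Subject],
    path,
    seed=None,
    config: Optional[Mapping] = None,
) -> None:
    """Write subjects to the measurements CSV with a provenance header."""
    rows = []
    for sub in subjects:
        for site in Site:
            m = sub.sites[site]
            rows.append(
                dict(
                    subject_id=m.subject_id,
                    site=site.value,
                    V_p_cm_s=m.V_p,
                    V_m_cm_s=m.V_m,
                    V_ed_cm_s=m.V_ed,
                    heart_rate_hz=m.heart_rate,
                    D_H_mm=m.D_H,
                    dos=sub.dos_value,
                    dos_class=None if sub.dos_class is None else sub.dos_class.value,
                )
            )
    frame = pd.DataFrame(rows)
    if frame["dos"].isna().all() and frame["dos_class"].isna().all():
        frame = frame.drop(columns=["dos", "dos_class"])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance_header(seed=seed, config=config))
        frame.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def write_features(
    patterns: Iterable[FeaturePattern],
    path,
    seed=None,
    config: Optional[Mapping] = None,
) -> None:
    rows = []
    for p in patterns:
        row = dict(zip(FEATURE_COLUMNS[1:], (float(v) for v in p.phi)))
        row = {"subject_id": p.subject_id, **row}
        row["dos_class"] = None if p.dos_class is None else p.dos_class.value
        rows.append(row)
    frame = pd.DataFrame(rows)
    if frame["dos_class"].isna().all():
        frame = frame.drop(columns=["dos_class"])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance_header(seed=seed, config=config))
        frame.to_csv(fh, index=False)


def read_features(path) -> list[FeaturePattern]:
    try:
        frame = pd.read_csv(path, comment="#", dtype={"subject_id": str})
    except (ValueError, OSError) as exc:
        raise SchemaError(f"cannot read features CSV {path}: {exc}") from exc
    missing = [c for c in FEATURE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"features CSV missing column(s): {', '.join(missing)}")
    patterns = []
    for row in frame.itertuples(index=False):
        dos_class = getattr(row, "dos_class", None)
        if dos_class is not None and pd.isna(dos_class):
            dos_class = None
        patterns.append(
            FeaturePattern(
                phi=np.array([getattr(row, c) for c in FEATURE_COLUMNS[1:]], dtype=float),
                dos_class=None if dos_class is None else DOSClass(str(dos_class)),
                subject_id=str(row.subject_id),
            )
        )
    return patterns


def write_classification(results: Iterable[ColorResult], path) -> None:
    """Classification output CSV; hue angle printed to 4 d.p."""
    rows = []
    any_true = False
    for r in results:
        rows.append(
            dict(
                subject_id=r.subject_id,
                H_deg=None if r.hue_H is None else f"{r.hue_H:.4f}",
                S=None if r.saturation_S is None else f"{r.saturation_S:.4f}",
                HC=None if r.H_C is None else f"{r.H_C:.6f}",
                predicted_class=(
                    "unclassifiable"
                    if r.predicted_class is None
                    else r.predicted_class.value
                ),
                true_class=None if r.true_class is None else r.true_class.value,
            )
        )
        any_true = any_true or r.true_class is not None
    frame = pd.DataFrame(rows)
    if not any_true:
        frame = frame.drop(columns=["true_class"])
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

def save_model(model: CRAModel, path) -> None:
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "xi": model.xi,
        "hue_branch_convention": model.hue_branch_convention,
        "error_mode": model.error_mode,
        "intensity_rescale": model.intensity_rescale,
        "patterns": [
            {
                "subject_id": p.subject_id,
                "phi": [float(v) for v in p.phi],
                "dos_class": p.dos_class.value,
                "dos_value": p.dos_value,
            }
            for p in model.training.patterns
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_model(path) -> CRAModel:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"cannot read model file {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"model schema version {version!r} unsupported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    for key in ("xi", "patterns"):
        if key not in payload:
            raise SchemaError(f"model file missing field {key!r}")
    patterns = tuple(
        FeaturePattern(
            phi=np.asarray(p["phi"], dtype=float),
            dos_class=DOSClass(p["dos_class"]),
            dos_value=p.get("dos_value"),
            subject_id=p.get("subject_id"),
        )
        for p in payload["patterns"]
    )
    return CRAModel(
        training=TrainingSet(patterns=patterns),
        xi=float(payload["xi"]),
        hue_branch_convention=payload.get("hue_branch_convention", "class_centered"),
        error_mode=payload.get("error_mode", "wrapped"),
        intensity_rescale=bool(payload.get("intensity_rescale", False)),
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML or JSON run configuration (equivalent trees)."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"cannot parse config {path}: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise SchemaError("config root must be a mapping")
    return data


def fluid_from_config(cfg: Mapping) -> FluidProperties:
    block = cfg.get("fluid", {})
    return FluidProperties(
        density=float(block.get("density", 1055.0)),
        dynamic_viscosity_mu=float(block.get("dynamic_viscosity_mu", 0.01063)),
        hematocrit=float(block.get("hematocrit", 0.40)),
    )
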