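"""File formats and packaged reference tables.

* Endpoint tables — the long CSV dialect (``patient, course,
  structure, V100, D98, Dmax, Dmean, D0.03cc``) with ``–`` marking an
  absent value.  The packaged fixtures transcribe the published
  endpoint tables verbatim, printed glyphs included (en-dash missing
  markers, Unicode minus signs); readers normalize them to ASCII.
* Scorecard tables — the wide CSV dialect with one column per
  criterion plus the total.
* Scoring functions and course manifests — JSON.
* Dose and mask grids — NRRD via SimpleITK.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .grids import DoseGrid, StructureMask, TARGET_STRUCTURES
from .dvh import ENDPOINT_COLUMNS
from .scoring import (
    AnyScoringFunction,
    CRITERIA,
    ScoringFunction,
    SerialOrganScore,
)

__all__ = [
    "MISSING_MARKER",
    "COURSE_LABELS",
    "EndpointTableError",
    "read_endpoint_table",
    "write_endpoint_table",
    "read_scorecard_table",
    "write_scorecard_table",
    "load_endpoint_fixture",
    "load_scorecard_fixture",
    "save_scoring_functions",
    "load_scoring_functions",
    "default_scoring_functions",
    "read_nrrd",
    "write_nrrd",
    "read_mask_nrrd",
    "write_mask_nrrd",
    "RunConfig",
]

log = logging.getLogger("aptqa")

MISSING_MARKER = "–"  # en dash, as printed
COURSE_LABELS = ("nominal", "offline", "online", "online-f")

# printed glyph -> ASCII
_GLYPHS = {"−": "-", "‐": "-", "‒": "-", "–": "-", "—": "-"}


class EndpointTableError(ValueError):
    """A malformed endpoint or scorecard table row."""


def _normalize_cell(raw: object) -> float:
    """Parse one numeric cell, normalizing printed minus/dash glyphs;
    a bare dash of any flavour is the missing marker."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    text = str(raw).strip()
    if text == "" or text in _GLYPHS or text == "-":
        return np.nan
    for glyph, ascii_ in _GLYPHS.items():
        text = text.replace(glyph, ascii_)
    return float(text)


def _parse_numeric(df: pd.DataFrame, columns: list[str], path: object) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        parsed = []
        for i, raw in enumerate(df[col]):
            try:
                parsed.append(_normalize_cell(raw))
            except ValueError:
                raise EndpointTableError(
                    f"{path}: row {i + 2}: cannot parse {col}={raw!r}"
                ) from None
        df[col] = parsed
    return df


def read_endpoint_table(path) -> pd.DataFrame:
    """Read a long endpoint table; missing markers become NaN.

    An empty file yields an empty table.  Unknown course labels and
    non-numeric cells raise :class:`EndpointTableError` naming the row.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["patient", "course", "structure"] + ENDPOINT_COLUMNS)
    expected = ["patient", "course", "structure"] + ENDPOINT_COLUMNS
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise EndpointTableError(f"{path}: missing columns {missing_cols}")
    for i, course in enumerate(df["course"]):
        if course not in COURSE_LABELS:
            raise EndpointTableError(f"{path}: row {i + 2}: unknown course label {course!r}")
    df = _parse_numeric(df, ENDPOINT_COLUMNS, path)
    df["patient"] = df["patient"].astype(int)
    return df[expected]


def write_endpoint_table(df: pd.DataFrame, path) -> None:
    """Write the long dialect, marking absent values with the printed
    en-dash so tables round-trip against the packaged fixtures."""
    out = df.copy()
    for col in ENDPOINT_COLUMNS:
        out[col] = [
            MISSING_MARKER if pd.isna(v) else f"{v:g}" for v in out[col]
        ]
    out.to_csv(path, index=False)


_SCORE_COLUMNS = [c for c, _, _ in CRITERIA] + ["total"]


def read_scorecard_table(path) -> pd.DataFrame:
    """Read the wide scorecard dialect (one criterion per column)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    present = [c for c in _SCORE_COLUMNS if c in df.columns]
    df = _parse_numeric(df, present, path)
    df["patient"] = df["patient"].astype(int)
    return df


def write_scorecard_table(df: pd.DataFrame, path, ndigits: int = 1) -> None:
    out = df.copy()
    for col in _SCORE_COLUMNS:
        if col in out.columns:
            out[col] = [
                MISSING_MARKER if pd.isna(v) else f"{round(float(v), ndigits):.{ndigits}f}"
                for v in out[col]
            ]
    out.to_csv(path, index=False)


def _fixture(name: str):
    return resources.files("aptqa.data").joinpath(name)


def load_endpoint_fixture(which: str = "cohort") -> pd.DataFrame:
    """Packaged endpoint tables: ``cohort`` (10 patients x 3 courses)
    or ``finetuned`` (the patient-5 fine-tuning comparison)."""
    name = {"cohort": "endpoints_cohort.csv", "finetuned": "endpoints_finetuned.csv"}[which]
    with resources.as_file(_fixture(name)) as p:
        return read_endpoint_table(p)


def load_scorecard_fixture(which: str = "cohort") -> pd.DataFrame:
    """Packaged published scorecards matching the endpoint fixtures."""
    name = {"cohort": "scores_cohort.csv", "finetuned": "scores_finetuned.csv"}[which]
    with resources.as_file(_fixture(name)) as p:
        return read_scorecard_table(p)


def save_scoring_functions(fns: Mapping[str, AnyScoringFunction], path) -> None:
    doc = {"score_cap": 7.0, "functions": {k: f.as_dict() for k, f in fns.items()}}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_scoring_functions(path_or_file) -> dict[str, AnyScoringFunction]:
    if hasattr(path_or_file, "read"):
        doc = json.load(path_or_file)
    else:
        doc = json.loads(Path(path_or_file).read_text())
    out: dict[str, AnyScoringFunction] = {}
    for key, spec in doc["functions"].items():
        kind = spec.pop("type")
        if kind == "piecewise":
            out[key] = ScoringFunction(**spec)
        elif kind == "serial":
            out[key] = SerialOrganScore(**spec)
        else:
            raise ValueError(f"unknown scoring function type {kind!r}")
    return out


def default_scoring_functions() -> dict[str, AnyScoringFunction]:
    """The shipped scoring-function set, calibrated from the packaged
    endpoint/score tables by ``scripts/calibrate_defaults.py``."""
    with resources.as_file(_fixture("scoring_functions.json")) as p:
        return load_scoring_functions(p)


# ---------------------------------------------------------------------------
# NRRD grids (SimpleITK stores arrays z-major; our arrays are x-major)


def write_nrrd(grid: DoseGrid, path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(grid.spacing))
    img.SetOrigin(tuple(grid.origin))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_nrrd(path) -> DoseGrid:
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return DoseGrid(values, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def write_mask_nrrd(mask: StructureMask, grid: DoseGrid, path) -> None:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(mask.mask.astype(np.uint8).transpose(2, 1, 0))
    )
    img.SetSpacing(tuple(grid.spacing))
    img.SetOrigin(tuple(grid.origin))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_mask_nrrd(path, name: str, role: str | None = None) -> StructureMask:
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(bool)
    if role is None:
        role = "target" if name in TARGET_STRUCTURES else "oar"
    return StructureMask(name, values, role=role)


# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Resolved configuration of one artifact-producing run; fully
    serializable so every run can log a config hash alongside its
    seeds."""

    command: str
    seed: int | None = None
    goals_source: str = "builtin"
    functions_source: str = "packaged"
    drop_threshold: float = 3.0
    qact_interval: int = 10
    replan_lag: int = 5
    online_margin_mm: float = 1.5
    offline_margin_mm: float = 3.0
    n_fractions: int | None = None
    output: str | None = None
    rounding: int = 1
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @property
    def config_hash(self) -> str:
        # the output path is where results land, not what they are
        doc = {k: v for k, v in asdict(self).items() if k != "output"}
        payload = json.dumps(doc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def log(self) -> None:
        from . import __version__

        log.info(
            "aptqa %s | command=%s | config=%s | seed=%s",
            __version__,
            self.command,
            self.config_hash,
            self.seed,
        )
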