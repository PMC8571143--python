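"""Cell-table I/O, threshold scoring, and phenotype assignment.

Cells live in a pandas DataFrame, one row per segmented cell, with columns

    cell_id, core_id, patient_id, x_um, y_um,
    "<MARKER>:nucleus" / "<MARKER>:membrane"   (median intensities)

Scoring adds one boolean column per marker named ``<MARKER>+`` and phenotype
assignment adds a ``phenotype`` string column. A single file may hold many
cores; ``core_id`` groups rows.

Scoring rule: a marker is positive when the median intensity on its
designated compartment (nucleus for FOXP3, membrane for the others) is
greater than or equal to the marker's threshold. The boundary is closed
(``>=``) and intensities on the other compartment are ignored. DAPI is
positive for every segmented cell by construction.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, StateError, ValidationError
from .panel import MarkerPanel
from .phenotypes import CD21_ONLY, DAPI_ONLY

log = logging.getLogger(__name__)

ID_COLUMNS = ("cell_id", "core_id", "patient_id", "x_um", "y_um")
_REQUIRED_META = ("core_id", "x_um", "y_um")


def positivity_column(marker: str) -> str:
    return f"{marker}+"


def read_cell_table(path: str | Path, panel: MarkerPanel) -> pd.DataFrame:
    """Read a cell table CSV and validate it against the panel.

    Requires ``core_id``, ``x_um``, ``y_um`` and the designated-compartment
    intensity column for every scored marker. Unknown columns are kept but
    noted in the log. Negative intensities raise with the offending row.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED_META if c not in df.columns]
    missing += [c for c in panel.required_columns() if c not in df.columns]
    if missing:
        raise FormatError(
            f"cell table {path}: missing required column(s) {', '.join(missing)}"
        )
    known = set(ID_COLUMNS) | {
        f"{m}:{c}" for m in panel.markers for c in ("nucleus", "membrane")
    } | {positivity_column(m) for m in panel.markers} | {"phenotype"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        log.info("cell table %s: ignoring unknown column(s) %s", path, unknown)
    intensity_cols = [c for c in df.columns if ":" in c and c in known]
    for col in intensity_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0])
            raise ValidationError(f"column {col!r}: non-numeric value at row {row}")
        if (vals < 0).any():
            row = int(np.flatnonzero(vals.to_numpy() < 0)[0])
            raise ValidationError(f"column {col!r}: negative intensity at row {row}")
        df[col] = vals.astype(float)
    if not np.isfinite(df[["x_um", "y_um"]].to_numpy(float)).all():
        raise ValidationError("x_um/y_um must be finite")
    return df


def write_cell_table(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    """Write a cell table CSV, optionally preceded by ``#`` metadata lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def score_cells(cells: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Apply per-marker thresholds; returns a copy with ``<MARKER>+`` columns.

    Idempotent: re-scoring an already-scored table overwrites the calls with
    identical values.
    """
    out = cells.copy()
    for marker in panel.scored_markers:
        col = panel.intensity_column(marker)
        if col not in out.columns:
            raise ValidationError(f"missing intensity column {col!r} for scoring")
        vals = out[col].to_numpy(float)
        if np.isnan(vals).any():
            raise ValidationError(f"missing intensity value(s) in column {col!r}")
        out[positivity_column(marker)] = vals >= float(panel.threshold_of[marker])
    if "DAPI" in panel.markers:
        # segmentation is DAPI-driven: every segmented cell carries a nucleus
        out[positivity_column("DAPI")] = True
    return out


def assign_phenotypes(cells: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Assign one phenotype label per scored cell (vectorised).

    The label is the positivity combination code over the phenotyping
    markers; all-negative cells become ``DAPI_ONLY`` or, if CD21-positive,
    ``CD21_ONLY``.
    """
    pos_cols = [positivity_column(m) for m in panel.phenotyping_markers]
    for c in pos_cols:
        if c not in cells.columns:
            raise StateError("cells must be scored before phenotype assignment")
    out = cells.copy()
    flags = out[pos_cols].to_numpy(bool)
    parts = np.empty(flags.shape, dtype=object)
    for j, m in enumerate(panel.phenotyping_markers):
        parts[:, j] = np.where(flags[:, j], f"{m}+", f"{m}-")
    codes = np.array(["".join(row) for row in parts], dtype=object)
    none_positive = ~flags.any(axis=1)
    cd21_col = positivity_column("CD21")
    cd21 = (
        out[cd21_col].to_numpy(bool)
        if cd21_col in out.columns
        else np.zeros(len(out), bool)
    )
    codes[none_positive & cd21] = CD21_ONLY
    codes[none_positive & ~cd21] = DAPI_ONLY
    out["phenotype"] = codes
    return out
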