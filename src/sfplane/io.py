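"""Readers and writers for the plain-text formats the toolkit exchanges.

Time series are delimited numeric tables (timepoints x ROIs), connectivity
matrices are N x N CSVs with a JSON sidecar carrying metadata, and phenotypes
are headed CSVs. Delimiters are sniffed among comma / tab / whitespace.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CONNECTIVITY_KINDS,
    ConnectivityMatrix,
    ParseError,
    PhenotypeTable,
    SubjectTimeSeries,
    ValidationError,
)

_MISSING_TOKENS = {"nan", "na", "n/a", "null", ""}


def _sniff_split(line: str) -> list[str]:
    if "," in line:
        return [tok.strip() for tok in line.split(",")]
    if "\t" in line:
        return [tok.strip() for tok in line.split("\t")]
    return line.split()


def _is_numeric(token: str) -> bool:
    if token.strip().lower() in _MISSING_TOKENS:
        return False
    try:
        float(token)
    except ValueError:
        return False
    return True


def _parse_numeric_table(path: Path) -> np.ndarray:
    """Parse a delimited numeric table, rejecting ragged rows and missing cells."""
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    rows = [_sniff_split(ln) for ln in lines]
    start = 0
    if any(not _is_numeric(tok) for tok in rows[0]):
        # header row: every later row must be fully numeric
        start = 1
        if len(rows) == 1:
            raise ParseError(f"{path}: only a header row, no data")
    width = len(rows[start])
    data = np.empty((len(rows) - start, width))
    for r, row in enumerate(rows[start:], start=start):
        if len(row) != width:
            raise ParseError(
                f"{path}: ragged table — row {r + 1} has {len(row)} cells, expected {width}"
            )
        for c, tok in enumerate(row):
            if not _is_numeric(tok):
                raise ParseError(
                    f"{path}: non-numeric cell {tok!r} at row {r + 1}, column {c + 1}"
                )
            val = float(tok)
            if not np.isfinite(val):
                raise ParseError(
                    f"{path}: non-finite cell {tok!r} at row {r + 1}, column {c + 1}"
                )
            data[r - start, c] = val
    return data


def read_time_series(path, subject_id: str, tr: float) -> SubjectTimeSeries:
    """Load one subject's ROI time series from a delimited text table.

    The table is timepoints x ROIs; an optional header row (any non-numeric
    first row) is auto-detected and stripped.
    """
    data = _parse_numeric_table(Path(path))
    return SubjectTimeSeries(subject_id=subject_id, values=data, tr=tr)


def read_phenotypes(path, allow_repeated_subjects: bool = False) -> PhenotypeTable:
    """Load a phenotype CSV (header required; subject_id and site mandatory)."""
    df = pd.read_csv(path)
    return PhenotypeTable(df, allow_repeated_subjects=allow_repeated_subjects)


def write_phenotypes(phen: PhenotypeTable, path) -> None:
    phen.data.to_csv(path, index=False)


def write_connectivity_matrix(m: ConnectivityMatrix, path) -> None:
    """Persist a connectivity matrix as CSV plus a ``.json`` sidecar."""
    path = Path(path)
    np.savetxt(path, m.weights, delimiter=",", fmt="%.12g")
    sidecar = {"subject_id": m.subject_id, "kind": m.kind, "n_rois": m.n_rois}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_connectivity_matrix(path) -> ConnectivityMatrix:
    """Load a matrix written by :func:`write_connectivity_matrix`.

    Without a sidecar the subject id falls back to the file stem and the kind
    to ``pearson`` (the SRPBS-style precomputed-matrix convention).
    """
    path = Path(path)
    weights = _parse_numeric_table(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        subject_id = str(meta.get("subject_id", path.stem))
        kind = meta.get("kind", "pearson")
        if kind not in CONNECTIVITY_KINDS:
            raise ValidationError(f"{sidecar_path}: unknown kind {kind!r}")
    else:
        subject_id, kind = path.stem, "pearson"
    return ConnectivityMatrix(subject_id=subject_id, weights=weights, kind=kind)


def write_time_series(ts: SubjectTimeSeries, path) -> None:
    np.savetxt(Path(path), ts.values, delimiter=",", fmt="%.10g")
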