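"""CSV readers/writers and bundled example data.

The dialect is fixed: UTF-8, comma-delimited, dot decimal separator.  The
first row and first column carry labels; cell (i, j) of a pairwise file is
the judgment of the row criterion over the column criterion, and a decision
file may carry an optional ``OV`` row with user-chosen optimal values.
Parsing errors report row/column coordinates.
"""

from __future__ import annotations

import csv
import hashlib
import io as _io
import json
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .aras import build_decision_matrix
from .ahp import validate_pairwise
from .errors import ParseError
from .types import CriterionSpec, DecisionMatrix, PairwiseMatrix, WeightVector

OPTIMAL_ROW_LABEL = "OV"


def _read_labeled_grid(path) -> tuple[np.ndarray, list[str], list[str]]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r and any(c.strip() for c in r)]
    if len(rows) < 2:
        raise ParseError(f"{path}: expected a header row and at least one data row")
    header = [c.strip() for c in rows[0]]
    col_labels = header[1:]
    if not col_labels or any(not c for c in col_labels):
        raise ParseError(f"{path}: header must name every column")
    width = len(header)
    row_labels: list[str] = []
    values: list[list[float]] = []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ParseError(
                f"{path}: row {r} has {len(row)} fields, expected {width} (ragged row)"
            )
        label = row[0].strip()
        if not label:
            raise ParseError(f"{path}: row {r} is missing its label")
        parsed = []
        for c, cell in enumerate(row[1:], start=2):
            try:
                parsed.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell at row {r}, column {c} "
                    f"({label!r}, {col_labels[c - 2]!r}): {cell!r}"
                ) from None
        row_labels.append(label)
        values.append(parsed)
    return np.array(values, dtype=float), row_labels, col_labels


def read_matrix_csv(path, kind: str = "pairwise"):
    """Read a labeled matrix CSV.

    kind='pairwise' returns ``(grid, labels)`` after checking that row and
    column labels agree.  kind='decision' returns
    ``(scores, alternatives, criterion_labels, optimal_row_or_None)``,
    splitting off an optional ``OV`` row.
    """
    grid, row_labels, col_labels = _read_labeled_grid(path)
    if kind == "pairwise":
        if row_labels != col_labels:
            raise ParseError(
                f"{path}: pairwise row labels {row_labels} differ from "
                f"column labels {col_labels}"
            )
        return grid, col_labels
    if kind == "decision":
        optimal = None
        keep = np.ones(len(row_labels), dtype=bool)
        for i, lab in enumerate(row_labels):
            if lab.upper() == OPTIMAL_ROW_LABEL:
                if optimal is not None:
                    raise ParseError(f"{path}: more than one {OPTIMAL_ROW_LABEL} row")
                optimal = grid[i]
                keep[i] = False
        alternatives = [lab for lab, k in zip(row_labels, keep) if k]
        return grid[keep], alternatives, col_labels, optimal
    raise ParseError(f"unknown matrix kind {kind!r}")


def load_pairwise_csv(path, **validate_kwargs) -> PairwiseMatrix:
    grid, labels = read_matrix_csv(path, kind="pairwise")
    return validate_pairwise(grid, labels, **validate_kwargs)


def load_decision_csv(
    path, directions: Sequence[str] | None = None, use_file_optimal_row: bool = True
) -> DecisionMatrix:
    scores, alternatives, labels, optimal = read_matrix_csv(path, kind="decision")
    if directions is not None:
        if len(directions) != len(labels):
            raise ParseError(
                f"{path}: {len(directions)} directions supplied for {len(labels)} criteria"
            )
        criteria = [CriterionSpec(l, direction=d) for l, d in zip(labels, directions)]
    else:
        criteria = labels
    return build_decision_matrix(
        scores,
        alternatives=alternatives,
        criteria=criteria,
        optimal_row=optimal if use_file_optimal_row else None,
    )


def matrix_to_csv_text(grid, row_labels, col_labels, corner: str = "") -> str:
    """Canonical CSV text for a labeled grid (used for files and digests)."""
    grid = np.asarray(grid, dtype=float)
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow([corner, *col_labels])
    for lab, row in zip(row_labels, grid):
        writer.writerow([lab, *(repr(float(v)) for v in row)])
    return buf.getvalue()


def write_matrix_csv(path, grid, row_labels, col_labels, corner: str = "") -> None:
    Path(path).write_text(
        matrix_to_csv_text(grid, row_labels, col_labels, corner), encoding="utf-8"
    )


def write_pairwise_csv(path, m: PairwiseMatrix) -> None:
    write_matrix_csv(path, m.entries, m.labels, m.labels, corner="Criteria")


def write_decision_csv(path, d: DecisionMatrix, include_optimal_row: bool = True) -> None:
    rows = list(d.alternatives)
    grid = d.scores
    if include_optimal_row:
        rows.append(OPTIMAL_ROW_LABEL)
        grid = np.vstack([d.scores, d.optimal_row])
    write_matrix_csv(path, grid, rows, d.criterion_labels, corner="Alternatives")


def matrix_digest(grid, row_labels, col_labels) -> str:
    """SHA-256 of the canonical CSV serialization of a labeled grid."""
    text = matrix_to_csv_text(grid, row_labels, col_labels)
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def read_weights(path) -> WeightVector:
    """Read weights from an AHP report JSON or a two-column criterion,weight CSV."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text(encoding="utf-8"))
        try:
            return WeightVector(tuple(data["criteria"]), np.asarray(data["weights"], float))
        except KeyError as e:
            raise ParseError(f"{path}: weight report missing key {e}") from None
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r and any(c.strip() for c in r)]
    labels, values = [], []
    for r, row in enumerate(rows, start=1):
        if len(row) != 2:
            raise ParseError(f"{path}: row {r} must have exactly 2 fields")
        try:
            values.append(float(row[1]))
        except ValueError:
            if r == 1:
                continue  # header row
            raise ParseError(f"{path}: non-numeric weight at row {r}: {row[1]!r}") from None
        labels.append(row[0].strip())
    return WeightVector(tuple(labels), np.asarray(values, float))


def write_weights_csv(path, w: WeightVector) -> None:
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["criterion", "weight"])
    for c, v in zip(w.criteria, w.weights):
        writer.writerow([c, repr(float(v))])
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Bundled example study: evaluation of eight computer-based health-monitoring
# applications against eight benefit criteria (real-time ability, dynamic
# nature, surgical services, data security, telecommunication, disease
# monitoring, usability, convenience).

HEALTH_APPS_CRITERIA = (
    CriterionSpec("C1", "real-time ability"),
    CriterionSpec("C2", "dynamic nature"),
    CriterionSpec("C3", "surgical services"),
    CriterionSpec("C4", "data security"),
    CriterionSpec("C5", "telecommunication"),
    CriterionSpec("C6", "disease monitoring"),
    CriterionSpec("C7", "usability"),
    CriterionSpec("C8", "convenient"),
)


def example_data_path(name: str):
    """Path-like handle to a bundled example CSV (inside the installed package)."""
    return resources.files("mcda.data").joinpath(name)


def load_health_apps_study() -> tuple[PairwiseMatrix, DecisionMatrix]:
    """The bundled case study: expert pairwise judgments and 1-9 performance
    scores for eight health-monitoring applications."""
    with resources.as_file(example_data_path("health_apps_pairwise.csv")) as p:
        grid, labels = read_matrix_csv(p, kind="pairwise")
    pairwise = validate_pairwise(grid, HEALTH_APPS_CRITERIA)
    with resources.as_file(example_data_path("health_apps_decision.csv")) as p:
        scores, alternatives, clabels, optimal = read_matrix_csv(p, kind="decision")
    decision = build_decision_matrix(
        scores, alternatives=alternatives, criteria=HEALTH_APPS_CRITERIA
    )
    return pairwise, decision
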