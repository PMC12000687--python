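"""CSV formats: response matrices, target scores, and the weights table.

The weights table is the spreadsheet-facing export: one row per retained
item with a weight column per dimension, plus a final ``(intercept)`` row.
A predicted score is just ``sum(item value × weight) + intercept``, so the
file can be used to score participants with no code at all. Excluded items
are omitted — their weight is implicitly zero. Metadata (original item
count, target kind, alphas, seed, version) travels in ``#``-prefixed header
comment lines.

All CSVs are comma-delimited UTF-8 with a period decimal separator.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .reducer import ReducedModel, predict
from .targets import TargetScores

__all__ = [
    "read_responses",
    "write_responses",
    "read_targets",
    "write_targets",
    "export_weights",
    "read_weights",
    "predict_from_weights",
]

INTERCEPT_LABEL = "(intercept)"


def read_responses(path: str | Path) -> pd.DataFrame:
    """Read a participants × items response CSV.

    The header row must hold unique item identifiers; cells must be numeric
    (blank cells become missing values, rejected downstream unless
    imputation is requested). Errors carry row/column coordinates.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: file is empty") from None
        seen: dict[str, int] = {}
        for col in header:
            seen[col] = seen.get(col, 0) + 1
        dupes = [c for c, k in seen.items() if k > 1]
        if dupes:
            raise ValueError(f"{path}: duplicate item identifiers in header: {dupes}")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: row {lineno} has {len(row)} cells, expected {len(header)}"
                )
            parsed = []
            for col, cell in zip(header, row):
                cell = cell.strip()
                if cell == "":
                    parsed.append(np.nan)
                    continue
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at row {lineno}, column {col!r}"
                    ) from None
            rows.append(parsed)
    frame = pd.DataFrame(rows, columns=header)
    # keep integer dtype when the data allow it (Likert codes round-trip)
    if len(frame) and not frame.isna().any().any():
        as_int = frame.astype(np.int64, errors="ignore")
        if as_int.dtypes.eq(np.int64).all() and (as_int == frame).all().all():
            frame = as_int
    return frame


def write_responses(responses: pd.DataFrame, path: str | Path) -> None:
    responses.to_csv(path, index=False)


def read_targets(path: str | Path, kind: str = "sum") -> TargetScores:
    frame = read_responses(path)  # same validation rules apply
    return TargetScores(values=frame.astype(float), kind=kind)


def write_targets(targets: TargetScores, path: str | Path) -> None:
    targets.values.to_csv(path, index=False)


def export_weights(model: ReducedModel, path: str | Path, seed: int | None = None) -> None:
    """Write the spreadsheet-oriented weights CSV for a fitted model."""
    path = Path(path)
    dims = model.dimension_names
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# shortform weights table (version {__version__})\n")
        fh.write(f"# n_items_total: {model.n_items_total}\n")
        fh.write(f"# target_kind: {model.target_kind}\n")
        alphas = ",".join(f"{d}={a!r}" for d, a in model.alphas_used.items())
        fh.write(f"# alphas: {alphas}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        writer = csv.writer(fh)
        writer.writerow(["item", *dims])
        for item in model.included_items:
            writer.writerow([item, *(repr(float(w)) for w in model.weights.loc[item])])
        writer.writerow([INTERCEPT_LABEL, *(repr(float(b)) for b in model.intercepts)])


def read_weights(path: str | Path) -> ReducedModel:
    """Reconstruct a model from a weights CSV written by :func:`export_weights`."""
    path = Path(path)
    meta: dict[str, str] = {}
    body: list[list[str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    key, _, value = stripped.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            body.append(next(csv.reader([line])))
    if not body:
        raise ValueError(f"{path}: no weight rows found")
    header = body[0]
    if header[0] != "item" or len(header) < 2:
        raise ValueError(f"{path}: malformed weights header {header}")
    dims = header[1:]
    items, weights, intercepts = [], [], None
    for row in body[1:]:
        if row[0] == INTERCEPT_LABEL:
            if intercepts is not None:
                raise ValueError(f"{path}: multiple intercept rows")
            intercepts = [float(v) for v in row[1:]]
        else:
            items.append(row[0])
            weights.append([float(v) for v in row[1:]])
    if intercepts is None:
        raise ValueError(f"{path}: missing {INTERCEPT_LABEL} row")
    return ReducedModel(
        included_items=items,
        weights=pd.DataFrame(weights, index=items, columns=dims),
        intercepts=pd.Series(intercepts, index=dims),
        alphas_used=pd.Series(np.nan, index=dims),
        n_items_total=int(meta.get("n_items_total", len(items))),
        target_kind=meta.get("target_kind", "sum"),
    )


def predict_from_weights(weights_path: str | Path, responses_path: str | Path) -> pd.DataFrame:
    """Score a response CSV with an exported weights table.

    Equivalent to loading the model and calling ``predict``; responses may
    carry extra item columns, which are ignored.
    """
    model = read_weights(weights_path)
    responses = read_responses(responses_path)
    return predict(model, responses).values
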