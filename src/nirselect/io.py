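"""Reading and writing the package's file formats.

Spectral CSV dialect: a header row ``concentration,<wn1>,<wn2>,...`` with
wavenumbers in cm^-1 as column names, then one row per sample whose first
cell is the analyte concentration (fraction).  Values are written with 12
significant digits, which makes write -> read -> write byte-stable.

Selection results and evaluation reports are serialised as JSON; a
selection CSV lists per-variable channel index, wavenumber and the
evaluation-index components where available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synthetic import SpectralDataset

__all__ = ["read_dataset", "write_dataset", "write_selection_csv", "write_json"]

_FMT = "%.12g"


def write_dataset(dataset: SpectralDataset, path: str | Path) -> None:
    """Write a dataset in the spectral CSV dialect (12 significant digits)."""
    path = Path(path)
    header = "concentration," + ",".join(_FMT % w for w in dataset.wavenumbers)
    lines = [header]
    for yi, row in zip(dataset.y, dataset.X):
        lines.append(_FMT % yi + "," + ",".join(_FMT % v for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_dataset(path: str | Path) -> SpectralDataset:
    """Parse a spectral CSV file into a :class:`SpectralDataset`.

    Rejects ragged rows, non-numeric or missing cells, and duplicate
    wavenumbers, naming the offending row/column.  Wavenumber order is
    preserved as written.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header and at least one sample row")
    header = lines[0].split(",")
    if header[0].strip().lower() != "concentration":
        raise ValueError(
            f"{path}: first header column must be 'concentration', got {header[0]!r}"
        )
    try:
        wavenumbers = np.array([float(c) for c in header[1:]], dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavenumber in header: {exc}") from exc
    if wavenumbers.size < 1:
        raise ValueError(f"{path}: no wavenumber columns")
    if np.unique(wavenumbers).size != wavenumbers.size:
        raise ValueError(f"{path}: duplicate wavenumbers in header")
    n_cols = len(header)
    y = np.empty(len(lines) - 1)
    X = np.empty((len(lines) - 1, wavenumbers.size))
    for r, line in enumerate(lines[1:], start=2):
        cells = line.split(",")
        if len(cells) != n_cols:
            raise ValueError(
                f"{path}: row {r} has {len(cells)} cells, expected {n_cols}"
            )
        for c, cell in enumerate(cells):
            if cell.strip() == "":
                raise ValueError(f"{path}: missing cell at row {r}, column {c + 1}")
            try:
                val = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {r}, column {c + 1}"
                ) from None
            if c == 0:
                y[r - 2] = val
            else:
                X[r - 2, c - 1] = val
    return SpectralDataset(X, wavenumbers, y)


def write_selection_csv(
    path: str | Path,
    variables: np.ndarray,
    wavenumbers: np.ndarray,
    ei=None,
    final_set: np.ndarray | None = None,
) -> None:
    """Selection CSV: channel index, wavenumber, and EI columns if present."""
    variables = np.asarray(variables, dtype=int)
    final = set() if final_set is None else set(int(v) for v in final_set)
    rows = ["index,wavenumber,alpha,p,b,w,rank,selected"]
    if ei is not None:
        order = np.lexsort((ei.variables, -ei.alpha, -ei.w))
        rank_of = {int(ei.variables[j]): r + 1 for r, j in enumerate(order)}
        comp = {
            int(v): (ei.alpha[i], ei.purity[i], ei.b[i], ei.w[i])
            for i, v in enumerate(ei.variables)
        }
    for v in variables:
        v = int(v)
        if ei is not None and v in comp:
            a, p, b, w = comp[v]
            rows.append(
                f"{v},{_FMT % wavenumbers[v]},{_FMT % a},{_FMT % p},{_FMT % b},"
                f"{_FMT % w},{rank_of[v]},{int(v in final or final_set is None)}"
            )
        else:
            rows.append(f"{v},{_FMT % wavenumbers[v]},,,,,,1")
    Path(path).write_text("\n".join(rows) + "\n")


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON serialisation (sorted keys, stable float repr)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
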