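"""Tab-separated file formats for architectures, secretion data and curves.

Architecture files: header ``cell_id\tcell_type\tx_um\ty_um\tz_um``, one row
per cell, coordinates in decimal um (written to 6 decimal places).
Secretion files: header ``group_id\tinsulin_content_nmol\tglucagon\t
somatostatin``. Ablation-curve exports report the deleted fraction as a
percentage to mirror the conventional axis of connectivity-decay plots.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .ablation import AblationCurve
from .synthetic import CELL_TYPES, IsletArchitecture

ARCH_COLUMNS = ["cell_id", "cell_type", "x_um", "y_um", "z_um"]
SECRETION_COLUMNS = ["group_id", "insulin_content_nmol", "glucagon", "somatostatin"]


class FileFormatError(ValueError):
    """Malformed input file; the message names the offending line."""


def write_architecture(arch: IsletArchitecture, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ARCH_COLUMNS)
        for row in arch.cells.itertuples(index=False):
            w.writerow(
                [
                    int(row.cell_id),
                    row.cell_type,
                    f"{row.x_um:.6f}",
                    f"{row.y_um:.6f}",
                    f"{row.z_um:.6f}",
                ]
            )


def read_architecture(path, islet_id: str | None = None) -> IsletArchitecture:
    """Read an architecture table, validating schema row by row.

    Raises :class:`FileFormatError` naming the 1-based line number of the
    first malformed row (wrong field count, unknown cell type, non-numeric or
    non-finite coordinate, duplicate cell id).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FileFormatError(f"{path}: empty file") from None
        if header != ARCH_COLUMNS:
            raise FileFormatError(
                f"{path}: line 1: expected header {ARCH_COLUMNS}, got {header}"
            )
        ids: list[int] = []
        types: list[str] = []
        coords: list[tuple[float, float, float]] = []
        seen: set[int] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise FileFormatError(
                    f"{path}: line {lineno}: expected 5 fields, got {len(row)}"
                )
            try:
                cid = int(row[0])
            except ValueError:
                raise FileFormatError(
                    f"{path}: line {lineno}: cell_id {row[0]!r} is not an integer"
                ) from None
            if cid in seen:
                raise FileFormatError(
                    f"{path}: line {lineno}: duplicate cell_id {cid}"
                )
            if row[1] not in CELL_TYPES:
                raise FileFormatError(
                    f"{path}: line {lineno}: unknown cell_type {row[1]!r}"
                )
            try:
                xyz = tuple(float(v) for v in row[2:5])
            except ValueError:
                raise FileFormatError(
                    f"{path}: line {lineno}: non-numeric coordinate in {row[2:5]}"
                ) from None
            if not all(np.isfinite(xyz)):
                raise FileFormatError(
                    f"{path}: line {lineno}: non-finite coordinate"
                )
            seen.add(cid)
            ids.append(cid)
            types.append(row[1])
            coords.append(xyz)
    if not ids:
        raise FileFormatError(f"{path}: no cell rows")
    arr = np.asarray(coords)
    cells = pd.DataFrame(
        {
            "cell_id": ids,
            "cell_type": types,
            "x_um": arr[:, 0],
            "y_um": arr[:, 1],
            "z_um": arr[:, 2],
        }
    )
    return IsletArchitecture(islet_id=islet_id or path.stem, cells=cells)


def write_secretion(dataset: pd.DataFrame, path) -> None:
    missing = set(SECRETION_COLUMNS) - set(dataset.columns)
    if missing:
        raise ValueError(f"secretion table missing columns {sorted(missing)}")
    dataset.to_csv(
        path, sep="\t", index=False, columns=SECRETION_COLUMNS,
        float_format="%.6f",
    )


def read_secretion(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != SECRETION_COLUMNS:
        raise FileFormatError(
            f"{path}: expected columns {SECRETION_COLUMNS}, got {list(df.columns)}"
        )
    if len(df) < 3:
        raise FileFormatError(f"{path}: need at least 3 islet groups")
    if (df[SECRETION_COLUMNS[1:]] < 0).any().any():
        raise FileFormatError(f"{path}: negative content or secretion value")
    return df


def write_ablation_curve(curve: AblationCurve, path) -> None:
    """Export the curve, deleted fraction expressed in percent."""
    tbl = curve.to_frame()
    out = pd.DataFrame(
        {
            "percent_beta_deleted": (tbl["fraction_deleted"] * 100).map(
                lambda v: f"{v:.2f}"
            ),
            "mean_connected_fraction": tbl["mean_connected_fraction"].map(
                lambda v: f"{v:.6f}"
            ),
            "ci_low": tbl["ci_low"].map(lambda v: f"{v:.6f}"),
            "ci_high": tbl["ci_high"].map(lambda v: f"{v:.6f}"),
        }
    )
    out.to_csv(path, sep="\t", index=False)
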