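"""Reading and writing cell tables, cluster tables and analysis reports.

Cell tables are comma-separated UTF-8 text with a mandatory header. One row
per segmented nucleus/cell: coordinates in micrometres (right-handed axes,
dot decimal separator) plus strictly boolean marker flags for the seven-channel
panel (Otx2, Rx2, Zpr1, Rhodopsin, Prox1, Ath5::GFP, PKC-zeta). Intensity
thresholding into positive/negative calls happens upstream of this package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, TableValidationError

MARKER_COLUMNS = (
    "otx2",
    "rx2",
    "zpr1",
    "rhodopsin",
    "prox1",
    "ath5_gfp",
    "pkc_zeta",
)
COORD_COLUMNS = ("x", "y", "z")
CELL_COLUMNS = ("cell_id", *COORD_COLUMNS, *MARKER_COLUMNS, "organoid_id")

CLUSTER_COLUMNS = (
    "cluster_id",
    "organoid_id",
    "n_cells",
    "centroid_x",
    "centroid_y",
    "centroid_z",
    "n_pr",
    "n_bp",
    "n_cone",
    "n_rod",
)

_TRUE = {"1", "true", "True", "TRUE"}
_FALSE = {"0", "false", "False", "FALSE"}


@dataclass(frozen=True)
class OrganoidTable:
    """All cells of one organoid, validated.

    ``cells`` is a DataFrame with the canonical columns of ``CELL_COLUMNS``:
    float μm coordinates, boolean marker flags and unique ``cell_id`` strings.
    """

    organoid_id: str
    cells: pd.DataFrame
    unit: str = "um"
    provenance: str = ""

    def __post_init__(self) -> None:
        validate_cells(self.cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def positions(self) -> np.ndarray:
        return self.cells[list(COORD_COLUMNS)].to_numpy(dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrganoidTable):
            return NotImplemented
        return (
            self.organoid_id == other.organoid_id
            and self.unit == other.unit
            and self.cells.reset_index(drop=True).equals(
                other.cells.reset_index(drop=True)
            )
        )


def validate_cells(cells: pd.DataFrame) -> None:
    """Check column schema, coordinate finiteness and cell-id uniqueness."""
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(cells) == 0:
        raise TableValidationError("cell table is empty (non-empty invariant)")
    coords = cells[list(COORD_COLUMNS)].to_numpy()
    if not np.issubdtype(coords.dtype, np.number):
        for col in COORD_COLUMNS:
            bad = pd.to_numeric(cells[col], errors="coerce")
            if bad.isna().any():
                row = int(bad.index[bad.isna()][0])
                raise TableValidationError(
                    f"non-numeric coordinate in column '{col}' at row {row}"
                )
    finite = np.isfinite(coords.astype(float))
    if not finite.all():
        row_idx, col_idx = np.argwhere(~finite)[0]
        raise TableValidationError(
            f"non-finite coordinate in column "
            f"'{COORD_COLUMNS[col_idx]}' at row {int(cells.index[row_idx])}"
        )
    dup = cells["cell_id"].duplicated()
    if dup.any():
        raise TableValidationError(
            f"duplicate cell_id {cells['cell_id'][dup].iloc[0]!r}"
        )
    for col in MARKER_COLUMNS:
        if cells[col].dtype != bool:
            raise TableValidationError(
                f"marker column '{col}' is not boolean after parsing"
            )


def _parse_bool_column(series: pd.Series, col: str) -> pd.Series:
    if series.dtype == bool:
        return series
    as_str = series.astype(str).str.strip()
    out = pd.Series(index=series.index, dtype=bool)
    ok_true = as_str.isin(_TRUE)
    ok_false = as_str.isin(_FALSE)
    bad = ~(ok_true | ok_false)
    if bad.any():
        row = int(series.index[bad][0])
        raise TableValidationError(
            f"column '{col}' has non-boolean value "
            f"{series[bad].iloc[0]!r} at row {row} (expected 0/1/true/false)"
        )
    out[ok_true] = True
    out[ok_false] = False
    return out


def read_cell_table(path: str | Path, organoid_id: str | None = None) -> OrganoidTable:
    """Read a cell-table CSV, validate it and return an :class:`OrganoidTable`.

    If the file holds several organoids, ``organoid_id`` selects one; if it is
    omitted the file must contain exactly one organoid. Row order is preserved.
    """
    path = Path(path)
    cells = pd.read_csv(path, dtype={"cell_id": str, "organoid_id": str})
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    if organoid_id is not None:
        cells = cells[cells["organoid_id"] == organoid_id]
        if len(cells) == 0:
            raise TableValidationError(
                f"{path.name}: no rows with organoid_id {organoid_id!r}"
            )
        cells = cells.reset_index(drop=True)
    else:
        ids = cells["organoid_id"].unique()
        if len(ids) != 1:
            raise TableValidationError(
                f"{path.name}: {len(ids)} organoid ids present; pass organoid_id"
            )
        organoid_id = str(ids[0])
    cells = cells.copy()
    for col in COORD_COLUMNS:
        cells[col] = pd.to_numeric(cells[col], errors="coerce")
    for col in MARKER_COLUMNS:
        cells[col] = _parse_bool_column(cells[col], col)
    cells = cells[list(CELL_COLUMNS)]
    return OrganoidTable(
        organoid_id=organoid_id, cells=cells, provenance=f"read from {path}"
    )


def write_cell_table(table: OrganoidTable, path: str | Path) -> Path:
    """Write an :class:`OrganoidTable` as CSV.

    Canonical column order, booleans as 0/1, coordinates at 6 decimal places
    (lossless for the read/write round trip at 1e-6 μm).
    """
    path = Path(path)
    out = table.cells.copy()
    for col in MARKER_COLUMNS:
        out[col] = out[col].astype(int)
    out = out[list(CELL_COLUMNS)]
    out.to_csv(path, index=False, float_format="%.6f")
    return path


def read_many(paths: Sequence[str | Path]) -> list[OrganoidTable]:
    """Read one organoid table per path."""
    return [read_cell_table(p) for p in paths]


def write_cluster_table(clusters: Sequence, path: str | Path) -> Path:
    """Write detected clusters as CSV.

    Columns follow ``CLUSTER_COLUMNS`` plus a ``member_ids`` column
    (semicolon-joined cell ids) so downstream stages can recover membership.
    """
    path = Path(path)
    rows = []
    for c in clusters:
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "organoid_id": c.organoid_id,
                "n_cells": c.n_cells,
                "centroid_x": c.centroid[0],
                "centroid_y": c.centroid[1],
                "centroid_z": c.centroid[2],
                "n_pr": c.n_pr,
                "n_bp": c.n_bp,
                "n_cone": c.n_cone,
                "n_rod": c.n_rod,
                "member_ids": ";".join(c.member_ids),
            }
        )
    frame = pd.DataFrame(rows, columns=[*CLUSTER_COLUMNS, "member_ids"])
    frame.to_csv(path, index=False, float_format="%.6f")
    return path


def read_cluster_table(path: str | Path) -> list:
    """Read a cluster CSV written by :func:`write_cluster_table`."""
    from .clusters import Cluster

    frame = pd.read_csv(path, dtype={"cluster_id": str, "organoid_id": str})
    missing = [c for c in CLUSTER_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing cluster column(s): {', '.join(missing)}")
    out = []
    for _, row in frame.iterrows():
        members: tuple[str, ...] = ()
        if "member_ids" in frame.columns and isinstance(row["member_ids"], str):
            members = tuple(row["member_ids"].split(";"))
        out.append(
            Cluster(
                cluster_id=row["cluster_id"],
                organoid_id=row["organoid_id"],
                member_ids=members,
                centroid=np.array(
                    [row["centroid_x"], row["centroid_y"], row["centroid_z"]]
                ),
                n_cells=int(row["n_cells"]),
                n_pr=int(row["n_pr"]),
                n_bp=int(row["n_bp"]),
                n_cone=int(row["n_cone"]),
                n_rod=int(row["n_rod"]),
            )
        )
    return out


def jsonify(obj: Any) -> Any:
    """Convert numpy scalars/arrays and dataclass-like objects to JSON types."""
    if isinstance(obj, Mapping):
        return {str(k): jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        # NaN (e.g. empty-summary means) is not valid JSON; encode as null
        return None if math.isnan(obj) else float(obj)
    return obj


def write_report(results: Mapping[str, Any], path: str | Path) -> Path:
    """Write a machine-readable analysis report (JSON, sorted keys).

    Deterministic for identical inputs: no timestamps; the RNG seed and the
    config echo are part of ``results`` and land in the document verbatim.
    """
    path = Path(path)
    payload = jsonify(results)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
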