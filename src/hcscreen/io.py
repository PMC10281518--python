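"""Readers and writers for the pipeline's plain-text and TIFF formats.

CSV dialect is pinned: comma separator, UTF-8, ``.`` decimal point, missing
values as empty fields.  All tables carry a header row and readers validate
the required columns.  Images and label masks are single-plane grayscale
TIFFs; channel pairs share a filename stem with ``_dapi`` / ``_yfp``
suffixes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .design import PlateLayout, WellAssignment
from .plates import check_well

PLATEMAP_COLUMNS = ["plate_id", "well", "content_class", "sirna_id", "gene_id"]
WELL_TABLE_COLUMNS = ["plate_id", "well", "replicate", "raw_value", "n_nuclei"]


def write_platemap(layouts: Sequence[PlateLayout], path: str | Path) -> None:
    """Write plate layouts to the plate-map CSV schema."""
    rows = []
    for plate in layouts:
        for well, a in sorted(plate.wells.items()):
            rows.append((plate.plate_id, well, a.content_class, a.sirna_id, a.gene_id))
    pd.DataFrame(rows, columns=PLATEMAP_COLUMNS).to_csv(path, index=False)


def read_platemap(
    path: str | Path, n_rows: int = 16, n_cols: int = 24
) -> list[PlateLayout]:
    """Read and validate a plate-map CSV into plate layouts.

    Rejects missing columns, malformed well names, unknown content classes,
    and duplicate (plate, well) entries, naming the offending entry.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str})
    missing = [c for c in PLATEMAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate map {path}: missing columns {missing}")
    layouts: dict[str, PlateLayout] = {}
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        plate_id = row["plate_id"]
        well = row["well"]
        check_well(well, n_rows, n_cols)
        key = (plate_id, well)
        if key in seen:
            raise ValueError(f"plate map {path}: duplicate well {well} on plate {plate_id}")
        seen.add(key)
        sirna = row["sirna_id"] if pd.notna(row["sirna_id"]) else None
        gene = row["gene_id"] if pd.notna(row["gene_id"]) else None
        assign = WellAssignment(row["content_class"], sirna_id=sirna, gene_id=gene)
        layouts.setdefault(plate_id, PlateLayout(plate_id, n_rows, n_cols)).wells[well] = assign
    return [layouts[k] for k in sorted(layouts)]


def write_well_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_well_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str})
    missing = [c for c in WELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"well table {path}: missing columns {missing}")
    return df


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), image)


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def well_image_paths(directory: str | Path, stem: str) -> tuple[Path, Path]:
    """Paths of the paired DAPI / reporter TIFFs for one well."""
    d = Path(directory)
    return d / f"{stem}_dapi.tiff", d / f"{stem}_yfp.tiff"


def read_spot_list(path: str | Path) -> pd.DataFrame:
    """Read a spot-annotation CSV (image_id, cell_id, row, col, spot_class)."""
    df = pd.read_csv(path)
    required = ["row", "col", "spot_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"spot list {path}: missing columns {missing}")
    return df
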