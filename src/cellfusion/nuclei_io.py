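"""Reading and consolidating per-block nuclei segmentation output.

Gigapixel whole-slide images are segmented block by block (8000 x 8000 px by
default) by an upstream nuclei segmentation/classification tool.  Each block
yields a JSON file mapping nucleus id -> {"centroid": [x, y], "type": int},
with centroids in block-local pixel coordinates and integer type ids following
the PanNuke six-class convention.  This module reads those files, stitches the
blocks back into slide-global coordinates, and collapses the six raw classes
into the three categories the downstream embedding uses: neoplastic (tumor),
inflammatory (immune), and miscellaneous (non-neoplastic epithelial +
connective + dead, merged).  Non-nuclei detections are dropped.

Coordinates are 0-based with x = column, y = row; blocks and windows are
half-open intervals [origin, origin + size).  Nuclei are represented by their
centroid only: the downstream representation encodes abundance, not shape, so
contours in the upstream JSON are ignored.  Nuclei that cross block borders
may be reported once per block by the upstream tool; no de-duplication is
attempted (a known, documented bias of block-wise processing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RAW_CLASSES = (
    "neoplastic",
    "non_neoplastic_epithelial",
    "inflammatory",
    "connective",
    "dead",
    "non_nuclei",
)

MERGED_CLASSES = ("neoplastic", "inflammatory", "miscellaneous")

#: raw class -> merged category; ``None`` means the record is dropped.
CLASS_MERGE_TABLE: Mapping[str, str | None] = {
    "neoplastic": "neoplastic",
    "inflammatory": "inflammatory",
    "non_neoplastic_epithelial": "miscellaneous",
    "connective": "miscellaneous",
    "dead": "miscellaneous",
    "non_nuclei": None,
}

#: Default integer type-id table (PanNuke-checkpoint convention).  Upstream
#: dialects differ across tool versions, so this is overridable everywhere it
#: is consumed.
DEFAULT_TYPE_ID_TABLE: Mapping[int, str] = {
    0: "non_nuclei",
    1: "neoplastic",
    2: "inflammatory",
    3: "connective",
    4: "dead",
    5: "non_neoplastic_epithelial",
}

DEFAULT_BLOCK_SIZE = 8000
NOMINAL_MPP = 0.50  # microns per pixel at 20x magnification


class FormatError(ValueError):
    """Raised when an input file does not parse as the documented dialect."""


class ValidationError(ValueError):
    """Raised when parsed content violates a documented invariant."""


@dataclass(frozen=True)
class BlockSpec:
    """Origin and size of one block of the slide partition."""

    origin_x: int
    origin_y: int
    block_size: int = DEFAULT_BLOCK_SIZE


@dataclass
class NucleiTable:
    """Per-nucleus centroids and class labels.

    ``records`` is a DataFrame with columns ``centroid_x``, ``centroid_y``,
    ``raw_class`` and (after :func:`map_classes`) ``merged_class``.
    Coordinates are pixels; either block-local (straight out of
    :func:`read_block_nuclei`) or slide-global (after :func:`stitch_blocks`).
    """

    records: pd.DataFrame
    slide_width: int
    slide_height: int
    mpp: float = NOMINAL_MPP

    def __post_init__(self) -> None:
        if self.slide_width <= 0 or self.slide_height <= 0:
            raise ValidationError("slide dimensions must be positive")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def is_mapped(self) -> bool:
        return "merged_class" in self.records.columns

    def class_counts(self, column: str = "raw_class") -> dict[str, int]:
        order = MERGED_CLASSES if column == "merged_class" else RAW_CLASSES
        counts = self.records[column].value_counts()
        return {c: int(counts.get(c, 0)) for c in order}


def _empty_records(mapped: bool = False) -> pd.DataFrame:
    cols = ["centroid_x", "centroid_y", "raw_class"]
    if mapped:
        cols.append("merged_class")
    return pd.DataFrame({c: pd.Series(dtype=float if c.startswith("centroid") else object) for c in cols})


def read_block_nuclei(
    path: str | Path,
    block: BlockSpec,
    type_id_table: Mapping[int, str] | None = None,
) -> NucleiTable:
    """Read one block's segmentation output (centroids stay block-local).

    The file is a JSON object mapping nucleus id to an object with at least
    ``"centroid": [x, y]`` and ``"type": int``; extra keys (contours, etc.)
    are ignored.
    """
    table = dict(DEFAULT_TYPE_ID_TABLE if type_id_table is None else type_id_table)
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse block JSON {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise FormatError(f"block JSON {path} must be an object of nucleus entries")

    xs, ys, classes = [], [], []
    for nid, entry in payload.items():
        try:
            cx, cy = entry["centroid"]
            type_id = int(entry["type"])
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"nucleus {nid!r} in {path} lacks centroid/type") from exc
        if type_id not in table:
            raise ValidationError(f"unknown nucleus type id {type_id} for nucleus {nid!r}")
        xs.append(float(cx))
        ys.append(float(cy))
        classes.append(table[type_id])

    if xs:
        records = pd.DataFrame(
            {"centroid_x": xs, "centroid_y": ys, "raw_class": classes}
        )
    else:
        records = _empty_records()
    return NucleiTable(
        records=records, slide_width=block.block_size, slide_height=block.block_size
    )


def stitch_blocks(
    tables: Sequence[NucleiTable],
    blocks: Sequence[BlockSpec],
    slide_width: int,
    slide_height: int,
) -> NucleiTable:
    """Offset block-local centroids by their block origins and concatenate.

    Record count is conserved.  A centroid that lands outside the slide
    bounds after offsetting indicates inconsistent block metadata and raises
    :class:`ValidationError`.
    """
    if len(tables) != len(blocks):
        raise ValidationError(
            f"got {len(tables)} tables but {len(blocks)} block specs"
        )
    frames = []
    for table, block in zip(tables, blocks):
        df = table.records.copy()
        df["centroid_x"] = df["centroid_x"] + block.origin_x
        df["centroid_y"] = df["centroid_y"] + block.origin_y
        frames.append(df)
    records = pd.concat(frames, ignore_index=True) if frames else _empty_records()
    out_of_bounds = (
        (records["centroid_x"] < 0)
        | (records["centroid_x"] >= slide_width)
        | (records["centroid_y"] < 0)
        | (records["centroid_y"] >= slide_height)
    )
    if bool(out_of_bounds.any()):
        bad = records[out_of_bounds].iloc[0]
        raise ValidationError(
            "stitched centroid outside slide bounds: "
            f"({bad['centroid_x']}, {bad['centroid_y']}) vs "
            f"{slide_width}x{slide_height}"
        )
    return NucleiTable(records=records, slide_width=slide_width, slide_height=slide_height)


def map_classes(table: NucleiTable) -> NucleiTable:
    """Collapse six raw classes into the three merged categories.

    Non-nuclei records are removed; the operation is idempotent on tables
    that already carry a ``merged_class`` column.
    """
    if table.is_mapped:
        return table
    if "raw_class" not in table.records.columns or table.records["raw_class"].isna().any():
        raise ValidationError("every record needs a raw_class before mapping")
    records = table.records.copy()
    records["merged_class"] = records["raw_class"].map(CLASS_MERGE_TABLE)
    records = records.dropna(subset=["merged_class"]).reset_index(drop=True)
    if len(records) == 0:
        records = _empty_records(mapped=True)
    return replace(table, records=records)


def tile_blocks(slide_width: int, slide_height: int, block_size: int = DEFAULT_BLOCK_SIZE) -> list[BlockSpec]:
    """Non-overlapping block partition; ragged edge blocks are clipped."""
    if block_size <= 0:
        raise ValidationError("block_size must be positive")
    return [
        BlockSpec(origin_x=x, origin_y=y, block_size=block_size)
        for y in range(0, slide_height, block_size)
        for x in range(0, slide_width, block_size)
    ]


def read_block_manifest(path: str | Path) -> list[tuple[Path, BlockSpec]]:
    """Read a block-manifest CSV (columns: block_file, origin_x, origin_y).

    Optional column ``block_size`` overrides the default.  Paths are resolved
    relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"block_file", "origin_x", "origin_y"}
    if not required.issubset(df.columns):
        raise FormatError(f"manifest {path} must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        size = int(row["block_size"]) if "block_size" in df.columns else DEFAULT_BLOCK_SIZE
        spec = BlockSpec(int(row["origin_x"]), int(row["origin_y"]), size)
        out.append((path.parent / str(row["block_file"]), spec))
    return out


def ingest_slide(
    manifest_path: str | Path,
    slide_width: int,
    slide_height: int,
    type_id_table: Mapping[int, str] | None = None,
) -> NucleiTable:
    """read -> stitch -> map for a whole slide described by a block manifest."""
    entries = read_block_manifest(manifest_path)
    tables = [read_block_nuclei(p, b, type_id_table) for p, b in entries]
    stitched = stitch_blocks(tables, [b for _, b in entries], slide_width, slide_height)
    return map_classes(stitched)


def write_nuclei_csv(table: NucleiTable, path: str | Path) -> None:
    """Persist a mapped table as CSV (centroid_x, centroid_y, merged_class)."""
    if not table.is_mapped:
        raise ValidationError("table must be class-mapped before export")
    table.records[["centroid_x", "centroid_y", "merged_class"]].to_csv(path, index=False)


def read_nuclei_csv(path: str | Path, slide_width: int, slide_height: int, mpp: float = NOMINAL_MPP) -> NucleiTable:
    """Load a consolidated nuclei CSV produced by :func:`write_nuclei_csv`."""
    records = pd.read_csv(path)
    if not {"centroid_x", "centroid_y", "merged_class"}.issubset(records.columns):
        raise FormatError(f"{path} is not a consolidated nuclei CSV")
    if "raw_class" not in records.columns:
        records["raw_class"] = records["merged_class"]
    return NucleiTable(records=records, slide_width=slide_width, slide_height=slide_height, mpp=mpp)
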