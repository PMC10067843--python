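"""Reading and writing the pipeline's on-disk formats.

Channels and masks are single-plane grayscale TIFFs (8/16-bit integer or
float), one marker per file; masks use 0 = background, nonzero = foreground.
Tabular results are UTF-8 CSV with a header row, with floats serialized via
``repr`` so a reload reproduces every value bit-for-bit.

A population on disk is described by a ``manifest.csv`` with one row per
(cell, marker): ``cell_id, group, marker, channel_path, cell_mask_path,
nucleus_mask_path, pixel_size_um`` (paths relative to the manifest).
"""

from __future__ import annotations

import csv
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import tifffile

from .exceptions import DimensionError, ValidationError
from .model import BinaryMask, CellRecord, ChannelImage

MANIFEST_COLUMNS = [
    "cell_id",
    "group",
    "marker",
    "channel_path",
    "cell_mask_path",
    "nucleus_mask_path",
    "pixel_size_um",
]


def read_channel_tiff(path) -> np.ndarray:
    """Read a single-plane grayscale TIFF as float64, without rescaling.

    Integer inputs (8/16-bit) are promoted to float64 value-for-value: a
    16-bit pixel of 65535 loads as 65535.0.
    """
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise DimensionError(f"{path}: expected a single-plane 2D image, got shape {arr.shape}")
    return arr.astype(np.float64)


def read_multipage_tiff(path) -> list[np.ndarray]:
    """Convenience reader for a multi-page grayscale TIFF (e.g. a z-stack)."""
    arr = np.asarray(tifffile.imread(str(path)))
    if arr.ndim == 2:
        return [arr.astype(np.float64)]
    if arr.ndim != 3:
        raise DimensionError(f"{path}: expected 2D or 3D TIFF, got shape {arr.shape}")
    return [plane.astype(np.float64) for plane in arr]


def write_channel_tiff(path, pixels: np.ndarray) -> None:
    """Write a 2D array as an uncompressed grayscale TIFF.

    Integer-valued arrays within 16-bit range are stored as uint16 so the
    round-trip is bit-exact; anything else is stored as float32.
    """
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise DimensionError(f"can only write 2D images, got shape {arr.shape}")
    if arr.dtype.kind in "ui" and arr.min() >= 0 and arr.max() <= np.iinfo(np.uint16).max:
        out = arr.astype(np.uint16)
    elif arr.dtype.kind == "f" and np.allclose(arr, np.round(arr)) and arr.size and \
            arr.min() >= 0 and arr.max() <= np.iinfo(np.uint16).max:
        out = np.round(arr).astype(np.uint16)
    else:
        out = arr.astype(np.float32)
    tifffile.imwrite(str(path), out)


def write_mask_tiff(path, mask: BinaryMask | np.ndarray) -> None:
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)
    tifffile.imwrite(str(path), pixels.astype(np.uint8) * 255)


def read_mask_tiff(path, *, allow_empty: bool = True) -> BinaryMask:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise DimensionError(f"{path}: expected a 2D mask, got shape {arr.shape}")
    mask = BinaryMask(arr != 0)
    if not allow_empty and mask.area == 0:
        raise ValidationError(f"{path}: mask has no foreground pixels")
    return mask


def load_cell_record(
    channel_paths: Mapping[str, object],
    mask_path,
    cell_id: str,
    group: str,
    pixel_size_um: float,
    nucleus_mask_path=None,
) -> CellRecord:
    """Assemble a :class:`CellRecord` from per-marker TIFFs and mask TIFFs.

    Raises :class:`DimensionError` naming the offending marker on a shape
    mismatch, ``OSError`` for an unreadable file and
    :class:`ValidationError` for an empty cell mask.
    """
    if not channel_paths:
        raise ValidationError(f"cell '{cell_id}': no channel paths given")
    channels: dict[str, ChannelImage] = {}
    ref_shape: Optional[tuple[int, int]] = None
    for marker, path in channel_paths.items():
        arr = read_channel_tiff(path)
        if ref_shape is None:
            ref_shape = arr.shape
        elif arr.shape != ref_shape:
            raise DimensionError(
                f"cell '{cell_id}': channel '{marker}' has shape {arr.shape}, "
                f"expected {ref_shape}"
            )
        channels[marker] = ChannelImage(arr, marker_name=marker, pixel_size_um=pixel_size_um)
    cell_mask = read_mask_tiff(mask_path)
    if cell_mask.shape != ref_shape:
        raise DimensionError(
            f"cell '{cell_id}': cell mask has shape {cell_mask.shape}, expected {ref_shape}"
        )
    if cell_mask.area == 0:
        raise ValidationError(f"cell '{cell_id}': cell mask is empty")
    nucleus = read_mask_tiff(nucleus_mask_path) if nucleus_mask_path else None
    return CellRecord(
        cell_id=cell_id,
        group=group,
        channels=channels,
        cell_mask=cell_mask,
        nucleus_mask=nucleus,
    )


def _format_value(value) -> str:
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return str(value)


def write_table(rows: Sequence, path, fields: Optional[Sequence[str]] = None) -> int:
    """Write records (dataclasses or mappings) to CSV; return the row count.

    All records must share one field set; floats are serialized with full
    round-trip precision.
    """
    dicts = []
    for row in rows:
        if is_dataclass(row):
            dicts.append(asdict(row))
        elif isinstance(row, Mapping):
            dicts.append(dict(row))
        else:
            raise ValidationError(f"unsupported row type: {type(row).__name__}")
    if dicts:
        header = list(dicts[0]) if fields is None else list(fields)
        for i, d in enumerate(dicts):
            if set(d) != set(header):
                raise ValidationError(
                    f"row {i} fields {sorted(d)} do not match header {sorted(header)}"
                )
    else:
        header = list(fields) if fields is not None else []
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for d in dicts:
            writer.writerow([_format_value(d[name]) for name in header])
    return len(dicts)


def write_manifest(rows: Iterable[Mapping], path) -> int:
    """Write a population manifest (one row per cell x marker)."""
    rows = list(rows)
    for row in rows:
        missing = set(MANIFEST_COLUMNS) - set(row)
        if missing:
            raise ValidationError(f"manifest row missing columns: {sorted(missing)}")
    return write_table(rows, path, fields=MANIFEST_COLUMNS)


def read_manifest(path) -> list[dict]:
    """Read a manifest; paths are resolved relative to the manifest file."""
    path = Path(path)
    base = path.parent
    out: list[dict] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(MANIFEST_COLUMNS) - set(reader.fieldnames):
            raise ValidationError(
                f"{path}: manifest must have columns {MANIFEST_COLUMNS}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            rec = dict(row)
            for key in ("channel_path", "cell_mask_path", "nucleus_mask_path", "foreground_path"):
                if rec.get(key):
                    rec[key] = str((base / rec[key]).resolve())
            rec["pixel_size_um"] = float(rec["pixel_size_um"])
            out.append(rec)
    return out


def load_cells_from_manifest(path) -> list[CellRecord]:
    """Group manifest rows by cell and load every :class:`CellRecord`."""
    rows = read_manifest(path)
    by_cell: dict[str, list[dict]] = {}
    for row in rows:
        by_cell.setdefault(row["cell_id"], []).append(row)
    cells = []
    for cell_id, cell_rows in by_cell.items():
        first = cell_rows[0]
        cells.append(
            load_cell_record(
                channel_paths={r["marker"]: r["channel_path"] for r in cell_rows},
                mask_path=first["cell_mask_path"],
                cell_id=cell_id,
                group=first["group"],
                pixel_size_um=first["pixel_size_um"],
                nucleus_mask_path=first.get("nucleus_mask_path") or None,
            )
        )
    return cells


def save_cell_record(cell: CellRecord, outdir) -> list[dict]:
    """Write one cell's channels and masks as TIFFs; return manifest rows."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mask_path = outdir / f"{cell.cell_id}_cellmask.tiff"
    write_mask_tiff(mask_path, cell.cell_mask)
    nucleus_path = ""
    if cell.nucleus_mask is not None:
        nucleus_path = f"{cell.cell_id}_nucleusmask.tiff"
        write_mask_tiff(outdir / nucleus_path, cell.nucleus_mask)
    rows = []
    for marker, channel in cell.channels.items():
        channel_path = f"{cell.cell_id}_{marker}.tiff"
        write_channel_tiff(outdir / channel_path, channel.pixels)
        rows.append(
            {
                "cell_id": cell.cell_id,
                "group": cell.group,
                "marker": marker,
                "channel_path": channel_path,
                "cell_mask_path": mask_path.name,
                "nucleus_mask_path": nucleus_path,
                "pixel_size_um": channel.pixel_size_um,
            }
        )
    return rows
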