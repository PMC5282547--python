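"""Readers and writers for the pipeline's file formats.

Images travel as multi-page TIFF with the two channels interleaved per
timepoint (green page, then red page, for each frame); tables are plain
comma-separated UTF-8 CSV with a mandatory header row and "." decimals;
summary results are JSON.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .datatypes import DegradationRecord, ImageStack, LaneRecord, SurvivalRecord

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "read_table",
    "write_records",
    "write_json",
]

PathLike = Union[str, Path]

_SCHEMAS = {
    "lane": ["blot_id", "condition", "mg132", "target_intensity", "loading_intensity"],
    "survival": ["concentration", "replicate_id", "count_or_signal"],
    "degradation": [
        "condition",
        "replicate_id",
        "time_min",
        "target_intensity",
        "loading_intensity",
    ],
}


def read_image_stack(
    path: Union[PathLike, Sequence[PathLike]],
    timestamps_h: Sequence[float],
    pixel_size_um: float = 0.65,
) -> ImageStack:
    """Read a two-channel time lapse from TIFF.

    ``path`` is either one multi-page TIFF with channel-interleaved pages
    (green, red, green, red, ...) or a pair ``(green_path, red_path)`` of
    single-channel stacks.  Page counts must match ``timestamps_h``.
    """
    if isinstance(path, (str, Path)):
        pages = tifffile.imread(path)
        pages = np.atleast_3d(pages)
        if pages.ndim != 3:
            raise ValueError("expected a stack of 2-D pages")
        if pages.shape[0] % 2 != 0:
            raise ValueError(
                f"page count {pages.shape[0]} not divisible by channel count 2"
            )
        green, red = pages[0::2], pages[1::2]
    else:
        green_path, red_path = path
        green = np.atleast_3d(tifffile.imread(green_path))
        red = np.atleast_3d(tifffile.imread(red_path))
    timestamps = np.asarray(list(timestamps_h), dtype=float)
    if green.shape[0] != timestamps.size:
        raise ValueError(
            f"{green.shape[0]} frames per channel but {timestamps.size} timestamps"
        )
    return ImageStack(green=green, red=red, timestamps_h=timestamps,
                      pixel_size_um=pixel_size_um)


def write_image_stack(stack: ImageStack, path: PathLike) -> None:
    """Write a stack as a channel-interleaved multi-page TIFF."""
    pages = np.empty((2 * stack.n_frames,) + stack.shape, dtype=stack.green.dtype)
    pages[0::2] = stack.green
    pages[1::2] = stack.red
    tifffile.imwrite(path, pages)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes", "+", "+mg132"):
        return True
    if text in ("false", "0", "no", "-", "-mg132"):
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean")


def read_table(path: PathLike, schema: str):
    """Read a typed record list from CSV.

    ``schema`` is one of ``lane``, ``survival``, ``degradation``.  Rows that
    violate the record invariants are rejected with their (1-based, header
    excluded) row numbers reported.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    df = pd.read_csv(path)
    missing = [c for c in _SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns for schema {schema!r}: {missing}")

    records, bad_rows = [], []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            if schema == "lane":
                rec = LaneRecord(
                    blot_id=str(row.blot_id),
                    condition=str(row.condition),
                    mg132=_parse_bool(row.mg132),
                    target_intensity=float(row.target_intensity),
                    loading_intensity=float(row.loading_intensity),
                )
            elif schema == "survival":
                rec = SurvivalRecord(
                    concentration=float(row.concentration),
                    replicate_id=str(row.replicate_id),
                    count_or_signal=float(row.count_or_signal),
                )
            else:
                rec = DegradationRecord(
                    condition=str(row.condition),
                    replicate_id=str(row.replicate_id),
                    time_min=float(row.time_min),
                    target_intensity=float(row.target_intensity),
                    loading_intensity=float(row.loading_intensity),
                )
        except ValueError as exc:
            bad_rows.append((i, str(exc)))
            continue
        records.append(rec)

    if bad_rows:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows)
        raise ValueError(f"invalid rows in {path}: {detail}")

    if schema == "survival" and records:
        nonzero = {r.concentration for r in records if r.concentration > 0}
        if len(nonzero) < 2:
            raise ValueError(
                ">=2 distinct nonzero concentrations required in a survival table"
            )
    return records


def write_records(records, path: PathLike) -> None:
    """Write a homogeneous record list back to CSV."""
    if not records:
        raise ValueError("cannot write an empty record list")
    df = pd.DataFrame([vars(r) for r in records])
    df.to_csv(path, index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(data: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_json_default) + "\n")
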