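"""Readers and writers for on-disk artifacts.

Image stacks are multi-page 16-bit TIFF files with a JSON sidecar
(``<stem>.meta.json``) carrying pixel size (um/px), frame interval (s),
channel name and bit depth.  Tables are plain UTF-8 CSV with a header row and
'.' decimals, validated against named column schemas.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import SchemaError, SynaptofluxError
from .types import ImageStack, StackMeta

logger = logging.getLogger("synaptoflux")

#: Named CSV schemas (column order is canonical). Versioned as a whole.
SCHEMA_VERSION = 1
SCHEMAS: dict[str, list[str]] = {
    "roi": ["id", "area_px", "area_um2", "equiv_diameter_um", "centroid_row", "centroid_col"],
    "trace": ["roi", "frame", "time_s", "intensity"],
    "events": ["roi", "frame", "kind", "amplitude", "baseline_drop"],
    "spectrum": ["wavelength_nm", "intensity"],
    "assay": ["conc_uM", "replicate", "fluorescence"],
    "measurements": ["condition", "fov", "roi", "mean_intensity", "clustering_index", "area_um2"],
    "truth_boutons": [
        "condition", "bouton", "center_row", "center_col", "diameter_um",
        "amplitude", "mean_intensity",
    ],
    "pairs": ["x", "y"],
}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as multi-page uint16 TIFF plus a JSON metadata sidecar.

    Values are rounded and clipped to the 16-bit range on disk; keep analysis
    in memory if sub-integer precision matters.
    """
    path = Path(path)
    data = np.clip(np.round(stack.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "pixel_size_um": stack.meta.pixel_size,
        "frame_interval_s": stack.meta.frame_interval,
        "channel_name": stack.meta.channel_name,
        "bit_depth": 16,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    logger.info("wrote stack %s (%d frames)", path, data.shape[0])


def read_stack(path: str | Path) -> tuple[ImageStack, StackMeta]:
    """Read a TIFF stack and its sidecar metadata.

    A missing sidecar falls back to StackMeta defaults with a logged warning;
    an unreadable file raises an I/O error naming the path, and frames of
    inconsistent shape raise a format error.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (FileNotFoundError, OSError) as exc:
        raise SynaptofluxError(f"cannot read image stack {path}: {exc}") from exc
    except ValueError as exc:
        raise SynaptofluxError(f"inconsistent frame shapes in {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise SynaptofluxError(f"{path}: expected a 2-D image or 3-D stack, got ndim={data.ndim}")

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        meta = StackMeta(
            pixel_size=raw["pixel_size_um"],
            frame_interval=raw["frame_interval_s"],
            channel_name=raw.get("channel_name", ""),
            bit_depth=raw.get("bit_depth", 16),
        )
    else:
        logger.warning("no metadata sidecar for %s; using defaults", path)
        meta = StackMeta()
    logger.info("read stack %s (%d frames)", path, data.shape[0])
    return ImageStack(data.astype(np.float64), meta), meta


def write_table(path: str | Path, table: pd.DataFrame, schema_name: str) -> None:
    """Write a CSV validated against a named schema.

    Column sets must match the schema exactly (order is normalized on write);
    floats keep full precision.  An empty table produces a header-only file.
    """
    cols = _schema_columns(schema_name)
    missing = [c for c in cols if c not in table.columns]
    extra = [c for c in table.columns if c not in cols]
    if missing or extra:
        raise SchemaError(
            f"table does not match schema {schema_name!r}: missing={missing} extra={extra}"
        )
    path = Path(path)
    table[cols].to_csv(path, index=False)
    logger.info("wrote table %s (%d rows, schema %s)", path, len(table), schema_name)


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read a CSV and validate it against a named schema."""
    cols = _schema_columns(schema_name)
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except (FileNotFoundError, OSError) as exc:
        raise SynaptofluxError(f"cannot read table {path}: {exc}") from exc
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise SchemaError(f"{path} does not match schema {schema_name!r}: missing={missing}")
    logger.info("read table %s (%d rows, schema %s)", path, len(table), schema_name)
    return table[cols]


def _schema_columns(schema_name: str) -> list[str]:
    if schema_name not in SCHEMAS:
        raise SchemaError(
            f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}"
        )
    return SCHEMAS[schema_name]
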