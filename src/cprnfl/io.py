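"""File round-tripping: thickness maps (TIFF/CSV + JSON sidecar) and result tables.

A scan is stored as a single-page 32-bit-float TIFF (µm; NaN marks invalid
pixels) or a CSV matrix, with a JSON sidecar carrying the grid and identity
metadata.  Result tables are CSVs with a one-line header; a leading ``#``
comment line embeds the tool version and configuration hash so any output
can be traced to the settings that produced it (read back with
``pandas.read_csv(..., comment="#")``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .geometry import RasterScan

__all__ = ["write_scan", "read_scan", "write_table", "read_table", "scan_stem"]


def scan_stem(scan: RasterScan) -> str:
    return f"{scan.subject_id}_{scan.scan_id}_{scan.assessor_id}"


def write_scan(scan: RasterScan, out_dir: str | Path, fmt: str = "tiff") -> Path:
    """Write a scan + sidecar; returns the sidecar path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = scan_stem(scan)
    data = np.where(scan.valid_mask, scan.thickness, np.nan).astype(np.float32)
    if fmt == "tiff":
        tifffile.imwrite(out_dir / f"{stem}.tif", data)
    elif fmt == "csv":
        np.savetxt(out_dir / f"{stem}.csv", data, delimiter=",", fmt="%.4f")
    else:
        raise ValueError("fmt must be 'tiff' or 'csv'")
    sidecar = {
        "n_ascans": scan.n_ascans,
        "n_bscans": scan.n_bscans,
        "extent_mm": [scan.extent_x_mm, scan.extent_y_mm],
        "onh_center_mm": list(scan.onh_center_mm),
        "laterality": scan.laterality,
        "quality": scan.quality,
        "subject_id": scan.subject_id,
        "scan_id": scan.scan_id,
        "assessor_id": scan.assessor_id,
        "seed": scan.meta.get("seed"),
        "format": fmt,
    }
    path = out_dir / f"{stem}.json"
    path.write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
    return path


def read_scan(sidecar_path: str | Path) -> RasterScan:
    """Read a scan from its JSON sidecar (locating the TIFF/CSV next to it)."""
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    stem = sidecar_path.with_suffix("")
    fmt = meta.get("format", "tiff")
    if fmt == "tiff":
        data = tifffile.imread(stem.with_suffix(".tif")).astype(float)
    else:
        data = np.loadtxt(stem.with_suffix(".csv"), delimiter=",", ndmin=2)
    valid = np.isfinite(data)
    expected = (meta["n_bscans"], meta["n_ascans"])
    if data.shape != expected:
        raise ValueError(f"grid shape {data.shape} does not match sidecar {expected}")
    return RasterScan(
        thickness=np.nan_to_num(data),
        valid_mask=valid,
        extent_x_mm=meta["extent_mm"][0],
        extent_y_mm=meta["extent_mm"][1],
        onh_center_mm=tuple(meta["onh_center_mm"]),
        laterality=meta["laterality"],
        quality=meta["quality"],
        subject_id=meta["subject_id"],
        scan_id=meta["scan_id"],
        assessor_id=meta["assessor_id"],
        meta={"seed": meta.get("seed")},
    )


def write_table(frame: pd.DataFrame, path: str | Path, config_hash: str = "") -> Path:
    """Write a result CSV with a provenance comment line (version + config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# cprnfl-version={__version__} config-hash={config_hash}\n")
        frame.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
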