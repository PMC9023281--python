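"""Reading and writing the pipeline's on-disk formats.

A simulated or recorded field of view is stored as one multi-page TIFF
per channel plus a YAML sidecar carrying the calibration (frame
interval, nt per pixel) and channel file names; molecule annotations
travel as a CSV with one ROI per row.  All tabular outputs are plain
CSV.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .kymo import ClearanceTrace, KymographStack, MoleculeROI

__all__ = [
    "write_stack",
    "read_stack",
    "write_roi_table",
    "read_roi_table",
    "write_trace_csv",
    "sha256_of",
]

_SIDEcar = "stack.yaml"


def write_stack(stack: KymographStack, directory) -> Path:
    """Write one TIFF per channel plus a YAML sidecar; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, arr in stack.channels.items():
        fname = f"{name}.tif"
        tifffile.imwrite(directory / fname, np.asarray(arr, dtype=np.float32))
        files[name] = fname
    sidecar = {
        "channels": files,
        "frame_interval_s": float(stack.frame_interval_s),
        "nt_per_px": float(stack.nt_per_px),
        "meta": {k: _plain(v) for k, v in stack.meta.items()},
    }
    path = directory / _SIDEcar
    path.write_text(yaml.safe_dump(sidecar, sort_keys=True))
    return path


def _plain(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v


def read_stack(path) -> KymographStack:
    """Read a stack written by :func:`write_stack` (sidecar path or directory)."""
    path = Path(path)
    if path.is_dir():
        path = path / _SIDEcar
    sidecar = yaml.safe_load(path.read_text())
    base = path.parent
    channels = {
        name: tifffile.imread(base / fname).astype(float)
        for name, fname in sidecar["channels"].items()
    }
    return KymographStack(
        channels=channels,
        frame_interval_s=sidecar["frame_interval_s"],
        nt_per_px=sidecar["nt_per_px"],
        meta=sidecar.get("meta", {}),
    )


_ROI_COLS = ["molecule_id", "row_center_px", "barrier_px", "anchor_px", "width_px"]


def write_roi_table(rois: list[MoleculeROI], path) -> None:
    pd.DataFrame(
        [
            {
                "molecule_id": r.molecule_id,
                "row_center_px": r.row_center_px,
                "barrier_px": r.barrier_px,
                "anchor_px": r.anchor_px,
                "width_px": r.width_px,
            }
            for r in rois
        ]
    ).to_csv(path, index=False)


def read_roi_table(path) -> list[MoleculeROI]:
    df = pd.read_csv(path)
    missing = set(_ROI_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"ROI table missing columns: {sorted(missing)}")
    return [
        MoleculeROI(
            barrier_px=int(r.barrier_px),
            anchor_px=int(r.anchor_px),
            row_center_px=int(r.row_center_px),
            width_px=int(r.width_px),
            molecule_id=str(r.molecule_id),
        )
        for r in df.itertuples()
    ]


def write_trace_csv(trace: ClearanceTrace, path) -> None:
    df = trace.df.copy()
    df.insert(0, "molecule_id", trace.molecule_id)
    df.insert(1, "channel", trace.channel)
    df.insert(2, "model", trace.model)
    df.to_csv(path, index=False)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
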