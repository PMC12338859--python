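"""Shared containers and on-disk formats: image pairs, manifests, TIFF I/O.

A *field* is one microscope field of view acquired with alternating
excitation (405 nm and 488 nm) of the same optical section.  Fields are
stored as two grayscale TIFFs plus a row in ``manifest.csv`` linking the
files to their acquisition metadata (condition label, buffer pH, treatment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FieldImagePair",
    "MANIFEST_COLUMNS",
    "read_manifest",
    "write_manifest",
    "load_field",
]

#: canonical manifest schema (one row per field of view)
MANIFEST_COLUMNS = [
    "field_id",
    "condition",
    "treatment",
    "species",
    "conc_E_mM",
    "pH_E",
    "true_pH_I",
    "path_ex405",
    "path_ex488",
    "path_labels",
]


@dataclass
class FieldImagePair:
    """Two co-registered excitation-channel images plus acquisition metadata."""

    img405: np.ndarray
    img488: np.ndarray
    field_id: str
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.img405.shape != self.img488.shape:
            raise ValueError(
                f"channel shape mismatch: 405 nm {self.img405.shape} vs "
                f"488 nm {self.img488.shape}"
            )
        if self.img405.ndim != 2:
            raise ValueError("channel images must be 2-D")
        if np.any(self.img405 < 0) or np.any(self.img488 < 0):
            raise ValueError("channel intensities must be non-negative")


def write_manifest(rows: list[dict], path: Path) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"field_id": str, "condition": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {sorted(missing)}")
    return df


def load_field(row: pd.Series, root: Optional[Path] = None) -> FieldImagePair:
    """Load one manifest row's image pair; paths are relative to *root*."""
    root = Path(root) if root is not None else Path(".")
    img405 = tifffile.imread(root / row["path_ex405"]).astype(np.float64)
    img488 = tifffile.imread(root / row["path_ex488"]).astype(np.float64)
    meta = {
        "condition": row["condition"],
        "treatment": row.get("treatment"),
        "species": row.get("species"),
        "conc_E_mM": row.get("conc_E_mM"),
        "pH_E": row.get("pH_E"),
        "true_pH_I": row.get("true_pH_I"),
    }
    return FieldImagePair(img405=img405, img488=img488, field_id=str(row["field_id"]), metadata=meta)
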