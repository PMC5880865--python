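"""NIfTI / TSV / JSON input-output helpers.

All volumes are stored as plain ``numpy`` arrays with a diagonal affine
built from the voxel spacing; orientation handling beyond that is out of
scope for this package (synthetic data and pre-aligned atlases only).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def spacing_affine(spacing_mm) -> np.ndarray:
    """Diagonal affine from a 3-tuple of voxel sizes in mm."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def save_nifti(path, data: np.ndarray, spacing_mm=(3.0, 3.0, 7.0)) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), spacing_affine(spacing_mm))
    nib.save(img, str(path))
    return path


def load_nifti(path) -> tuple[np.ndarray, tuple]:
    """Return (data, spacing_mm) from a NIfTI file."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)


def save_tsv(path, df: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def load_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def save_json(path, obj) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default, allow_nan=True))
    return path


def load_json(path):
    return json.loads(Path(path).read_text())
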