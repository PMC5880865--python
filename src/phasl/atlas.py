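"""Multi-atlas label fusion and ROI statistics.

Atlases are assumed pre-aligned to subject space; fusion is plain
majority voting with deterministic tie-breaking (background loses ties
to any anatomical code, the lowest code wins among anatomical ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CODE_TABLE = {1: "striatum", 2: "thalamus", 3: "acc"}


@dataclass
class LabelMap:
    """Integer ROI volume with its code-to-name table (0 = background)."""

    labels: np.ndarray
    code_table: dict = field(default_factory=lambda: dict(DEFAULT_CODE_TABLE))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer")
        if self.labels.min() < 0:
            raise ValueError("label codes must be non-negative")


def majority_vote(atlases) -> LabelMap:
    """Fuse atlas label volumes by voxelwise majority voting.

    Ties: background (0) loses to any nonzero code; among tied nonzero
    codes the lowest wins.  A single atlas is returned unchanged.
    """
    vols = [np.asarray(a.labels if isinstance(a, LabelMap) else a) for a in atlases]
    if len(vols) == 0:
        raise ValueError("need at least one atlas")
    shape = vols[0].shape
    if any(v.shape != shape for v in vols):
        raise ValueError("atlases must share one grid")
    stack = np.stack(vols)  # (n_atlases, ...)
    codes = np.unique(stack)
    counts = np.stack([(stack == c).sum(axis=0) for c in codes])  # (n_codes, ...)
    # rank: higher count wins; nonzero beats background at equal count;
    # lower code beats higher code at equal count among nonzero
    key = counts.astype(np.float64) * (2 * len(codes))
    for ci, c in enumerate(codes):
        key[ci] += (1 if c != 0 else 0) * len(codes) + (len(codes) - 1 - ci)
    fused = codes[np.argmax(key, axis=0)].astype(np.int32)
    return LabelMap(labels=fused)


def roi_means(cbf_map, label_map: LabelMap, gm_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Mean CBF per ROI over voxels carrying the code, inside the GM mask.

    ``cbf_map`` may be a ``CbfMap`` (its mask is used unless ``gm_mask``
    overrides) or a bare volume.  ROIs with zero eligible voxels are
    reported with NaN mean and flagged via n_voxels = 0.
    Returns a table (roi, code, n_voxels, mean_cbf).
    """
    from .quant import CbfMap

    if isinstance(cbf_map, CbfMap):
        cbf = cbf_map.cbf
        mask = cbf_map.gm_mask if gm_mask is None else np.asarray(gm_mask, dtype=bool)
    else:
        cbf = np.asarray(cbf_map, dtype=np.float64)
        mask = np.ones(cbf.shape, dtype=bool) if gm_mask is None \
            else np.asarray(gm_mask, dtype=bool)
    labels = label_map.labels
    if cbf.shape != labels.shape:
        raise ValueError("cbf and label volumes must share one grid")
    rows = []
    for code, name in sorted(label_map.code_table.items()):
        sel = (labels == code) & mask & np.isfinite(cbf)
        rows.append({
            "roi": name, "code": int(code), "n_voxels": int(sel.sum()),
            "mean_cbf": float(cbf[sel].mean()) if sel.any() else float("nan"),
        })
    return pd.DataFrame(rows)
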