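"""Per-cell mean fluorescence intensity (MFI) and geometry extraction."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segment import LabelMask
from .stack import ChannelStack
from .tissue import TissueMask

#: CellTable column layout (MFI columns are ``mfi_<channel>`` in stack order).
BASE_COLUMNS = ["cell_uid", "label", "row", "col", "area_px", "in_tissue"]


def extract_cell_features(stack: ChannelStack, labels: LabelMask,
                          mask: TissueMask | None = None,
                          slide_id: str = "slide") -> pd.DataFrame:
    """Build the CellTable: one row per label with centroid, area and MFI.

    MFI of a channel is the arithmetic mean of that channel over the
    label's pixels; the centroid is the unweighted pixel centroid.  A cell
    is ``in_tissue`` when its centroid pixel lies inside the tissue mask
    (all cells are in_tissue when no mask is given).  Cells outside the
    tissue are retained but flagged, so the exclusion step stays auditable.
    """
    lab = labels.labels
    if lab.shape != stack.shape:
        raise ValueError(
            f"label mask shape {lab.shape} does not match image shape {stack.shape}"
        )
    if mask is not None and mask.mask.shape != stack.shape:
        raise ValueError(
            f"tissue mask shape {mask.mask.shape} does not match image shape "
            f"{stack.shape}"
        )

    ids = labels.ids
    if ids.size == 0:
        cols = BASE_COLUMNS + [f"mfi_{ch}" for ch in stack.channels]
        return pd.DataFrame(columns=cols)

    flat = lab.ravel()
    nmax = int(ids.max()) + 1
    area = np.bincount(flat, minlength=nmax)

    rows_idx, cols_idx = np.indices(lab.shape)
    sum_r = np.bincount(flat, weights=rows_idx.ravel(), minlength=nmax)
    sum_c = np.bincount(flat, weights=cols_idx.ravel(), minlength=nmax)
    centroid_r = sum_r[ids] / area[ids]
    centroid_c = sum_c[ids] / area[ids]

    table = {
        "cell_uid": [f"{slide_id}-{int(i)}" for i in ids],
        "label": ids.astype(int),
        "row": centroid_r,
        "col": centroid_c,
        "area_px": area[ids].astype(int),
    }
    if mask is None:
        table["in_tissue"] = np.ones(ids.size, dtype=bool)
    else:
        pr = np.clip(np.rint(centroid_r).astype(int), 0, lab.shape[0] - 1)
        pc = np.clip(np.rint(centroid_c).astype(int), 0, lab.shape[1] - 1)
        table["in_tissue"] = mask.mask[pr, pc]

    for ch, plane in zip(stack.channels, stack.data):
        total = np.bincount(flat, weights=np.asarray(plane, dtype=float).ravel(),
                            minlength=nmax)
        table[f"mfi_{ch}"] = total[ids] / area[ids]

    return pd.DataFrame(table)


def write_cell_table(cells: pd.DataFrame, path, config_hash: str | None = None) -> None:
    """CSV writer; an optional leading ``#`` comment carries the config hash."""
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# mifquant config_hash={config_hash}\n")
        cells.to_csv(fh, index=False)


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
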