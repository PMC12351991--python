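"""Overlap metrics on binary mask pairs: DSC, IoU (Jaccard), VOE.

DSC = 2|Ŷ∩Y| / (|Ŷ|+|Y|),  IoU = |Ŷ∩Y| / |Ŷ∪Y|,  VOE = 1 - IoU.
Metrics are computed on whole 3-D volumes, never slice-wise.  Two empty
masks score DSC = IoU = 1 (VOE = 0) — correctly predicting absence — and
the record flags that convention.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["MetricsRecord", "segmentation_metrics", "metrics_table"]


@dataclasses.dataclass
class MetricsRecord:
    dsc: float
    iou: float
    voe: float
    intersection: int
    pred_size: int
    gt_size: int
    union: int
    both_empty: bool = False


def _as_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary, found values {vals[:10]}")
    return arr.astype(bool)


def segmentation_metrics(pred: np.ndarray, gt: np.ndarray) -> MetricsRecord:
    """Compute DSC, IoU and VOE for one predicted/reference mask pair."""
    pred = _as_binary(pred, "pred")
    gt = _as_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    inter = int(np.count_nonzero(pred & gt))
    p_size = int(np.count_nonzero(pred))
    g_size = int(np.count_nonzero(gt))
    union = p_size + g_size - inter
    if union == 0:
        return MetricsRecord(1.0, 1.0, 0.0, 0, 0, 0, 0, both_empty=True)
    iou = inter / union
    dsc = 2.0 * inter / (p_size + g_size)
    return MetricsRecord(dsc, iou, 1.0 - iou, inter, p_size, g_size, union)


def metrics_table(records: Iterable[tuple[str, MetricsRecord]]) -> pd.DataFrame:
    """Per-case metric rows plus a final mean-over-cases row."""
    rows = [
        {"case_id": cid, "dsc": r.dsc, "iou": r.iou, "voe": r.voe,
         "pred_size": r.pred_size, "gt_size": r.gt_size}
        for cid, r in records
    ]
    df = pd.DataFrame(rows)
    if len(df):
        mean = df[["dsc", "iou", "voe"]].mean()
        df = pd.concat(
            [df, pd.DataFrame([{"case_id": "mean", **mean.to_dict()}])],
            ignore_index=True,
        )
    return df
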