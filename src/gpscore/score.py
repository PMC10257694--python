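"""Apply a trained model to new samples: DScores, prediction gating, and
retention-time anchor selection.

Prediction gating is the search-space control step: targets the model
predicts false are removed *before* FDR estimation, while decoys always
stay — they are the yardstick the q-value estimate is built on.  Gating
a target out never touches any decoy record.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import EmptySelection, NotScored, SchemaMismatch
from .io_model import SampleTable
from .train import PrecursorModel


def compute_dscore(model: PrecursorModel, table: SampleTable) -> SampleTable:
    """Score every record with the model's decision margin (DScore).

    A pure function of (model, features): identical feature vectors get
    identical scores and no record is dropped or reordered.
    """
    if tuple(table.feature_names) != tuple(model.feature_names):
        raise SchemaMismatch(
            "table features do not match the model's feature names"
        )
    df = table.data.copy()
    if len(df):
        df["dscore"] = model.decision_margin(table.features())
    else:
        df["dscore"] = pd.Series(dtype=np.float64)
    return table.with_data(df)


def predict_targets(
    model: PrecursorModel,
    table: SampleTable,
    threshold: float | None = None,
) -> tuple[SampleTable, SampleTable]:
    """Flag predicted-true records and return (flagged table, gated table).

    The gated table keeps the targets predicted true plus *all* decoys,
    whatever the decoys' own predictions: decoys must survive gating so
    FDR can still be estimated on the gated set.
    """
    if "dscore" not in table.data.columns:
        raise NotScored("predict_targets requires a scored table")
    threshold = model.probability_threshold if threshold is None else threshold
    df = table.data.copy()
    prob = 1.0 / (1.0 + np.exp(-df["dscore"].to_numpy(dtype=np.float64)))
    df["predicted_target"] = (prob >= threshold).astype(np.int64)
    flagged = table.with_data(df)
    keep = (df["predicted_target"] == 1) | (df["decoy"] == 1)
    gated = table.with_data(df.loc[keep].reset_index(drop=True))
    return flagged, gated


def build_rt_library(table: SampleTable, num_bins: int) -> pd.DataFrame:
    """Select per-bin retention-time anchor precursors.

    The observed RT range of the predicted-true targets is split into
    ``num_bins`` equal-width bins; each non-empty bin contributes its
    single highest-scoring record (ties: lowest peakgroup_rank, then
    input order).  Returns at most ``num_bins`` anchors as a frame of
    (precursor_id, retention_time, dscore).
    """
    if num_bins < 1:
        raise ValueError("num_bins must be >= 1")
    df = table.data
    if "predicted_target" not in df.columns or "dscore" not in df.columns:
        raise NotScored("build_rt_library requires a scored, predicted table")
    cand = df[(df["decoy"] == 0) & (df["predicted_target"] == 1)]
    if len(cand) == 0:
        raise EmptySelection("no predicted-true targets to anchor on")
    rt = cand["retention_time"].to_numpy(dtype=np.float64)
    lo, hi = rt.min(), rt.max()
    if hi == lo:
        bins = np.zeros(len(cand), dtype=np.int64)
    else:
        edges = np.linspace(lo, hi, num_bins + 1)
        bins = np.clip(np.digitize(rt, edges[1:-1]), 0, num_bins - 1)
    cand = cand.assign(_bin=bins).reset_index(drop=True)
    order = cand.sort_values(
        ["_bin", "dscore", "peakgroup_rank"],
        ascending=[True, False, True],
        kind="stable",
    )
    anchors = order.drop_duplicates("_bin", keep="first").sort_values("_bin")
    return anchors.loc[:, ["precursor_id", "retention_time", "dscore"]].reset_index(
        drop=True
    )
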