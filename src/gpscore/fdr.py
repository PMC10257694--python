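"""Target-decoy q-value estimation and global peptide/protein rollup.

At a score threshold s the estimated false-discovery fraction is

    FDR(s) = D(s) / (T(s) + D(s))

with D(s) and T(s) the numbers of decoys and targets scoring at least s.
This is the fraction-of-accepted formulation; no incorrect-target prior
(PIT/pi0) down-weights the decoys anywhere in this module — search-space
control is done upstream by prediction gating, not by re-weighting the
decoy estimate.  The q-value of a score s is the smallest FDR(t) over
the thresholds t <= s whose acceptance region contains s; this running
minimum makes q-values monotone non-increasing in the score.

Two estimators are provided:

* counting — exact empirical tail counts; fast, stepwise;
* spline — smoothed target/decoy score densities (histogram on a fixed
  grid, monotone cubic interpolation of the cumulative counts) whose tail
  integrals replace the raw counts; this stabilizes the estimate in
  sparse tails and is the default when both classes have enough scores.

The global rollup picks the highest-scoring representative per peptide or
protein group across all samples of an experiment and estimates q-values
on those representatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import PchipInterpolator

from .errors import EmptyInput, TooFewRecords
from .io_model import SampleTable, concat_tables

#: Minimum scores per class for a stable density fit.
MIN_SCORES_FOR_SPLINE = 50


def _counting_q_on_axis(
    target_scores: np.ndarray, decoy_scores: np.ndarray, axis: np.ndarray
) -> np.ndarray:
    """Raw D/(T+D) at each ascending axis point, monotonized into q-values.

    q(s) = min over thresholds t <= s of FDR(t): the smallest estimated
    FDR of any acceptance region containing s.  On an ascending axis this
    is a forward cumulative minimum, and it makes q non-increasing in s.
    """
    ts = np.sort(target_scores)
    ds = np.sort(decoy_scores)
    T = ts.size - np.searchsorted(ts, axis, side="left")
    D = ds.size - np.searchsorted(ds, axis, side="left")
    denom = T + D
    raw = np.divide(D, denom, out=np.zeros_like(axis, dtype=float), where=denom > 0)
    return np.minimum.accumulate(raw)


def qvalues_counting(
    target_scores: Sequence[float], decoy_scores: Sequence[float]
) -> np.ndarray:
    """Decoy-counting q-value per target score, aligned with the input.

    Tied scores share one value; q-values are clipped to [0, 1] and are
    monotone non-increasing in the score.
    """
    t = np.asarray(target_scores, dtype=np.float64)
    d = np.asarray(decoy_scores, dtype=np.float64)
    if t.size == 0:
        raise EmptyInput("no target scores")
    order = np.argsort(t, kind="stable")
    q_sorted = _counting_q_on_axis(t, d, t[order])
    out = np.empty_like(t)
    out[order] = np.clip(q_sorted, 0.0, 1.0)
    return out


@dataclass
class ScoreDistribution:
    """Smoothed target and decoy score densities on a common grid.

    Densities are built by monotone cubic (PCHIP) interpolation of the
    cumulative histogram counts, so they are non-negative everywhere and
    each integrates to 1 (trapezoid rule) over the grid.
    """

    score_grid: np.ndarray
    target_density: np.ndarray
    decoy_density: np.ndarray
    target_count: int
    decoy_count: int
    # integral of density from s to grid max, per grid point
    _target_tail: np.ndarray = field(repr=False, default=None)
    _decoy_tail: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self._target_tail is None:
            self._target_tail = _tail_integral(self.score_grid, self.target_density)
        if self._decoy_tail is None:
            self._decoy_tail = _tail_integral(self.score_grid, self.decoy_density)

    def target_tail(self, scores: np.ndarray) -> np.ndarray:
        return np.interp(scores, self.score_grid, self._target_tail)

    def decoy_tail(self, scores: np.ndarray) -> np.ndarray:
        return np.interp(scores, self.score_grid, self._decoy_tail)


def _tail_integral(grid: np.ndarray, density: np.ndarray) -> np.ndarray:
    cum = cumulative_trapezoid(density, grid, initial=0.0)
    return cum[-1] - cum


def _smooth_density(
    scores: np.ndarray, edges: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Density and tail integral on the grid from one class's scores.

    The cumulative histogram is interpolated by a monotone cubic (PCHIP),
    so its derivative is a non-negative density and the tail integral
    from s to the grid maximum is available in closed form as
    cdf(max) - cdf(s), with no quadrature error.
    """
    counts, _ = np.histogram(scores, bins=edges)
    cdf_knots = np.concatenate([[0.0], np.cumsum(counts)]) / scores.size
    interp = PchipInterpolator(edges, cdf_knots)
    density = np.clip(interp.derivative()(grid), 0.0, None)
    density = density / np.trapezoid(density, grid)
    cdf = interp(grid)
    return density, cdf[-1] - cdf


def fit_score_distributions(
    target_scores: Sequence[float],
    decoy_scores: Sequence[float],
    grid_size: int = 1000,
) -> ScoreDistribution:
    """Fit smoothed target/decoy densities on a shared padded grid.

    The grid spans the pooled score range padded by three histogram bin
    widths on each side.  Raises :class:`TooFewRecords` below
    :data:`MIN_SCORES_FOR_SPLINE` scores per class; callers fall back to
    :func:`qvalues_counting`.
    """
    t = np.asarray(target_scores, dtype=np.float64)
    d = np.asarray(decoy_scores, dtype=np.float64)
    if t.size < MIN_SCORES_FOR_SPLINE or d.size < MIN_SCORES_FOR_SPLINE:
        raise TooFewRecords(
            f"need >= {MIN_SCORES_FOR_SPLINE} scores per class for a density fit"
        )
    pooled = np.concatenate([t, d])
    lo, hi = pooled.min(), pooled.max()
    width = (hi - lo) / grid_size if hi > lo else 1.0
    pad = 3.0 * width
    edges = np.linspace(lo - pad, hi + pad, grid_size + 1)
    grid = edges
    target_density, target_tail = _smooth_density(t, edges, grid)
    decoy_density, decoy_tail = _smooth_density(d, edges, grid)
    return ScoreDistribution(
        score_grid=grid,
        target_density=target_density,
        decoy_density=decoy_density,
        target_count=int(t.size),
        decoy_count=int(d.size),
        _target_tail=target_tail,
        _decoy_tail=decoy_tail,
    )


def qvalues_spline(
    dist: ScoreDistribution, scores: Sequence[float]
) -> np.ndarray:
    """Spline-density q-value per score.

    D(s) and T(s) are the decoy/target tail integrals scaled by the class
    counts; FDR(s) = D/(T+D) is monotonized into q(s) = min over
    thresholds t <= s of FDR(t) and clipped to [0, 1].  Scores outside
    the grid are clamped to the grid edge.
    """
    s = np.clip(
        np.asarray(scores, dtype=np.float64),
        dist.score_grid[0],
        dist.score_grid[-1],
    )
    # evaluate raw FDR at the requested scores only, then monotonize over
    # them — thresholds live at observed scores, exactly as in counting
    order = np.argsort(s, kind="stable")
    D = dist.decoy_count * dist.decoy_tail(s[order])
    T = dist.target_count * dist.target_tail(s[order])
    denom = T + D
    raw = np.divide(D, denom, out=np.zeros_like(denom), where=denom > 0)
    q_sorted = np.clip(np.minimum.accumulate(raw), 0.0, 1.0)
    out = np.empty_like(q_sorted)
    out[order] = q_sorted
    return out


def qvalues_auto(
    target_scores: Sequence[float], decoy_scores: Sequence[float]
) -> tuple[np.ndarray, str]:
    """Spline q-values when both classes allow a density fit, else counting.

    Returns the per-target q-values and the method actually used.
    """
    try:
        dist = fit_score_distributions(target_scores, decoy_scores)
        return qvalues_spline(dist, target_scores), "spline"
    except TooFewRecords:
        return qvalues_counting(target_scores, decoy_scores), "counting"


def annotate_sample_qvalues(
    table: SampleTable, method: str = "auto"
) -> SampleTable:
    """Attach per-record precursor q-values to one scored sample.

    Targets get q-values estimated against the sample's decoys; decoy
    records are annotated with the q-value their own score would receive
    (useful for diagnostics, never for filtering them out).
    """
    df = table.data.copy()
    tmask = df["decoy"] == 0
    t = df.loc[tmask, "dscore"].to_numpy(dtype=np.float64)
    d = df.loc[~tmask, "dscore"].to_numpy(dtype=np.float64)
    if t.size == 0:
        raise EmptyInput("sample has no target records")
    if method == "counting":
        q_t = qvalues_counting(t, d)
        q_d = np.interp(d, *_monotone_axis(t, q_t))
    elif method in ("auto", "spline"):
        if method == "spline":
            dist = fit_score_distributions(t, d)
            q_t = qvalues_spline(dist, t)
            q_d = qvalues_spline(dist, d)
        else:
            q_t, used = qvalues_auto(t, d)
            if used == "spline":
                dist = fit_score_distributions(t, d)
                q_d = qvalues_spline(dist, d)
            else:
                q_d = np.interp(d, *_monotone_axis(t, q_t))
    else:
        raise ValueError(f"unknown method {method!r}")
    df.loc[tmask, "qvalue_precursor"] = q_t
    df.loc[~tmask, "qvalue_precursor"] = q_d
    return table.with_data(df)


def _monotone_axis(scores: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(scores, kind="stable")
    return scores[order], q[order]


@dataclass
class GlobalLevelModel:
    """Best-score-per-group table with a fitted score-to-q mapping.

    ``level`` is "peptide" or "protein"; the table holds one row per group
    key with the maximal DScore over all samples, its decoy status and its
    q-value.  ``annotate_scores`` maps arbitrary new scores onto q-values
    through the fitted axis, so future results can be annotated without
    refitting.
    """

    level: str
    table: pd.DataFrame  # index: group key; columns: dscore, decoy, qvalue
    score_axis: np.ndarray
    q_axis: np.ndarray
    method: str

    def lookup(self, keys: Sequence[str]) -> np.ndarray:
        """q-value per group key; NaN for keys the model has not seen."""
        return self.table["qvalue"].reindex(keys).to_numpy(dtype=np.float64)

    def annotate_scores(self, scores: Sequence[float]) -> np.ndarray:
        s = np.asarray(scores, dtype=np.float64)
        return np.interp(s, self.score_axis, self.q_axis)

    def save(self, path) -> None:
        import json

        doc = {
            "format": "gpscore-global-v1",
            "level": self.level,
            "method": self.method,
            "keys": self.table.index.tolist(),
            "dscore": self.table["dscore"].tolist(),
            "decoy": self.table["decoy"].astype(int).tolist(),
            "qvalue": self.table["qvalue"].tolist(),
            "score_axis": self.score_axis.tolist(),
            "q_axis": self.q_axis.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "GlobalLevelModel":
        import json

        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        table = pd.DataFrame(
            {
                "dscore": doc["dscore"],
                "decoy": doc["decoy"],
                "qvalue": doc["qvalue"],
            },
            index=pd.Index(doc["keys"], name="group_key"),
        )
        return cls(
            level=doc["level"],
            table=table,
            score_axis=np.asarray(doc["score_axis"], dtype=np.float64),
            q_axis=np.asarray(doc["q_axis"], dtype=np.float64),
            method=doc["method"],
        )


def global_rollup(
    samples: Iterable[SampleTable], level: str
) -> GlobalLevelModel:
    """Roll per-sample best-peakgroup scores up to peptide or protein level.

    For each group key (peptide_id or protein_group) the maximal DScore
    over all samples represents the group; q-values are estimated on the
    representative target scores against the representative decoy scores
    (spline when counts allow, else counting).
    """
    if level not in ("peptide", "protein"):
        raise ValueError(f"unknown level {level!r}")
    key_col = "peptide_id" if level == "peptide" else "protein_group"
    df = concat_tables(samples)
    if "dscore" not in df.columns or df["dscore"].isna().any():
        raise EmptyInput("global rollup requires fully scored samples")

    order = df.sort_values(
        [key_col, "dscore", "peakgroup_rank"],
        ascending=[True, False, True],
        kind="stable",
    )
    best = order.drop_duplicates(key_col, keep="first")
    reps = best.set_index(key_col).loc[:, ["dscore", "decoy"]]

    t = reps.loc[reps["decoy"] == 0, "dscore"].to_numpy(dtype=np.float64)
    d = reps.loc[reps["decoy"] == 1, "dscore"].to_numpy(dtype=np.float64)
    if t.size == 0:
        raise EmptyInput("no target groups to roll up")
    q_t, method = qvalues_auto(t, d)
    axis_scores, axis_q = _monotone_axis(t, q_t)
    reps["qvalue"] = np.interp(
        reps["dscore"].to_numpy(dtype=np.float64), axis_scores, axis_q
    )
    reps.loc[reps["decoy"] == 0, "qvalue"] = q_t
    reps.index.name = "group_key"
    return GlobalLevelModel(
        level=level,
        table=reps,
        score_axis=axis_scores,
        q_axis=axis_q,
        method=method,
    )
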