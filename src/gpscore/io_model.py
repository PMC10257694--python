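"""Peak-group data model and tabular I/O.

A *peak group* is one candidate chromatographic co-elution of a precursor's
fragment traces; a precursor (modified peptide sequence + charge) may have
several candidates distinguished by ``peakgroup_rank``.  Every record carries
the 22 MS2-level subscores produced during extracted-ion signal scoring
(library correlation, co-elution, mass deviation, ... — the ``var_*``
columns), a target/decoy flag, retention time and an optional intensity.

Tables are exchanged as UTF-8 tab-separated text with a header row; an empty
cell encodes an absent value.  The in-memory container is a thin wrapper
around a :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import EmptyInput, MalformedValue, MissingColumn, NotScored

#: Canonical ordering of the 22 MS2 subscore features.
SUBSCORE_COLUMNS: tuple[str, ...] = (
    "var_bseries_score",
    "var_dotprod_score",
    "var_intensity_score",
    "var_isotope_correlation_score",
    "var_isotope_overlap_score",
    "var_library_corr",
    "var_library_dotprod",
    "var_library_manhattan",
    "var_library_rmsd",
    "var_library_rootmeansquare",
    "var_library_sangle",
    "var_log_sn_score",
    "var_manhattan_score",
    "var_massdev_score",
    "var_massdev_score_weighted",
    "var_mi_score",
    "var_mi_weighted_score",
    "var_norm_rt_score",
    "var_xcorr_coelution",
    "var_xcorr_coelution_weighted",
    "var_xcorr_shape_weighted",
    "var_yseries_score",
)

#: Columns that must be present in every peak-group table.
MANDATORY_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "precursor_id",
    "peakgroup_rank",
    "peptide_id",
    "protein_group",
    "decoy",
    "retention_time",
    "intensity",
) + SUBSCORE_COLUMNS

#: Columns written when present; absent values are empty cells.
OPTIONAL_COLUMNS: tuple[str, ...] = (
    "dscore",
    "predicted_target",
    "qvalue_precursor",
    "truth_label",
    "species_tag",
)

TRUTH_LABELS = ("true_target", "false_target", "decoy")


@dataclass
class SampleTable:
    """All candidate peak groups of one sample (run).

    Parameters
    ----------
    sample_id
        Identifier of the run the records belong to.  Empty for an empty
        table.
    data
        One row per peak group.  Mandatory columns per
        :data:`MANDATORY_COLUMNS`; optional annotation columns are kept
        as-is.
    feature_names
        The subscore columns, in the canonical order used for model
        features.  Tables combined in one experiment must agree on this.
    """

    sample_id: str
    data: pd.DataFrame
    feature_names: tuple[str, ...] = SUBSCORE_COLUMNS

    def __post_init__(self) -> None:
        self.feature_names = tuple(self.feature_names)
        if len(self.data):
            ids = self.data["sample_id"].unique()
            if len(ids) > 1:
                raise MalformedValue(
                    f"table mixes sample_ids {sorted(map(str, ids))!r}"
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def is_scored(self) -> bool:
        return "dscore" in self.data.columns and not self.data["dscore"].isna().any()

    def targets(self) -> pd.DataFrame:
        return self.data[self.data["decoy"] == 0]

    def decoys(self) -> pd.DataFrame:
        return self.data[self.data["decoy"] == 1]

    def features(self, rows: pd.DataFrame | None = None) -> np.ndarray:
        """Subscore matrix (n_records, 22) in canonical column order."""
        frame = self.data if rows is None else rows
        return frame.loc[:, list(self.feature_names)].to_numpy(dtype=np.float64)

    def with_data(self, data: pd.DataFrame) -> "SampleTable":
        return SampleTable(self.sample_id, data, self.feature_names)


def _coerce_schema(df: pd.DataFrame, path: str) -> pd.DataFrame:
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise MissingColumn(f"{path}: missing mandatory column {col!r}")
    if len(df) == 0:
        return df
    df = df.copy()
    df["peakgroup_rank"] = df["peakgroup_rank"].astype(np.int64)
    df["decoy"] = df["decoy"].astype(np.int64)
    for col in ("retention_time", "intensity") + SUBSCORE_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    sub = df.loc[:, list(SUBSCORE_COLUMNS)].to_numpy(dtype=np.float64)
    bad = ~np.isfinite(sub)
    if bad.any():
        row, col = np.argwhere(bad)[0]
        raise MalformedValue(
            f"{path}: non-finite subscore {SUBSCORE_COLUMNS[col]!r} "
            f"in data row {row}"
        )
    for col in ("dscore", "qvalue_precursor"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "predicted_target" in df.columns:
        df["predicted_target"] = (
            pd.to_numeric(df["predicted_target"], errors="coerce").astype("Int64")
        )
    return df


def read_peakgroups(path, dialect: str = "tsv") -> SampleTable:
    """Read a peak-group table from a TSV file.

    Raises :class:`MissingColumn` when a mandatory column is absent and
    :class:`MalformedValue` when a subscore is non-finite (the offending
    row index is reported).  A header-only file yields an empty table.
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", header=0)
    df = _coerce_schema(df, str(path))
    sample_id = str(df["sample_id"].iloc[0]) if len(df) else ""
    return SampleTable(sample_id, df.reset_index(drop=True))


def _ordered_columns(df: pd.DataFrame) -> list[str]:
    known = list(MANDATORY_COLUMNS) + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in known]
    return known + extra


def write_scored(table: SampleTable, path) -> None:
    """Write a scored table as TSV; round-trips through :func:`read_peakgroups`.

    Every record must carry a discriminant score (``dscore``); q-values and
    prediction flags are optional.  Absent intensities become empty cells.
    """
    df = table.data
    if "dscore" not in df.columns or (len(df) and df["dscore"].isna().any()):
        raise NotScored("table has records without a dscore; score it first")
    out = df.copy()
    if "predicted_target" in out.columns:
        out["predicted_target"] = out["predicted_target"].astype("Int64")
    out.loc[:, _ordered_columns(out)].to_csv(path, sep="\t", index=False, na_rep="")


def write_peakgroups(table: SampleTable, path) -> None:
    """Write a (possibly unscored) table as TSV."""
    df = table.data
    out = df.loc[:, _ordered_columns(df)] if len(df) else df
    out.to_csv(path, sep="\t", index=False, na_rep="")


def select_best_peakgroup(table: SampleTable) -> SampleTable:
    """Keep the highest-scoring candidate peak group per precursor.

    Ties on the score are broken by the lowest ``peakgroup_rank``, then by
    input order, so the selection is deterministic and stable.
    """
    df = table.data
    if "dscore" not in df.columns or (len(df) and df["dscore"].isna().any()):
        raise NotScored("select_best_peakgroup requires a fully scored table")
    if len(df) == 0:
        return table.with_data(df.copy())
    df = df.reset_index(drop=True)
    order = df.sort_values(
        ["precursor_id", "dscore", "peakgroup_rank"],
        ascending=[True, False, True],
        kind="stable",
    )
    best = order.drop_duplicates("precursor_id", keep="first")
    best = best.sort_index().reset_index(drop=True)
    return table.with_data(best)


def concat_tables(tables: Iterable[SampleTable]) -> pd.DataFrame:
    """Stack the records of several samples into one frame."""
    frames = [t.data for t in tables if len(t.data)]
    if not frames:
        raise EmptyInput("no records in any input table")
    return pd.concat(frames, ignore_index=True)


def tables_equal(a: SampleTable, b: SampleTable, rtol: float = 1e-9) -> bool:
    """Field-for-field equality: exact on text/integers, ``rtol`` on reals."""
    da, db = a.data, b.data
    if list(da.columns) != list(db.columns) or len(da) != len(db):
        return False
    for col in da.columns:
        xa, xb = da[col], db[col]
        if pd.api.types.is_float_dtype(xa) or pd.api.types.is_float_dtype(xb):
            va = pd.to_numeric(xa).to_numpy(dtype=float)
            vb = pd.to_numeric(xb).to_numpy(dtype=float)
            both_nan = np.isnan(va) & np.isnan(vb)
            close = np.isclose(va, vb, rtol=rtol, atol=0.0, equal_nan=True)
            if not np.all(close | both_nan):
                return False
        else:
            if not (
                (xa.isna() & xb.isna()) | (xa.astype(object) == xb.astype(object))
            ).all():
                return False
    return True
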