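"""Annotated quantitative matrix and evaluation metrics.

The matrix is precursor x sample: a cell is present only when that
sample's record passed the precursor-level q-value cutoff, and a row
survives only if its peptide and protein pass their global cutoffs.
Missing cells stay missing — no zero imputation here; downstream tooling
decides how to treat absence.

Evaluation covers the three checks used to judge a validator without
ground truth from real data:

* missingness — the fraction of absent cells in the retained matrix;
* entrapment FDR — identifications of a species known to be absent,
  divided by all identifications, as a function of the q cutoff;
* ratio validation — in a two-group spike-in design, the fraction of
  rows whose between-group log2 fold change lands within a tolerance of
  the species' expected ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInput
from .fdr import GlobalLevelModel
from .io_model import SampleTable

ANNOTATION_COLUMNS = (
    "peptide_id",
    "protein_group",
    "species_tag",
    "qvalue_peptide_global",
    "qvalue_protein_global",
)


@dataclass
class QuantMatrix:
    """Precursor x sample intensity matrix with q-value annotations.

    ``values``: float frame indexed by precursor_id, one column per
    sample, NaN = absent.  ``annotations``: per-precursor peptide/protein
    keys, optional species tag and the global q-values.  Decoys are never
    part of a matrix, and every retained row passed its per-sample cutoff
    in at least one sample.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    @property
    def n_precursors(self) -> int:
        return len(self.values)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        wide = pd.concat([self.annotations, self.values], axis=1)
        wide.index.name = "precursor_id"
        wide.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_tsv(cls, path) -> "QuantMatrix":
        wide = pd.read_csv(path, sep="\t", index_col="precursor_id")
        ann_cols = [c for c in ANNOTATION_COLUMNS if c in wide.columns]
        return cls(
            values=wide.drop(columns=ann_cols).astype(np.float64),
            annotations=wide.loc[:, ann_cols],
        )


def build_matrix(
    samples: Iterable[SampleTable],
    peptide_model: GlobalLevelModel,
    protein_model: GlobalLevelModel,
    precursor_q: float = 0.01,
    peptide_q: float = 0.01,
    protein_q: float = 0.01,
) -> QuantMatrix:
    """Assemble the filtered, annotated quantitative matrix.

    A cell is present iff the sample's (best) record for that precursor
    has ``qvalue_precursor`` <= ``precursor_q``.  Rows whose global
    peptide or protein q-value exceeds its cutoff are dropped entirely,
    as are decoys and rows with no passing cell.
    """
    for name, thr in (
        ("precursor_q", precursor_q),
        ("peptide_q", peptide_q),
        ("protein_q", protein_q),
    ):
        if not 0.0 <= thr <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {thr}")

    cells = []
    for table in samples:
        df = table.data
        if "qvalue_precursor" not in df.columns:
            raise EmptyInput(
                f"sample {table.sample_id!r} lacks per-record q-values"
            )
        ok = (df["decoy"] == 0) & (df["qvalue_precursor"] <= precursor_q)
        sub = df.loc[
            ok,
            ["sample_id", "precursor_id", "peptide_id", "protein_group", "intensity"]
            + (["species_tag"] if "species_tag" in df.columns else []),
        ]
        cells.append(sub)
    if not cells:
        raise EmptyInput("no samples given")
    long = pd.concat(cells, ignore_index=True)
    if len(long) == 0:
        raise EmptyInput("no record passed the precursor q cutoff in any sample")

    values = long.pivot_table(
        index="precursor_id",
        columns="sample_id",
        values="intensity",
        aggfunc="first",
        dropna=False,
    )
    values.columns.name = None

    ann = (
        long.drop(columns=["sample_id", "intensity"])
        .drop_duplicates("precursor_id")
        .set_index("precursor_id")
        .reindex(values.index)
    )
    if "species_tag" not in ann.columns:
        ann["species_tag"] = np.nan
    ann["qvalue_peptide_global"] = peptide_model.lookup(ann["peptide_id"])
    ann["qvalue_protein_global"] = protein_model.lookup(ann["protein_group"])

    keep = (ann["qvalue_peptide_global"] <= peptide_q) & (
        ann["qvalue_protein_global"] <= protein_q
    )
    values = values.loc[keep.fillna(False)]
    ann = ann.loc[keep.fillna(False), list(ANNOTATION_COLUMNS)]
    return QuantMatrix(values=values, annotations=ann)


def missingness(matrix: QuantMatrix) -> float:
    """Fraction of absent cells in the matrix."""
    total = matrix.values.size
    if total == 0:
        raise EmptyInput("empty quantitative matrix")
    return float(matrix.values.isna().to_numpy().sum()) / total


@dataclass
class EntrapmentReport:
    """Entrapment FDR per q cutoff: absent-species ids / all ids."""

    true_species: str
    table: pd.DataFrame  # columns: threshold, total, entrapment, entrapment_fdr


def entrapment_curve(
    identifications: pd.DataFrame,
    true_species: str,
    thresholds: Sequence[float] = (0.01, 0.02, 0.05, 0.1),
) -> EntrapmentReport:
    """Empirical FDR from an entrapment species at each q cutoff.

    ``identifications`` needs a ``species_tag`` and a ``qvalue`` column
    (target records only).  The entrapment FDR at cutoff t is the number
    of identifications whose species differs from ``true_species``
    divided by all identifications with qvalue <= t; it is NaN (flagged,
    not zero) when nothing passes.
    """
    if identifications["species_tag"].isna().any():
        raise ValueError("every identification needs a species_tag")
    q = identifications["qvalue"].to_numpy(dtype=np.float64)
    entrap = (identifications["species_tag"] != true_species).to_numpy()
    rows = []
    for t in thresholds:
        passed = q <= t
        total = int(passed.sum())
        n_entrap = int((passed & entrap).sum())
        rows.append(
            {
                "threshold": t,
                "total": total,
                "entrapment": n_entrap,
                "entrapment_fdr": n_entrap / total if total else np.nan,
            }
        )
    return EntrapmentReport(true_species=true_species, table=pd.DataFrame(rows))


@dataclass
class RatioReport:
    """Spike-in ratio validation at a given tolerance.

    ``per_precursor`` holds one row per evaluable matrix row with its
    log2 fold change, expected value and validated flag;
    ``n_not_quantified`` counts rows absent from one whole group (no
    computable ratio).  ``counts`` aggregates validated precursors,
    peptides (any validated precursor) and proteins (any validated
    peptide).  ``curve`` evaluates the validated count and the
    out-of-window fraction on a tolerance grid.
    """

    tolerance: float
    per_precursor: pd.DataFrame
    counts: dict
    curve: pd.DataFrame
    n_not_quantified: int


def ratio_validation(
    matrix: QuantMatrix,
    design: Mapping[str, str],
    expected: Mapping[str, float],
    tolerance: float = 0.2,
    groups: tuple[str, str] | None = None,
    tolerance_grid: Sequence[float] | None = None,
    log_of_means: bool = True,
) -> RatioReport:
    """Validate between-group ratios against the species' expected log2FC.

    ``design`` maps sample_id to group; ``groups`` fixes (reference,
    comparison) order, defaulting to the sorted group names.  The fold
    change is log2 of the ratio of group mean intensities over present
    cells (set ``log_of_means=False`` for the mean-of-logs variant).  A
    row needs at least one quantified replicate per group; rows absent
    from a whole group are excluded and counted separately.
    """
    group_names = groups or tuple(sorted(set(design.values())))
    if len(group_names) != 2:
        raise ConfigurationError("ratio validation needs exactly two groups")
    ref, comp = group_names
    cols_ref = [s for s in matrix.sample_ids if design.get(s) == ref]
    cols_comp = [s for s in matrix.sample_ids if design.get(s) == comp]
    if not cols_ref or not cols_comp:
        raise ConfigurationError("each group needs at least one sample column")

    vals = matrix.values
    n_ref = vals[cols_ref].notna().sum(axis=1)
    n_comp = vals[cols_comp].notna().sum(axis=1)
    quantifiable = (n_ref >= 1) & (n_comp >= 1)
    n_not_quantified = int((~quantifiable).sum())

    sub = vals.loc[quantifiable]
    if log_of_means:
        # log2 of the ratio (not difference of logs): exact when the group
        # means are in an exact power-of-two ratio, as in noise-free spikes
        lfc = np.log2(sub[cols_comp].mean(axis=1) / sub[cols_ref].mean(axis=1))
    else:
        lfc = np.log2(sub[cols_comp]).mean(axis=1) - np.log2(sub[cols_ref]).mean(
            axis=1
        )
    ann = matrix.annotations.loc[quantifiable]
    expected_lfc = ann["species_tag"].map(expected).to_numpy(dtype=np.float64)
    dev = np.abs(lfc.to_numpy(dtype=np.float64) - expected_lfc)
    validated = dev <= tolerance

    per = pd.DataFrame(
        {
            "peptide_id": ann["peptide_id"].to_numpy(),
            "protein_group": ann["protein_group"].to_numpy(),
            "species_tag": ann["species_tag"].to_numpy(),
            "log2fc": lfc.to_numpy(dtype=np.float64),
            "expected_log2fc": expected_lfc,
            "validated": validated,
        },
        index=sub.index,
    )
    counts = {
        "precursors": int(validated.sum()),
        "peptides": int(per.loc[per["validated"], "peptide_id"].nunique()),
        "proteins": int(
            per.loc[per["validated"], "protein_group"].nunique()
        ),
        "evaluated": int(len(per)),
    }
    grid = (
        np.asarray(tolerance_grid, dtype=np.float64)
        if tolerance_grid is not None
        else np.round(np.arange(0.05, 1.0001, 0.05), 2)
    )
    curve = pd.DataFrame(
        {
            "tolerance": grid,
            "validated": [(dev <= t).sum() for t in grid],
            "out_of_window_fraction": [(dev > t).mean() for t in grid],
        }
    )
    return RatioReport(
        tolerance=tolerance,
        per_precursor=per,
        counts=counts,
        curve=curve,
        n_not_quantified=n_not_quantified,
    )
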