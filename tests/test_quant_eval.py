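"""Quantitative matrix construction and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

from gpscore.errors import ConfigurationError, EmptyInput
from gpscore.fdr import GlobalLevelModel
from gpscore.quant_eval import (
    QuantMatrix,
    build_matrix,
    entrapment_curve,
    missingness,
    ratio_validation,
)
from gpscore.synthetic import simulate_spikein

from conftest import make_table


def _global_model(level, qmap):
    keys = list(qmap)
    table = pd.DataFrame(
        {"dscore": 0.0, "decoy": 0, "qvalue": [qmap[k] for k in keys]},
        index=pd.Index(keys, name="group_key"),
    )
    return GlobalLevelModel(
        level=level,
        table=table,
        score_axis=np.array([0.0, 1.0]),
        q_axis=np.array([1.0, 0.0]),
        method="counting",
    )


def _sample_with_q(sample_id, qvalues, seed):
    """Ten-precursor table with hand-assigned per-record q-values."""
    table = make_table(n_targets=10, seed=seed, sample_id=sample_id)
    df = table.data.copy()
    df["dscore"] = 1.0
    df["qvalue_precursor"] = qvalues
    return table.with_data(df)


@pytest.fixture()
def toy_matrix_inputs():
    rng = np.random.default_rng(11)
    samples = [
        _sample_with_q(f"S{j}", rng.choice([0.001, 0.05], size=10), seed=50 + j)
        for j in range(4)
    ]
    peptides = {f"PEP{i:04d}": 0.001 for i in range(10)}
    proteins = {f"PROT{i:03d}": 0.001 for i in range(4)}
    return samples, _global_model("peptide", peptides), _global_model(
        "protein", proteins
    )


def test_matrix_matches_bruteforce_filter(toy_matrix_inputs):
    samples, pep_model, prot_model = toy_matrix_inputs
    matrix = build_matrix(samples, pep_model, prot_model, precursor_q=0.01)

    expected_cells = {}
    for t in samples:
        for _, row in t.data.iterrows():
            if row["decoy"] == 0 and row["qvalue_precursor"] <= 0.01:
                expected_cells[(row["precursor_id"], row["sample_id"])] = row[
                    "intensity"
                ]
    assert set(matrix.values.index) == {k[0] for k in expected_cells}
    for (pid, sid), inten in expected_cells.items():
        assert matrix.values.loc[pid, sid] == pytest.approx(inten)
    present = matrix.values.notna().sum().sum()
    assert present == len(expected_cells)


def test_matrix_drops_rows_failing_global_cutoffs(toy_matrix_inputs):
    samples, pep_model, prot_model = toy_matrix_inputs
    prot_model.table.loc["PROT000", "qvalue"] = 0.02  # above the 0.01 cutoff
    matrix = build_matrix(samples, pep_model, prot_model, precursor_q=0.01)
    assert not (matrix.annotations["protein_group"] == "PROT000").any()


def test_matrix_rejects_bad_threshold(toy_matrix_inputs):
    samples, pep_model, prot_model = toy_matrix_inputs
    with pytest.raises(ConfigurationError):
        build_matrix(samples, pep_model, prot_model, precursor_q=1.5)


def test_matrix_build_is_idempotent(toy_matrix_inputs):
    samples, pep_model, prot_model = toy_matrix_inputs
    matrix = build_matrix(samples, pep_model, prot_model, precursor_q=0.01)
    # feed the surviving cells back through the same filter
    rebuilt_samples = []
    for t in samples:
        df = t.data.copy()
        keep = [
            pid in matrix.values.index
            and not pd.isna(matrix.values.loc[pid, t.sample_id])
            for pid in df["precursor_id"]
        ]
        rebuilt_samples.append(t.with_data(df.loc[keep].reset_index(drop=True)))
    rebuilt = build_matrix(rebuilt_samples, pep_model, prot_model, precursor_q=0.01)
    assert rebuilt.values.equals(matrix.values)


def test_missingness_counts_absent_cells():
    values = pd.DataFrame(np.ones((5, 4)), columns=list("abcd"))
    values.iloc[0, 0] = np.nan
    values.iloc[1, :3] = np.nan
    matrix = QuantMatrix(values=values, annotations=pd.DataFrame(index=values.index))
    assert missingness(matrix) == pytest.approx(4 / 20)
    full = QuantMatrix(
        values=pd.DataFrame(np.ones((2, 2))), annotations=pd.DataFrame()
    )
    assert missingness(full) == 0.0
    with pytest.raises(EmptyInput):
        missingness(
            QuantMatrix(values=pd.DataFrame(), annotations=pd.DataFrame())
        )


def test_entrapment_fraction_and_monotone_counts():
    ids = pd.DataFrame(
        {
            "species_tag": ["mouse"] * 95 + ["yeast"] * 5,
            "qvalue": np.concatenate(
                [np.linspace(0, 0.009, 95), np.full(5, 0.008)]
            ),
        }
    )
    report = entrapment_curve(ids, "mouse", thresholds=(0.01, 0.05))
    assert report.table.loc[0, "entrapment_fdr"] == pytest.approx(0.05)
    assert (report.table["total"].diff().dropna() >= 0).all()

    clean = pd.DataFrame({"species_tag": ["mouse"] * 10, "qvalue": [0.001] * 10})
    assert entrapment_curve(clean, "mouse").table["entrapment_fdr"].eq(0.0).all()

    empty_pass = pd.DataFrame({"species_tag": ["mouse"], "qvalue": [0.5]})
    assert np.isnan(
        entrapment_curve(empty_pass, "mouse", thresholds=(0.01,)).table[
            "entrapment_fdr"
        ].iloc[0]
    )


def _spikein_matrix(noise_sd, n_replicates=3, seed=60, missing_rate=0.0):
    tables, lib = simulate_spikein(
        n_replicates=n_replicates,
        precursors_per_sample=200,
        decoys_per_sample=50,
        log_intensity_noise_sd=noise_sd,
        missing_rate=missing_rate,
        seed=seed,
    )
    frames = []
    for t in tables:
        df = t.data
        rank1 = df[(df["decoy"] == 0) & (df["peakgroup_rank"] == 1)]
        frames.append(
            rank1[["sample_id", "precursor_id", "intensity"]]
        )
    long = pd.concat(frames)
    values = long.pivot(index="precursor_id", columns="sample_id", values="intensity")
    values.columns.name = None
    ann = lib.set_index("precursor_id").loc[
        values.index, ["peptide_id", "protein_group", "species_tag"]
    ]
    ann["qvalue_peptide_global"] = 0.0
    ann["qvalue_protein_global"] = 0.0
    design = {t.sample_id: t.data["group"].iloc[0] for t in tables}
    return QuantMatrix(values=values, annotations=ann), design


def test_ratio_validation_flags_and_exclusions():
    matrix, design = _spikein_matrix(noise_sd=0.05)
    # a row quantified in only one group is excluded, counted separately
    b_cols = [s for s, g in design.items() if g == "B"]
    matrix.values.loc[matrix.values.index[0], b_cols] = np.nan
    report = ratio_validation(
        matrix,
        design,
        expected={"mouse": 0.0, "yeast": 2.0},
        tolerance=0.2,
        groups=("A", "B"),
    )
    assert report.n_not_quantified == 1
    assert report.counts["evaluated"] == len(matrix.values) - 1
    assert report.counts["precursors"] >= 0.9 * report.counts["evaluated"]
    # validated-count curve is monotone non-decreasing in tolerance
    assert (report.curve["validated"].diff().dropna() >= 0).all()
    assert (report.curve["out_of_window_fraction"].diff().dropna() <= 0).all()


def test_noise_free_spikein_gives_exact_log2fc():
    matrix, design = _spikein_matrix(noise_sd=0.0)
    report = ratio_validation(
        matrix, design, expected={"mouse": 0.0, "yeast": 2.0}, groups=("A", "B")
    )
    yeast = report.per_precursor[report.per_precursor["species_tag"] == "yeast"]
    assert (yeast["log2fc"] == 2.0).all()
    mouse = report.per_precursor[report.per_precursor["species_tag"] == "mouse"]
    assert (mouse["log2fc"] == 0.0).all()


def test_borderline_ratio_validated_only_at_wider_tolerance():
    values = pd.DataFrame(
        {"A_0": [1000.0], "B_0": [1000.0 * 2**1.7]},
        index=pd.Index(["P1"], name="precursor_id"),
    )
    ann = pd.DataFrame(
        {
            "peptide_id": ["pep1"],
            "protein_group": ["prot1"],
            "species_tag": ["yeast"],
            "qvalue_peptide_global": [0.0],
            "qvalue_protein_global": [0.0],
        },
        index=values.index,
    )
    matrix = QuantMatrix(values=values, annotations=ann)
    design = {"A_0": "A", "B_0": "B"}
    narrow = ratio_validation(
        matrix, design, {"yeast": 2.0}, tolerance=0.2, groups=("A", "B")
    )
    wide = ratio_validation(
        matrix, design, {"yeast": 2.0}, tolerance=0.35, groups=("A", "B")
    )
    assert narrow.counts["precursors"] == 0
    assert wide.counts["precursors"] == 1


def test_matrix_tsv_roundtrip(tmp_path, toy_matrix_inputs):
    samples, pep_model, prot_model = toy_matrix_inputs
    matrix = build_matrix(samples, pep_model, prot_model, precursor_q=0.01)
    path = tmp_path / "matrix.tsv"
    matrix.to_tsv(path)
    back = QuantMatrix.from_tsv(path)
    pd.testing.assert_frame_equal(matrix.values, back.values, check_names=False)
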