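"""q-value estimators and global rollup."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpscore.errors import EmptyInput, TooFewRecords
from gpscore.fdr import (
    GlobalLevelModel,
    annotate_sample_qvalues,
    fit_score_distributions,
    global_rollup,
    qvalues_counting,
    qvalues_spline,
)

from conftest import make_table


def bruteforce_qvalues(targets, decoys):
    """Enumerate every threshold at a target score; q(s) = min FDR over
    thresholds t <= s."""
    targets = np.asarray(targets, float)
    decoys = np.asarray(decoys, float)
    out = np.empty_like(targets)
    for i, s in enumerate(targets):
        fdrs = []
        for t in targets[targets <= s]:
            D = (decoys >= t).sum()
            T = (targets >= t).sum()
            fdrs.append(D / (T + D))
        out[i] = min(fdrs)
    return np.clip(out, 0.0, 1.0)


def test_counting_hand_count_oracles():
    np.testing.assert_allclose(
        qvalues_counting([3, 2, 1], [1.5]), [0.0, 0.0, 0.25]
    )
    np.testing.assert_allclose(qvalues_counting([1, 1], [2]), [1 / 3, 1 / 3])
    np.testing.assert_allclose(qvalues_counting([5, 1], []), [0.0, 0.0])
    with pytest.raises(EmptyInput):
        qvalues_counting([], [1.0])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    t=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=30),
    d=st.lists(st.floats(-5, 5, allow_nan=False), min_size=0, max_size=30),
)
def test_counting_matches_bruteforce_and_is_monotone(t, d):
    q = qvalues_counting(t, d)
    np.testing.assert_allclose(q, bruteforce_qvalues(t, d), atol=1e-12)
    assert (q >= 0).all() and (q <= 1).all()
    order = np.argsort(t)
    assert (np.diff(q[order]) <= 1e-12).all()


def test_density_fit_normalization_and_moments():
    rng = np.random.default_rng(1)
    d = rng.standard_normal(10000)
    t = rng.normal(2, 1, 10000)
    dist = fit_score_distributions(t, d)
    g = dist.score_grid
    assert abs(np.trapezoid(dist.decoy_density, g) - 1.0) <= 1e-3
    assert abs(np.trapezoid(dist.target_density, g) - 1.0) <= 1e-3
    mean_d = np.trapezoid(g * dist.decoy_density, g)
    assert abs(mean_d) <= 0.05
    assert (dist.decoy_density >= 0).all() and (dist.target_density >= 0).all()


def test_density_fit_guards_small_samples():
    with pytest.raises(TooFewRecords):
        fit_score_distributions(np.arange(10.0), np.arange(10.0))


def test_identical_samples_give_matching_densities():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(5000)
    dist = fit_score_distributions(x, x.copy())
    assert np.max(np.abs(dist.target_density - dist.decoy_density)) <= 0.05


def test_spline_boundary_values():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(2000)
    dist = fit_score_distributions(x, x.copy())
    lo = dist.score_grid[0]
    hi = dist.score_grid[-1]
    q_lo = qvalues_spline(dist, [lo])[0]
    # full tails: raw FDR = D/(T+D) with both classes complete
    assert q_lo == pytest.approx(
        dist.decoy_count / (dist.target_count + dist.decoy_count), abs=1e-9
    )
    assert qvalues_spline(dist, [hi])[0] == pytest.approx(0.0, abs=1e-9)


def test_spline_agrees_with_counting_in_confident_region():
    rng = np.random.default_rng(4)
    t = rng.normal(2, 1, 10000)
    d = rng.normal(0, 1, 10000)
    qc = qvalues_counting(t, d)
    qs = qvalues_spline(fit_score_distributions(t, d), t)
    region = qc <= 0.1
    assert np.abs(qs - qc)[region].max() <= 0.01


def test_no_pi0_downweighting_with_equal_samples():
    rng = np.random.default_rng(5)
    x = rng.standard_normal(5000)
    q = qvalues_counting(x, x.copy())
    assert q[np.argmin(x)] == pytest.approx(0.5)


def _scored_tables(seed, n=100, samples=2):
    rng = np.random.default_rng(seed)
    out = []
    for s in range(samples):
        table = make_table(n_targets=n, n_decoys=n, seed=seed + s, sample_id=f"S{s}")
        df = table.data.copy()
        shift = np.where(df["decoy"] == 0, 2.0, 0.0)
        df["dscore"] = rng.standard_normal(len(df)) + shift
        out.append(table.with_data(df))
    return out


def test_global_rollup_uses_max_score_per_group():
    tables = _scored_tables(6)
    model = global_rollup(tables, "peptide")
    df = pd.concat([t.data for t in tables])
    for key, grp in df.groupby("peptide_id"):
        assert model.table.loc[key, "dscore"] == grp["dscore"].max()
    # decoy groups populate the decoy side of the rollup
    assert (model.table["decoy"] == 1).sum() == 100


def test_global_rollup_qvalues_match_counting_oracle():
    tables = _scored_tables(7, n=200)
    model = global_rollup(tables, "peptide")
    reps = model.table
    t = reps.loc[reps["decoy"] == 0, "dscore"].to_numpy()
    d = reps.loc[reps["decoy"] == 1, "dscore"].to_numpy()
    oracle = qvalues_counting(t, d)
    got = reps.loc[reps["decoy"] == 0, "qvalue"].to_numpy()
    assert np.abs(got - oracle).max() <= 0.01


def test_global_model_roundtrips_bit_exact(tmp_path):
    model = global_rollup(_scored_tables(8), "protein")
    p1, p2 = tmp_path / "g1.json", tmp_path / "g2.json"
    model.save(p1)
    loaded = GlobalLevelModel.load(p1)
    loaded.save(p2)
    assert p1.read_bytes() == p2.read_bytes()
    keys = model.table.index[:5]
    assert np.array_equal(model.lookup(keys), loaded.lookup(keys))


def test_annotated_sample_qvalues_are_monotone_in_score():
    table = _scored_tables(9, n=300, samples=1)[0]
    out = annotate_sample_qvalues(table, method="counting")
    df = out.data[out.data["decoy"] == 0].sort_values("dscore")
    assert (np.diff(df["qvalue_precursor"].to_numpy()) <= 1e-12).all()
    assert df["qvalue_precursor"].between(0, 1).all()
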