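"""Shared fixtures: small simulated experiments and trained models.

Everything is generated programmatically at collection time from fixed
seeds; no fixture files are read from disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gpscore.denoise import DenoiseConfig, denoise_sample
from gpscore.io_model import SUBSCORE_COLUMNS, SampleTable
from gpscore.synthetic import SimulationConfig, simulate_experiment
from gpscore.train import TrainingConfig, assemble_training_set, train_classifier


def make_table(
    n_targets: int = 0,
    n_decoys: int = 0,
    seed: int = 0,
    sample_id: str = "S1",
    target_shift: float = 0.0,
    candidates: int = 1,
) -> SampleTable:
    """Hand-rolled tiny table with standard-normal subscores."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_targets):
        for rank in range(1, candidates + 1):
            rows.append(
                {
                    "sample_id": sample_id,
                    "precursor_id": f"PEP{i:04d}_2",
                    "peakgroup_rank": rank,
                    "peptide_id": f"PEP{i:04d}",
                    "protein_group": f"PROT{i // 3:03d}",
                    "decoy": 0,
                    "retention_time": float(rng.uniform(0, 100)),
                    "intensity": float(rng.uniform(1e4, 1e6)),
                }
            )
    for i in range(n_decoys):
        rows.append(
            {
                "sample_id": sample_id,
                "precursor_id": f"DECOY_PEP{i:04d}_2",
                "peakgroup_rank": 1,
                "peptide_id": f"DECOY_PEP{i:04d}",
                "protein_group": f"DECOY_PROT{i // 3:03d}",
                "decoy": 1,
                "retention_time": float(rng.uniform(0, 100)),
                "intensity": float(rng.uniform(1e3, 1e5)),
            }
        )
    df = pd.DataFrame(rows)
    feats = rng.standard_normal((len(df), len(SUBSCORE_COLUMNS)))
    if len(df):
        shift = np.where((df["decoy"] == 0) & (df["peakgroup_rank"] == 1), 1.0, 0.0)
        feats = feats + target_shift * shift[:, None]
    for j, col in enumerate(SUBSCORE_COLUMNS):
        df[col] = feats[:, j] if len(df) else pd.Series(dtype=float)
    return SampleTable(sample_id if len(df) else "", df)


@pytest.fixture(scope="session")
def small_experiment():
    """Six matched-library samples, half the targets true, 3-sigma effect."""
    config = SimulationConfig(
        n_samples=6,
        precursors_per_sample=1200,
        true_target_fraction=0.5,
        decoys_per_sample=1200,
        effect_size=3.0,
        seed=20,
    )
    return simulate_experiment(config)


@pytest.fixture(scope="session")
def small_denoised(small_experiment):
    tables, _ = small_experiment
    config = DenoiseConfig(k_folds=5, ensemble_size=5, seed=21)
    return [denoise_sample(t, config) for t in tables[:3]]


@pytest.fixture(scope="session")
def svm_model(small_denoised):
    pool = assemble_training_set(small_denoised)
    return train_classifier(pool, TrainingConfig(model_kind="svm", seed=22))


@pytest.fixture(scope="session")
def gbt_model(small_denoised):
    pool = assemble_training_set(small_denoised)
    return train_classifier(pool, TrainingConfig(model_kind="gbt", seed=22))
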