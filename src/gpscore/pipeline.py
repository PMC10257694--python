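"""End-to-end workflow wiring: simulate -> denoise -> train -> score ->
combine -> matrix -> evaluate.

Each stage is a thin call into the corresponding library module; the
pipeline only moves tables between them, writes artifacts, and records a
manifest (config hash, seed, software version, per-stage counts) so a
rerun with the same config and seed reproduces the artifact tree
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from . import __version__
from .denoise import DenoiseConfig, denoise_sample
from .errors import ConfigurationError
from .fdr import annotate_sample_qvalues, global_rollup
from .io_model import select_best_peakgroup, write_peakgroups, write_scored
from .quant_eval import build_matrix, entrapment_curve, missingness, ratio_validation
from .score import compute_dscore, predict_targets
from .synthetic import SimulationConfig, simulate_experiment
from .train import TrainingConfig, assemble_training_set, train_classifier


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError("pipeline config must be a mapping")
    return config


def run_pipeline(config: dict, out_dir, seed: int) -> dict:
    """Run the full workflow described by ``config`` under ``out_dir``.

    Required config sections: ``simulate`` (SimulationConfig fields) and
    ``n_train_samples``.  Optional: ``denoise``, ``train``,
    ``predict_threshold``, ``thresholds`` (precursor_q/peptide_q/
    protein_q) and ``evaluate`` (``entrapment`` and/or ``ratios``).
    Returns the manifest, which is also written as ``manifest.json``.
    """
    out = Path(out_dir)
    (out / "samples").mkdir(parents=True, exist_ok=True)
    (out / "reports").mkdir(exist_ok=True)

    if "simulate" not in config:
        raise ConfigurationError("config is missing the 'simulate' section")
    if "n_train_samples" not in config:
        raise ConfigurationError("config is missing 'n_train_samples'")

    sim_cfg = SimulationConfig(**config["simulate"], seed=seed)
    tables, truth = simulate_experiment(sim_cfg)
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)

    n_train = int(config["n_train_samples"])
    if not 0 < n_train < len(tables):
        raise ConfigurationError(
            "n_train_samples must leave at least one evaluation sample"
        )
    train_tables, eval_tables = tables[:n_train], tables[n_train:]

    den_cfg = DenoiseConfig(**config.get("denoise", {}), seed=seed + 1)
    denoised = []
    counts = {"denoise": []}
    for t in train_tables:
        d = denoise_sample(t, den_cfg)
        denoised.append(d)
        counts["denoise"].append(
            {
                "sample_id": t.sample_id,
                "targets_in": int((t.data["decoy"] == 0).sum()),
                "targets_kept": int((d.data["decoy"] == 0).sum()),
            }
        )
        write_peakgroups(d, out / "samples" / f"{t.sample_id}.denoised.tsv")

    train_cfg = TrainingConfig(**config.get("train", {}), seed=seed + 2)
    pool = assemble_training_set(denoised)
    model = train_classifier(pool, train_cfg)
    model.save(out / "model.gps")

    threshold = float(config.get("predict_threshold", 0.5))
    qmethod = config.get("qvalue_method", "auto")
    scored_best = []
    counts["score"] = []
    for t in eval_tables:
        scored = compute_dscore(model, t)
        _, gated = predict_targets(model, scored, threshold)
        best = select_best_peakgroup(gated)
        best = annotate_sample_qvalues(best, method=qmethod)
        scored_best.append(best)
        counts["score"].append(
            {
                "sample_id": t.sample_id,
                "records_in": len(t),
                "gated": len(gated),
                "q_le_0.01": int(
                    (
                        (best.data["decoy"] == 0)
                        & (best.data["qvalue_precursor"] <= 0.01)
                    ).sum()
                ),
            }
        )
        write_scored(best, out / "samples" / f"{t.sample_id}.scored.tsv")

    peptide_model = global_rollup(scored_best, "peptide")
    protein_model = global_rollup(scored_best, "protein")
    peptide_model.save(out / "peptide.global.json")
    protein_model.save(out / "protein.global.json")

    thr = config.get("thresholds", {})
    matrix = build_matrix(
        scored_best,
        peptide_model,
        protein_model,
        precursor_q=float(thr.get("precursor_q", 0.01)),
        peptide_q=float(thr.get("peptide_q", 0.01)),
        protein_q=float(thr.get("protein_q", 0.01)),
    )
    matrix.to_tsv(out / "matrix.tsv")
    counts["matrix"] = {
        "precursors": matrix.n_precursors,
        "samples": len(matrix.sample_ids),
        "missingness": missingness(matrix) if matrix.values.size else None,
    }

    evaluate = config.get("evaluate", {})
    if "entrapment" in evaluate:
        spec = evaluate["entrapment"]
        import pandas as pd

        ids = pd.concat(
            [
                b.data.loc[
                    b.data["decoy"] == 0,
                    ["species_tag", "qvalue_precursor"],
                ].rename(columns={"qvalue_precursor": "qvalue"})
                for b in scored_best
            ],
            ignore_index=True,
        )
        report = entrapment_curve(
            ids,
            true_species=spec["true_species"],
            thresholds=spec.get("thresholds", (0.01, 0.02, 0.05, 0.1)),
        )
        report.table.to_csv(out / "reports" / "entrapment.tsv", sep="\t", index=False)
        counts["entrapment"] = report.table.to_dict("records")
    if "ratios" in evaluate:
        spec = evaluate["ratios"]
        design = {
            t.sample_id: str(t.data["group"].iloc[0]) for t in eval_tables
        }
        report = ratio_validation(
            matrix,
            design=design,
            expected=spec["expected"],
            tolerance=float(spec.get("tolerance", 0.2)),
            groups=tuple(spec["groups"]) if "groups" in spec else None,
        )
        report.curve.to_csv(out / "reports" / "ratio_curve.tsv", sep="\t", index=False)
        counts["ratios"] = report.counts

    manifest = {
        "software": {"name": "gpscore", "version": __version__},
        "seed": seed,
        "config_hash": _config_hash(config),
        "counts": counts,
        "artifacts": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        ),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
    return manifest
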