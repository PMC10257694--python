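"""Training-label denoising by per-sample k-fold ensemble voting.

In a target-decoy DIA search every extracted target is initially labeled
positive, but a large fraction of those labels are wrong: the "false
targets" whose library entry is not present in the sample behave exactly
like decoys.  Training a classifier on the raw labels therefore trains it
on noise.

The denoiser removes those noisy positives sample by sample.  Targets are
split into k folds; for each held-out fold an ensemble of bagged logistic
scorers is fitted on the remaining targets (label 1) plus all decoys
(label 0), each member on its own full-size bootstrap resample with
per-bag feature standardization.  Members vote on the held-out targets: a
vote is positive when the member's predicted probability reaches
``vote_probability`` (a probability exactly at the threshold counts).
A target survives only if at least ``required_vote_fraction`` of members
vote positive — by default all of them.  Decoys, the negative training
set, are never filtered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import SGDClassifier

from .errors import DegenerateLabels, TooFewRecords
from .io_model import SampleTable


@dataclass
class DenoiseConfig:
    """Defaults follow the published recipe: ten folds, an ensemble of ten,
    a 0.75 vote-probability threshold, and unanimous voting."""

    k_folds: int = 10
    ensemble_size: int = 10
    vote_probability: float = 0.75
    required_vote_fraction: float = 1.0
    seed: int = 0


@dataclass
class VoteResult:
    """Per-record ensemble verdict for one held-out target."""

    index: int
    mean_probability: float
    vote_fraction: float


class _Member:
    """One bagged logistic scorer: per-bag scaler + SGD logistic fit."""

    __slots__ = ("mean", "scale", "clf")

    def __init__(self, X: np.ndarray, y: np.ndarray, seed: int) -> None:
        self.mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0
        self.scale = scale
        # iterate-averaged SGD: removes the single-pass gradient noise that
        # otherwise makes member probabilities jitter around the vote cut
        self.clf = SGDClassifier(
            loss="log_loss",
            penalty="l2",
            alpha=1e-4,
            max_iter=200,
            tol=1e-3,
            average=True,
            class_weight="balanced",
            random_state=seed,
        )
        self.clf.fit((X - self.mean) / self.scale, y)

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba((X - self.mean) / self.scale)[:, 1]


def assign_folds(table: SampleTable, k: int, seed: int) -> np.ndarray:
    """Fold label (0..k-1) per target record, in the order targets appear.

    Fold sizes differ by at most one; the same seed reproduces the same
    assignment.  Raises :class:`TooFewRecords` with fewer targets than
    folds.
    """
    n_targets = int((table.data["decoy"] == 0).sum())
    if n_targets < k:
        raise TooFewRecords(f"{n_targets} targets but {k} folds requested")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_targets)
    labels = np.empty(n_targets, dtype=np.int64)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        labels[chunk] = fold
    return labels


def train_vote_ensemble(
    X: np.ndarray, y: np.ndarray, n: int, seed: int
) -> list[_Member]:
    """Fit ``n`` bagged logistic members on a labeled partition.

    Each member trains on an independent bootstrap resample of the
    partition (same size, drawn with replacement).  Raises
    :class:`DegenerateLabels` if the partition holds a single class.
    """
    if len(np.unique(y)) < 2:
        raise DegenerateLabels("training partition contains a single class")
    seq = np.random.SeedSequence(seed)
    members = []
    for child in seq.spawn(n):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, len(y), size=len(y))
        while len(np.unique(y[idx])) < 2:  # resample a degenerate bag
            idx = rng.integers(0, len(y), size=len(y))
        members.append(_Member(X[idx], y[idx], int(rng.integers(2**31))))
    return members


def vote(
    ensemble: list[_Member], X: np.ndarray, vote_probability: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mean probability and positive-vote fraction per held-out record."""
    probs = np.stack([m.predict_probability(X) for m in ensemble])
    mean_probability = probs.mean(axis=0)
    vote_fraction = (probs >= vote_probability).mean(axis=0)
    return mean_probability, vote_fraction


def denoise_sample(
    table: SampleTable,
    config: DenoiseConfig | None = None,
    return_votes: bool = False,
):
    """Filter one sample's noisy target labels; decoys pass through intact.

    Returns a new :class:`SampleTable` containing every decoy record
    unchanged plus the targets whose vote fraction reached
    ``required_vote_fraction``.  With ``return_votes=True`` also returns
    the per-target :class:`VoteResult` list (aligned with target order).
    """
    config = config or DenoiseConfig()
    df = table.data.reset_index(drop=True)
    target_mask = (df["decoy"] == 0).to_numpy()
    target_idx = np.flatnonzero(target_mask)
    decoy_idx = np.flatnonzero(~target_mask)
    if len(target_idx) == 0 or len(decoy_idx) == 0:
        raise DegenerateLabels("sample needs both targets and decoys")

    folds = assign_folds(table, config.k_folds, config.seed)
    X_all = table.features(df)
    X_t = X_all[target_idx]
    X_d = X_all[decoy_idx]

    seq = np.random.SeedSequence(config.seed)
    fold_seeds = [int(s.generate_state(1)[0] % 2**31) for s in seq.spawn(config.k_folds)]

    mean_prob = np.empty(len(target_idx))
    vote_frac = np.empty(len(target_idx))
    for fold in range(config.k_folds):
        held = folds == fold
        X_train = np.vstack([X_t[~held], X_d])
        y_train = np.concatenate(
            [np.ones((~held).sum(), dtype=np.int64), np.zeros(len(X_d), dtype=np.int64)]
        )
        ensemble = train_vote_ensemble(
            X_train, y_train, config.ensemble_size, fold_seeds[fold]
        )
        mp, vf = vote(ensemble, X_t[held], config.vote_probability)
        mean_prob[held] = mp
        vote_frac[held] = vf

    keep_target = vote_frac >= config.required_vote_fraction
    keep_rows = np.zeros(len(df), dtype=bool)
    keep_rows[decoy_idx] = True
    keep_rows[target_idx[keep_target]] = True
    kept = df.loc[keep_rows].reset_index(drop=True)
    result = table.with_data(kept)
    if return_votes:
        votes = [
            VoteResult(int(i), float(p), float(f))
            for i, p, f in zip(target_idx, mean_prob, vote_frac)
        ]
        return result, votes
    return result
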