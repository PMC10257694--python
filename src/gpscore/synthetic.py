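"""Ground-truth-labeled DIA peak-group simulator.

Emulates the three evaluation regimes a search-space-agnostic validator has
to survive:

* a matched library, where roughly half the extracted targets are real;
* a large-search-space mismatch, where only a small fraction (~5%) of
  library targets are actually present in the sample;
* a two-species spike-in quantification design with known log2 fold
  changes per species (e.g. a constant background species at 0 and a
  spiked species at 2, i.e. a 4x spike).

The generative model is deliberately simple: each peak group carries a
22-dimensional Gaussian subscore vector with exchangeable correlation.
True targets are shifted by a standardized effect size on a subset of
"informative" features; false targets and decoys share one null
distribution, which is exactly the exchangeability assumption target-decoy
FDR estimation relies on.  Non-best candidate peak groups are drawn from
the null.  Intensities are log-normal around a per-precursor baseline with
a per-species group effect and missing-at-random dropout.

All randomness flows from one master seed through
:class:`numpy.random.SeedSequence` spawning, so a fixed seed reproduces
every table bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_model import SUBSCORE_COLUMNS, SampleTable

N_FEATURES = len(SUBSCORE_COLUMNS)


@dataclass
class SimulationConfig:
    """Parameters of one simulated experiment.

    ``true_target_fraction`` is the fraction of library targets genuinely
    present in the sample: ~0.5 models a matched spectral library, ~0.05
    the plasma-versus-tissue-library mismatch where almost every extracted
    target is false.  ``species_true_fraction`` overrides it per species,
    which is how an entrapment species (present in the library, absent
    from the sample) is expressed: its true fraction is 0.

    ``effect_size`` is the standardized mean shift applied to each of the
    ``n_informative`` informative subscores of a true target's best peak
    group; 3.0 gives the clearly bimodal target score distribution typical
    of well-extracted DIA data.
    """

    n_samples: int = 1
    precursors_per_sample: int = 5000
    true_target_fraction: float = 0.5
    decoys_per_sample: int = 5000
    candidate_peakgroups_per_precursor: int = 1
    effect_size: float = 3.0
    n_informative: int = 12
    feature_correlation: float = 0.3
    null_shift: float = 0.0
    species_mix: Mapping[str, float] = field(default_factory=lambda: {"mouse": 1.0})
    species_true_fraction: Mapping[str, float] | None = None
    species_log2fc: Mapping[str, float] = field(default_factory=lambda: {"mouse": 0.0})
    groups: Sequence[str] = ("A",)
    replicates_per_group: int | None = None
    log_intensity_noise_sd: float = 0.1
    missing_rate: float = 0.0
    base_log2_intensity_mean: float = 14.0
    base_log2_intensity_sd: float = 2.0
    peptides_per_protein: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.precursors_per_sample <= 0 or self.decoys_per_sample < 0:
            raise ConfigurationError("sizes must be positive")
        if not 0.0 <= self.true_target_fraction <= 1.0:
            raise ConfigurationError("true_target_fraction must be in [0, 1]")
        if self.candidate_peakgroups_per_precursor < 1:
            raise ConfigurationError("need at least one candidate peak group")
        if not 0.0 <= self.feature_correlation < 1.0:
            raise ConfigurationError("feature_correlation must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not 1 <= self.n_informative <= N_FEATURES:
            raise ConfigurationError("n_informative out of range")
        total = sum(self.species_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("species_mix fractions must sum to 1")
        if self.replicates_per_group is not None:
            if self.replicates_per_group * len(self.groups) != self.n_samples:
                raise ConfigurationError(
                    "groups x replicates_per_group must equal n_samples"
                )


def _draw_features(
    rng: np.random.Generator,
    n: int,
    rho: float,
    mean_shift: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Exchangeably correlated Gaussian subscores, unit marginal variance."""
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, N_FEATURES))
    x = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
    return x + mean_shift


def _informative_shift(config: SimulationConfig) -> np.ndarray:
    shift = np.zeros(N_FEATURES)
    shift[: config.n_informative] = config.effect_size
    return shift


def build_library(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """The target 'spectral library': per-precursor static ground truth.

    One precursor per peptide; peptides are grouped into proteins of
    ``peptides_per_protein``.  Truth labels and species assignments are
    drawn once and shared by every sample, as in a real experiment where
    the same library is queried against every run.
    """
    n = config.precursors_per_sample
    species_names = list(config.species_mix)
    counts = np.floor(
        np.array([config.species_mix[s] for s in species_names]) * n
    ).astype(int)
    counts[-1] = n - counts[:-1].sum()
    species = np.repeat(species_names, counts)
    rng.shuffle(species)

    pi = np.empty(n)
    overrides = config.species_true_fraction or {}
    for name in species_names:
        pi[species == name] = overrides.get(name, config.true_target_fraction)
    is_true = rng.random(n) < pi

    idx = np.arange(n)
    peptide_ids = np.array([f"PEP{i:06d}" for i in idx])
    protein_ids = np.array(
        [f"PROT{i // config.peptides_per_protein:05d}_{s}" for i, s in zip(idx, species)]
    )
    lib = pd.DataFrame(
        {
            "precursor_id": [f"PEP{i:06d}_2" for i in idx],
            "peptide_id": peptide_ids,
            "protein_group": protein_ids,
            "species_tag": species,
            "truth_label": np.where(is_true, "true_target", "false_target"),
            "base_log2_intensity": rng.normal(
                config.base_log2_intensity_mean, config.base_log2_intensity_sd, n
            ),
            "true_log2fc": np.array(
                [config.species_log2fc.get(s, 0.0) for s in species]
            ),
        }
    )
    return lib


def _sample_groups(config: SimulationConfig) -> list[str]:
    if config.replicates_per_group is not None:
        return [
            g for g in config.groups for _ in range(config.replicates_per_group)
        ]
    return [config.groups[i % len(config.groups)] for i in range(config.n_samples)]


def _simulate_sample(
    config: SimulationConfig,
    lib: pd.DataFrame,
    sample_id: str,
    group: str,
    rng: np.random.Generator,
) -> SampleTable:
    n_t = len(lib)
    n_d = config.decoys_per_sample
    n_c = config.candidate_peakgroups_per_precursor
    rho = config.feature_correlation
    shift = _informative_shift(config)
    is_true = (lib["truth_label"] == "true_target").to_numpy()

    rows = []
    for rank in range(1, n_c + 1):
        feats = _draw_features(rng, n_t, rho, config.null_shift)
        if rank == 1:
            feats[is_true] = _draw_features(rng, int(is_true.sum()), rho, shift)
        rows.append((rank, feats))

    # reference group = first listed group; other groups get the species shift
    group_effect = 0.0 if group == config.groups[0] else 1.0
    log2_int = lib["base_log2_intensity"].to_numpy() + (
        rng.normal(0.0, config.log_intensity_noise_sd, n_t)
        if config.log_intensity_noise_sd > 0
        else 0.0
    )
    # spike factor applied multiplicatively so an integer log2FC is an
    # exact power-of-two ratio in the noise-free limit
    intensities = np.exp2(log2_int) * np.exp2(
        group_effect * lib["true_log2fc"].to_numpy()
    )

    frames = []
    rt = rng.uniform(0.0, 3600.0, n_t)
    for rank, feats in rows:
        frame = pd.DataFrame(feats, columns=list(SUBSCORE_COLUMNS))
        frame.insert(0, "sample_id", sample_id)
        frame.insert(1, "precursor_id", lib["precursor_id"].to_numpy())
        frame.insert(2, "peakgroup_rank", rank)
        frame.insert(3, "peptide_id", lib["peptide_id"].to_numpy())
        frame.insert(4, "protein_group", lib["protein_group"].to_numpy())
        frame.insert(5, "decoy", 0)
        frame.insert(6, "retention_time", rt + (rank - 1) * rng.uniform(5, 30))
        frame.insert(7, "intensity", intensities if rank == 1 else intensities * 0.1)
        frame["truth_label"] = lib["truth_label"].to_numpy()
        frame["species_tag"] = lib["species_tag"].to_numpy()
        frames.append(frame)

    decoy_feats = _draw_features(rng, n_d, rho, config.null_shift)
    decoy = pd.DataFrame(decoy_feats, columns=list(SUBSCORE_COLUMNS))
    decoy.insert(0, "sample_id", sample_id)
    decoy.insert(1, "precursor_id", [f"DECOY_PEP{i:06d}_2" for i in range(n_d)])
    decoy.insert(2, "peakgroup_rank", 1)
    decoy.insert(3, "peptide_id", [f"DECOY_PEP{i:06d}" for i in range(n_d)])
    decoy.insert(
        4,
        "protein_group",
        [f"DECOY_PROT{i // config.peptides_per_protein:05d}" for i in range(n_d)],
    )
    decoy.insert(5, "decoy", 1)
    decoy.insert(6, "retention_time", rng.uniform(0.0, 3600.0, n_d))
    decoy.insert(
        7,
        "intensity",
        np.exp2(
            rng.normal(
                config.base_log2_intensity_mean - 4.0,
                config.base_log2_intensity_sd,
                n_d,
            )
        ),
    )
    decoy["truth_label"] = "decoy"
    decoy["species_tag"] = "decoy"
    frames.append(decoy)

    data = pd.concat(frames, ignore_index=True)
    if config.missing_rate > 0:
        drop = rng.random(len(data)) < config.missing_rate
        data.loc[drop, "intensity"] = np.nan
    data["group"] = group
    return SampleTable(sample_id, data)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[list[SampleTable], pd.DataFrame]:
    """Generate one experiment: a list of sample tables plus ground truth.

    Returns the per-sample peak-group tables (each carrying ``truth_label``
    and ``species_tag`` columns) and the library-level ground-truth frame
    (one row per precursor with its truth label, species, baseline
    intensity and true log2 fold change).
    """
    config.validate()
    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(config.n_samples + 1)
    lib = build_library(config, np.random.default_rng(children[0]))
    groups = _sample_groups(config)
    tables = []
    for i in range(config.n_samples):
        sample_id = f"{groups[i]}_{i:03d}"
        rng = np.random.default_rng(children[i + 1])
        tables.append(_simulate_sample(config, lib, sample_id, groups[i], rng))
    return tables, lib


def simulate_spikein(
    n_replicates: int = 10,
    spike_log2fc: float = 2.0,
    constant_species: str = "mouse",
    spiked_species: str = "yeast",
    spiked_fraction: float = 0.5,
    precursors_per_sample: int = 2000,
    decoys_per_sample: int = 2000,
    log_intensity_noise_sd: float = 0.1,
    missing_rate: float = 0.0,
    effect_size: float = 3.0,
    seed: int = 0,
) -> tuple[list[SampleTable], pd.DataFrame]:
    """Two-group spike-in design: a constant background species at log2FC 0
    and a spiked species at ``spike_log2fc`` (2.0 models a 4x spike).

    Both species are genuinely present (all targets true); the design
    isolates quantitative accuracy from identification error.  In the
    noise-free limit (``log_intensity_noise_sd=0``) every spiked-species
    precursor's log2 fold change is exactly ``spike_log2fc``.
    """
    config = SimulationConfig(
        n_samples=2 * n_replicates,
        precursors_per_sample=precursors_per_sample,
        true_target_fraction=1.0,
        decoys_per_sample=decoys_per_sample,
        effect_size=effect_size,
        species_mix={
            constant_species: 1.0 - spiked_fraction,
            spiked_species: spiked_fraction,
        },
        species_log2fc={constant_species: 0.0, spiked_species: spike_log2fc},
        groups=("A", "B"),
        replicates_per_group=n_replicates,
        log_intensity_noise_sd=log_intensity_noise_sd,
        missing_rate=missing_rate,
        seed=seed,
    )
    return simulate_experiment(config)
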