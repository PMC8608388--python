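"""Synthetic iBAQ-matrix generator with known ground truth.

The generator emulates the statistical structure of processed label-free
proteomics tables from pooled (colony) or single-individual trophallactic
fluid samples:

* protein baseline abundances are log-normal across proteins (log10 scale),
  spanning several orders of magnitude;
* per-observation biological/technical noise is multiplicative log-normal
  (log2 scale);
* a planted subset of proteins differs between the two groups by a fixed
  |log2 fold change| with per-protein sign;
* detection is missing-not-at-random: an entry is observed with logistic
  probability in its latent log10 abundance, shifted by the sample's fluid
  volume, so low-abundance proteins and low-volume samples drop out more;
* a "core" subset never drops out (present in every sample);
* single-individual samples carry colony-level random intercepts.

All randomness derives from one master seed through named
``numpy.random.SeedSequence`` substreams, so outputs are byte-identical for
identical specs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .data import (
    AbundanceMatrix,
    SampleAnnotation,
    ValidationError,
    annotation_frame,
)

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "null_copy"]

_LOG2_PER_LOG10 = np.log2(10.0)


@dataclass
class SyntheticSpec:
    """Generative parameters; defaults are the package's standard study conditions.

    Defaults give ~500 proteins, 20 samples per group, a 5% core set, a
    baseline of 10^N(7, 1.2) iBAQ units, 50 planted proteins at |log2 FC| = 4,
    log2-normal noise of SD 0.5, and moderate logistic dropout (midpoint
    10^5, slope 1 per log10 unit) whose midpoint shifts with sample volume.
    """

    n_proteins: int = 500
    n_samples_per_group: int = 20
    core_fraction: float = 0.05
    base_log10_mean: float = 7.0
    base_log10_sd: float = 1.2
    n_da: int = 50
    delta_log2: float = 4.0
    noise_log2_sd: float = 0.5
    dropout_midpoint_log10: float = 5.0
    dropout_slope: float = 1.0
    volume_effect: float = 0.5
    colony_sd_log2: float = 0.5
    seed: int = 0
    scale: str = "colony"
    n_colonies: int = 4
    group_labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.n_samples_per_group <= 0:
            raise ValidationError("n_proteins and n_samples_per_group must be positive")
        if not 0 < self.core_fraction < 1:
            raise ValidationError("core_fraction must lie in (0, 1)")
        if not 0 <= self.n_da <= self.n_proteins:
            raise ValidationError("n_da must lie in [0, n_proteins]")
        if self.base_log10_sd <= 0 or self.noise_log2_sd < 0:
            raise ValidationError("base_log10_sd must be > 0 and noise_log2_sd >= 0")
        if self.dropout_slope <= 0:
            raise ValidationError("dropout_slope must be positive")
        if self.colony_sd_log2 < 0:
            raise ValidationError("colony_sd_log2 must be non-negative")
        if self.scale not in ("colony", "individual"):
            raise ValidationError("scale must be 'colony' or 'individual'")
        if self.scale == "individual" and self.n_colonies < 1:
            raise ValidationError("n_colonies must be >= 1 for individual scale")
        if len(self.group_labels) != 2 or self.group_labels[0] == self.group_labels[1]:
            raise ValidationError("group_labels must be two distinct labels")


@dataclass
class SyntheticTruth:
    """Planted structure of a generated dataset."""

    da_proteins: dict[str, int]  # protein_id -> sign of the planted log2 effect
    core_proteins: list[str]
    volumes: dict[str, float]
    params: dict = field(default_factory=dict)


def _substreams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate(
    spec: SyntheticSpec,
) -> tuple[AbundanceMatrix, list[SampleAnnotation], SyntheticTruth]:
    """Draw one dataset: matrix, annotations and ground truth."""
    rngs = _substreams(
        spec.seed, ["base", "sets", "volumes", "colony", "noise", "dropout"]
    )
    p, n_half = spec.n_proteins, spec.n_samples_per_group
    n = 2 * n_half
    width = max(3, len(str(p)))
    proteins = [f"P{i:0{width}d}" for i in range(p)]
    la, lb = spec.group_labels
    samples = [f"{la}{i + 1:02d}" for i in range(n_half)] + [
        f"{lb}{i + 1:02d}" for i in range(n_half)
    ]
    is_b = np.array([False] * n_half + [True] * n_half)

    base_log10 = rngs["base"].normal(spec.base_log10_mean, spec.base_log10_sd, size=p)

    n_core = int(round(spec.core_fraction * p))
    order = rngs["sets"].permutation(p)
    core_idx = np.sort(order[:n_core])
    da_idx = np.sort(rngs["sets"].permutation(p)[: spec.n_da])
    da_sign = rngs["sets"].choice([-1, 1], size=spec.n_da)

    # fluid volume (ul): colony pools are larger than single-individual draws
    mean_vol = 4.0 if spec.scale == "colony" else 0.8
    volumes = rngs["volumes"].lognormal(np.log(mean_vol), 0.4, size=n)

    if spec.scale == "individual":
        colonies = [f"C{(i % spec.n_colonies) + 1}" for i in range(n)]
        intercepts = rngs["colony"].normal(0.0, spec.colony_sd_log2, size=spec.n_colonies)
        colony_shift = np.array(
            [intercepts[i % spec.n_colonies] for i in range(n)]
        )
    else:
        colonies = list(samples)  # each pooled sample is its own colony
        colony_shift = np.zeros(n)

    # latent log2 abundance, proteins x samples
    latent_log2 = np.tile((base_log10 * _LOG2_PER_LOG10)[:, None], (1, n))
    effect = np.zeros(p)
    effect[da_idx] = da_sign * spec.delta_log2
    latent_log2[:, is_b] += effect[:, None]
    latent_log2 += colony_shift[None, :]
    latent_log2 += rngs["noise"].normal(0.0, spec.noise_log2_sd, size=(p, n))

    latent_log10 = latent_log2 / _LOG2_PER_LOG10
    logit = spec.dropout_slope * (latent_log10 - spec.dropout_midpoint_log10)
    logit += spec.volume_effect * (volumes - volumes.mean())[None, :]
    p_detect = 1.0 / (1.0 + np.exp(-logit))
    detected = rngs["dropout"].random(size=(p, n)) < p_detect
    detected[core_idx, :] = True

    values = np.where(detected, np.exp2(latent_log2), 0.0)
    matrix = AbundanceMatrix.from_arrays(values, proteins, samples)
    annotations = [
        SampleAnnotation(
            sample_id=samples[i],
            sample_type=lb if is_b[i] else la,
            colony_id=colonies[i],
            volume_ul=float(volumes[i]),
            scale=spec.scale,
        )
        for i in range(n)
    ]
    truth = SyntheticTruth(
        da_proteins={proteins[j]: int(s) for j, s in zip(da_idx, da_sign)},
        core_proteins=[proteins[j] for j in core_idx],
        volumes={samples[i]: float(volumes[i]) for i in range(n)},
        params=asdict(spec),
    )
    return matrix, annotations, truth


def null_copy(
    matrix: AbundanceMatrix,
    annotations: Sequence[SampleAnnotation],
    seed: int = 0,
) -> tuple[AbundanceMatrix, list[SampleAnnotation]]:
    """Reassign the two group labels at random, keeping everything else.

    Volumes, colonies and values stay with their samples; only the
    ``sample_type`` labels are permuted across samples, preserving the label
    multiset.  Used for empirical type-I-error suites.
    """
    types = [a.sample_type for a in annotations]
    levels = sorted(set(types))
    if len(levels) != 2:
        raise ValidationError(f"null_copy needs exactly two sample types, got {levels}")
    if min(types.count(t) for t in levels) < 2:
        raise ValidationError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    shuffled = [types[i] for i in rng.permutation(len(types))]
    new_annotations = [
        SampleAnnotation(
            sample_id=a.sample_id,
            sample_type=t,
            colony_id=a.colony_id,
            volume_ul=a.volume_ul,
            pair_key=a.pair_key,
            scale=a.scale,
        )
        for a, t in zip(annotations, shuffled)
    ]
    return matrix, new_annotations
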