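"""Core domain types for iBAQ protein-quantification analyses.

The central container is :class:`AbundanceMatrix`, a proteins x samples table
of non-negative iBAQ intensities in which a value of exactly 0 encodes "not
detected" (missing-not-at-random dropout).  Sample-level metadata lives in
:class:`SampleAnnotation` records, and a two-group comparison with its
significance thresholds is described by :class:`ComparisonDesign`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrophoError",
    "FormatError",
    "IntegrityError",
    "ValidationError",
    "ProteinRecord",
    "AbundanceMatrix",
    "SampleAnnotation",
    "ComparisonDesign",
    "annotation_frame",
]


class TrophoError(ValueError):
    """Base class for errors raised by this package."""


class FormatError(TrophoError):
    """An input file does not conform to the expected dialect."""


class IntegrityError(TrophoError):
    """Inputs are well-formed but internally inconsistent (duplicates, gaps)."""


class ValidationError(TrophoError):
    """A parameter object violates its invariants."""


@dataclass(frozen=True)
class ProteinRecord:
    """Identification metadata for one protein group.

    ``score`` is the search-engine identification score; the three boolean
    flags mark decoy hits (``is_reverse``), known contaminants and groups
    identified only by modification site, all of which are excluded before
    quantitative analysis.
    """

    protein_id: str
    score: float = float("inf")
    gene_name: str | None = None
    is_contaminant: bool = False
    is_reverse: bool = False
    is_only_by_site: bool = False

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if not np.isnan(self.score) and self.score < 0:
            raise ValidationError(f"negative score for {self.protein_id!r}")

    @property
    def flagged(self) -> bool:
        return self.is_contaminant or self.is_reverse or self.is_only_by_site


class AbundanceMatrix:
    """Proteins x samples table of iBAQ intensities (0 = not detected)."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate protein ids: {dups[:5]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate sample ids: {dups[:5]}")
        values = data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("abundance values must not be NaN (use 0 for absent)")
        if (values < 0).any():
            raise ValidationError("abundance values must be non-negative")
        self.data = pd.DataFrame(values, index=data.index.astype(str), columns=data.columns.astype(str))

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        proteins: Sequence[str],
        samples: Sequence[str],
    ) -> "AbundanceMatrix":
        return cls(pd.DataFrame(np.asarray(values, dtype=float), index=list(proteins), columns=list(samples)))

    # -- basic accessors ------------------------------------------------------
    @property
    def proteins(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def select_proteins(self, ids: Iterable[str]) -> "AbundanceMatrix":
        ids = list(ids)
        missing = set(ids) - set(self.data.index)
        if missing:
            raise IntegrityError(f"unknown protein ids: {sorted(missing)[:5]}")
        return AbundanceMatrix(self.data.loc[ids])

    def select_samples(self, ids: Iterable[str]) -> "AbundanceMatrix":
        ids = list(ids)
        missing = set(ids) - set(self.data.columns)
        if missing:
            raise IntegrityError(f"unknown sample ids: {sorted(missing)[:5]}")
        return AbundanceMatrix(self.data[ids])

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected (value > 0) entries."""
        return self.data > 0

    def equals(self, other: "AbundanceMatrix") -> bool:
        return self.data.equals(other.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AbundanceMatrix({self.n_proteins} proteins x {self.n_samples} samples)"


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample metadata: comparison label, colony, fluid volume, pairing.

    ``scale`` distinguishes pooled colony samples from single-individual
    samples; the two scales are analysed separately throughout.  ``pair_key``
    links resampled pairs (e.g. the same colony sampled in the field and
    again in the lab) for paired designs.
    """

    sample_id: str
    sample_type: str
    colony_id: str | None = None
    volume_ul: float | None = None
    pair_key: str | None = None
    scale: str = "colony"

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not self.sample_type:
            raise ValidationError(f"sample_type missing for {self.sample_id!r}")
        if self.volume_ul is not None and not self.volume_ul > 0:
            raise ValidationError(f"volume_ul must be positive for {self.sample_id!r}")
        if self.scale not in ("colony", "individual"):
            raise ValidationError(f"scale must be 'colony' or 'individual', got {self.scale!r}")


def annotation_frame(annotations: Sequence[SampleAnnotation]) -> pd.DataFrame:
    """Tabulate annotations, indexed by sample_id (raises on duplicates)."""
    rows = [
        {f.name: getattr(a, f.name) for f in fields(SampleAnnotation)}
        for a in annotations
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValidationError("no sample annotations given")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise IntegrityError(f"duplicate sample ids in metadata: {dups[:5]}")
    return df.set_index("sample_id")


@dataclass
class ComparisonDesign:
    """A two-group comparison and the significance thresholds of each arm.

    Defaults follow the study conventions: permutation FDR 0.05 with S0 = 2
    for the frequentist arm on colony samples, BH FDR 0.01 for individual
    samples, an absolute log2 fold-change gate of 2 for the moderated-t arm,
    and a 70% presence filter before the frequentist tests.
    """

    group_a: str
    group_b: str
    paired: bool = False
    alpha_perm: float = 0.05
    alpha_bh: float = 0.01
    s0: float = 2.0
    log2fc_cutoff: float = 2.0
    presence_fraction: float = 0.70

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b or self.group_a == self.group_b:
            raise ValidationError("groups must be non-empty and distinct")
        if not 0 < self.presence_fraction < 1:
            raise ValidationError("presence_fraction must lie in (0, 1)")
        for name in ("alpha_perm", "alpha_bh"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.s0 < 0:
            raise ValidationError("s0 must be non-negative")
        if self.log2fc_cutoff < 0:
            raise ValidationError("log2fc_cutoff must be non-negative")

    def group_samples(
        self, annotations: Sequence[SampleAnnotation]
    ) -> tuple[list[str], list[str]]:
        """Sample ids of group_a and group_b, in annotation order."""
        a = [x.sample_id for x in annotations if x.sample_type == self.group_a]
        b = [x.sample_id for x in annotations if x.sample_type == self.group_b]
        if not a or not b:
            raise ValidationError(
                f"design groups {self.group_a!r}/{self.group_b!r} not both present in metadata"
            )
        return a, b

    def pairs(
        self, annotations: Sequence[SampleAnnotation]
    ) -> list[tuple[str, str]]:
        """Resolve pair_key links into (group_a sample, group_b sample) pairs."""
        a = {x.pair_key: x.sample_id for x in annotations if x.sample_type == self.group_a}
        b = {x.pair_key: x.sample_id for x in annotations if x.sample_type == self.group_b}
        if None in a or None in b:
            raise IntegrityError("paired design requires pair_key on every compared sample")
        if set(a) != set(b) or len(a) != sum(1 for x in annotations if x.sample_type == self.group_a):
            raise IntegrityError("pair_key must match exactly one sample of each condition")
        return [(a[k], b[k]) for k in sorted(a)]
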