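"""Transformations feeding the statistical arms.

The frequentist arm works on log2-transformed, per-sample median-centered
values in which zeros (not detected) become missing, and missing entries are
then imputed from a per-sample downshifted normal distribution — the
standard missing-not-at-random treatment for label-free intensities, which
places imputed values in the low tail where undetected proteins plausibly
sit.  The self-similarity metric instead uses a square-root transform in
which zeros are kept as data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AbundanceMatrix, TrophoError, ValidationError

__all__ = [
    "PreprocessConfig",
    "presence_filter",
    "log2_median_center",
    "impute_downshifted",
    "sqrt_median_transform",
]


@dataclass
class PreprocessConfig:
    """Presence filter and imputation parameters.

    ``impute_shift_sd`` and ``impute_width_sd`` are in units of the
    per-sample observed standard deviation: missing entries of sample *s*
    are drawn from Normal(mu_s - shift*sigma_s, (width*sigma_s)^2).
    """

    presence_fraction: float = 0.70
    impute_shift_sd: float = 2.0
    impute_width_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.presence_fraction < 1:
            raise ValidationError("presence_fraction must lie in (0, 1)")
        if self.impute_width_sd <= 0:
            raise ValidationError("impute_width_sd must be positive")


def presence_filter(matrix: AbundanceMatrix, fraction: float = 0.70) -> AbundanceMatrix:
    """Retain proteins detected in strictly more than ``fraction`` of samples.

    "Over 70%" is read strictly: a protein detected in exactly 70% of the
    samples is dropped.  An empty result is allowed.
    """
    if not 0 < fraction < 1:
        raise ValidationError("fraction must lie in (0, 1)")
    detected_frac = (matrix.data > 0).sum(axis=1) / matrix.n_samples
    keep = detected_frac.index[detected_frac > fraction].tolist()
    return matrix.select_proteins(keep)


def log2_median_center(
    matrix: AbundanceMatrix, return_medians: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.Series]:
    """log2-transform detected values and center each sample at median 0.

    Zeros become missing (NaN).  The per-sample median is computed over
    detected values only; optionally the medians are returned so centering
    can be undone.
    """
    values = matrix.data.to_numpy(dtype=float).copy()
    values[values <= 0] = np.nan
    log2v = np.log2(values)
    n_obs = (~np.isnan(log2v)).sum(axis=0)
    if (n_obs == 0).any():
        bad = [s for s, k in zip(matrix.samples, n_obs) if k == 0]
        raise TrophoError(f"sample(s) with no detected values: {bad}")
    medians = np.nanmedian(log2v, axis=0)
    centered = pd.DataFrame(log2v - medians, index=matrix.proteins, columns=matrix.samples)
    if return_medians:
        return centered, pd.Series(medians, index=matrix.samples)
    return centered


def impute_downshifted(
    tmatrix: pd.DataFrame, config: PreprocessConfig | None = None
) -> pd.DataFrame:
    """Fill missing entries from a per-sample downshifted normal.

    For sample *s* with observed mean mu_s and SD sigma_s (ddof=1), each
    missing entry is an independent draw from
    Normal(mu_s - shift*sigma_s, (width*sigma_s)^2).  Observed entries are
    unchanged; output is deterministic given ``config.seed``.
    """
    config = config or PreprocessConfig()
    rng = np.random.default_rng(config.seed)
    out = tmatrix.to_numpy(dtype=float).copy()
    for j, sample in enumerate(tmatrix.columns):
        col = out[:, j]
        obs = col[~np.isnan(col)]
        if obs.size < 2:
            raise TrophoError(f"sample {sample!r} has fewer than 2 observed values")
        mu, sigma = obs.mean(), obs.std(ddof=1)
        miss = np.isnan(col)
        if miss.any():
            col[miss] = rng.normal(
                mu - config.impute_shift_sd * sigma,
                config.impute_width_sd * sigma,
                size=int(miss.sum()),
            )
    return pd.DataFrame(out, index=tmatrix.index, columns=tmatrix.columns)


def sqrt_median_transform(matrix: AbundanceMatrix, axis: str = "sample") -> pd.DataFrame:
    """Square-root transform, then subtract medians of the transformed values.

    Zeros are kept as values (sqrt(0) = 0), not treated as missing.  ``axis``
    selects whether the subtracted median is per sample (default) or per
    protein; per-protein centering leaves inter-sample distances unchanged.
    """
    root = np.sqrt(matrix.data.to_numpy(dtype=float))
    if axis == "sample":
        centered = root - np.median(root, axis=0)
    elif axis == "protein":
        centered = root - np.median(root, axis=1)[:, None]
    else:
        raise ValueError(f"axis must be 'sample' or 'protein', got {axis!r}")
    return pd.DataFrame(centered, index=matrix.proteins, columns=matrix.samples)
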