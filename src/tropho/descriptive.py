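"""Descriptive layer: self-similarity, variability and protein-count models.

* ``self_similarity`` — per-sample score S = |D_within - D_across| / D_all
  on standardized Euclidean distances of square-root transformed,
  median-subtracted abundances.  S is 0 for a sample equidistant to both
  group centroids and grows when a sample sits closer to its own type.
* ``cv_by_type`` — per-protein coefficients of variation (SD/mean over
  strictly positive iBAQ values) modelled with a gamma GLM (log link) on
  sample type, with single-step multiplicity-adjusted pairwise contrasts.
* ``protein_count_model`` — detected-protein counts per sample modelled
  with a negative-binomial GLM (log link) on sample type.
* ``count_volume_correlation`` — Pearson correlation of detected-protein
  count with fluid volume, separately per sample scale.
* ``core_proteins`` — proteins detected in every sample.
* ``pca_scores`` — PCA of raw (column-centered, unscaled) iBAQ values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import cdist

from .data import (
    AbundanceMatrix,
    SampleAnnotation,
    TrophoError,
    ValidationError,
    annotation_frame,
)

__all__ = [
    "self_similarity",
    "cv_by_type",
    "protein_count_model",
    "count_volume_correlation",
    "core_proteins",
    "pca_scores",
    "GlmByTypeResult",
]


# ---------------------------------------------------------------------------
# self-similarity
# ---------------------------------------------------------------------------

def self_similarity(
    matrix: AbundanceMatrix,
    annotations: Sequence[SampleAnnotation],
    group_pair: tuple[str, str],
    median_axis: str = "protein",
) -> pd.DataFrame:
    """Per-sample self-similarity S between two sample types.

    Abundances are square-root transformed and median-subtracted (per
    protein by default; per-protein centering does not move samples
    relative to each other, ``median_axis="sample"`` exposes the
    alternative reading).  Pairwise dissimilarities are standardized
    Euclidean distances: each protein coordinate is divided by its SD
    (ddof=1) across all samples of the two groups; zero-SD proteins are
    dropped.  For each sample, D_within averages distances to same-type
    samples, D_across to other-type samples and D_all to all other
    samples; S = |D_within - D_across| / D_all.
    """
    ta, tb = group_pair
    ids = [a.sample_id for a in annotations if a.sample_type in (ta, tb)]
    types = {a.sample_id: a.sample_type for a in annotations}
    counts = {t: sum(1 for s in ids if types[s] == t) for t in (ta, tb)}
    if min(counts.values(), default=0) < 2:
        raise ValidationError(f"need >= 2 samples per type, got {counts}")
    sub = matrix.select_samples(ids)

    from .preprocess import sqrt_median_transform

    T = sqrt_median_transform(sub, axis=median_axis).to_numpy().T  # samples x proteins
    sd = T.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise TrophoError("all proteins have zero SD: distances undefined")
    Z = T[:, keep] / sd[keep]
    D = cdist(Z, Z)

    n = len(ids)
    same = np.array([[types[ids[i]] == types[ids[j]] for j in range(n)] for i in range(n)])
    off = ~np.eye(n, dtype=bool)
    rows = {}
    for i, s in enumerate(ids):
        within = D[i, same[i] & off[i]]
        across = D[i, ~same[i]]
        d_all = D[i, off[i]].mean()
        if d_all == 0:
            raise TrophoError(f"sample {s!r} is at zero distance from all others")
        rows[s] = {
            "sample_type": types[s],
            "d_within": within.mean(),
            "d_across": across.mean(),
            "d_all": d_all,
            "S": abs(within.mean() - across.mean()) / d_all,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# GLMs by sample type
# ---------------------------------------------------------------------------

@dataclass
class GlmByTypeResult:
    """A per-type GLM with its data and adjusted pairwise contrasts."""

    data: pd.DataFrame
    coefficients: pd.DataFrame  # per-type estimate (log scale) and SE
    contrasts: pd.DataFrame  # pairwise contrasts with single-step adjusted p
    model: object  # fitted statsmodels results

    def summary(self) -> str:
        return (
            self.coefficients.to_string()
            + "\n\npairwise contrasts (single-step max-|z| adjusted):\n"
            + self.contrasts.to_string()
        )


def _single_step_contrasts(
    params: np.ndarray,
    cov: np.ndarray,
    levels: list[str],
    seed: int = 0,
) -> pd.DataFrame:
    """All pairwise level contrasts with single-step max-|z| adjustment.

    The joint null distribution of the contrast z statistics is multivariate
    normal with the contrasts' correlation matrix; the adjusted p-value of
    contrast k is 1 - P(max_j |Z_j| <= |z_k|), the standard single-step
    multiple-comparison adjustment for GLM contrasts.
    """
    pairs = [(i, j) for i in range(len(levels)) for j in range(i + 1, len(levels))]
    L = np.zeros((len(pairs), len(params)))
    for r, (i, j) in enumerate(pairs):
        L[r, j] = 1.0
        L[r, i] = -1.0
    est = L @ params
    vc = L @ cov @ L.T
    se = np.sqrt(np.diag(vc))
    z = est / se
    corr = vc / np.outer(se, se)
    corr = (corr + corr.T) / 2 + 1e-10 * np.eye(len(pairs))
    mvn = scipy.stats.multivariate_normal(mean=np.zeros(len(pairs)), cov=corr, seed=seed)
    p_adj = np.empty(len(pairs))
    for k, zk in enumerate(np.abs(z)):
        p_adj[k] = 1.0 - float(
            mvn.cdf(np.full(len(pairs), zk), lower_limit=np.full(len(pairs), -zk))
        )
    p_raw = 2.0 * scipy.stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "contrast": [f"{levels[j]} - {levels[i]}" for i, j in pairs],
            "estimate": est,
            "se": se,
            "z": z,
            "p_value": p_raw,
            "p_adjusted": np.clip(p_adj, p_raw, 1.0),
        }
    ).set_index("contrast")


def cv_by_type(
    matrix: AbundanceMatrix,
    annotations: Sequence[SampleAnnotation],
    min_positive: int = 2,
) -> GlmByTypeResult:
    """Coefficient of variation per protein per type, gamma GLM on type.

    CV = sample SD / mean over strictly positive iBAQ values of the protein
    within the type (zeros excluded; proteins with fewer than
    ``min_positive`` positive values in a type contribute no CV there).
    """
    import statsmodels.api as sm

    ann = annotation_frame(list(annotations))
    rows = []
    for t, ids in ann.groupby("sample_type").groups.items():
        sub = matrix.data[list(ids)].to_numpy()
        for g, protein in enumerate(matrix.proteins):
            pos = sub[g][sub[g] > 0]
            if pos.size >= min_positive:
                m = pos.mean()
                cv = pos.std(ddof=1) / m
                if cv > 0:
                    rows.append({"sample_type": t, "protein_id": protein, "cv": cv})
    data = pd.DataFrame(rows)
    levels = sorted(ann["sample_type"].unique())
    missing = [t for t in levels if t not in set(data.get("sample_type", []))]
    if missing:
        raise TrophoError(f"no computable CVs for type(s): {missing}")
    X = pd.get_dummies(data["sample_type"], dtype=float)[levels].to_numpy()
    fit = sm.GLM(
        data["cv"].to_numpy(), X, family=sm.families.Gamma(link=sm.families.links.Log())
    ).fit()
    coef = pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse}, index=pd.Index(levels, name="sample_type")
    )
    contrasts = (
        _single_step_contrasts(fit.params, fit.cov_params(), levels)
        if len(levels) > 1
        else pd.DataFrame()
    )
    return GlmByTypeResult(data, coef, contrasts, fit)


def protein_count_model(
    matrix: AbundanceMatrix, annotations: Sequence[SampleAnnotation]
) -> GlmByTypeResult:
    """Detected-protein counts per sample, negative-binomial GLM on type."""
    import statsmodels.api as sm

    ann = annotation_frame(list(annotations))
    levels = sorted(ann["sample_type"].unique())
    if len(levels) < 2:
        raise ValidationError("need at least 2 sample types")
    counts = (matrix.data > 0).sum(axis=0)
    data = pd.DataFrame(
        {
            "sample_id": ann.index,
            "sample_type": ann["sample_type"].to_numpy(),
            "count": counts.loc[ann.index].to_numpy(),
        }
    )
    X = pd.get_dummies(data["sample_type"], dtype=float)[levels].to_numpy()
    y = data["count"].to_numpy(dtype=float)
    model = sm.NegativeBinomial(y, X)
    # start at the per-type log means: the default start diverges for
    # no-intercept dummy coding
    start = np.array(
        [np.log(max(y[X[:, k] == 1].mean(), 0.5)) for k in range(len(levels))] + [0.1]
    )
    k = len(levels)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
        # last parameter is the dispersion alpha; contrasts act on type means
        cov = np.asarray(fit.cov_params())[:k, :k]
        params = np.asarray(fit.params)[:k]
        se = np.asarray(fit.bse)[:k]
        if np.isnan(cov).any() or np.isnan(se).any():
            raise ValueError("singular NB information matrix")
    except Exception:
        # dispersion at the zero boundary (counts not overdispersed): the
        # negative binomial degenerates to Poisson
        fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        cov = np.asarray(fit.cov_params())
        params = np.asarray(fit.params)
        se = np.asarray(fit.bse)
    coef = pd.DataFrame(
        {"estimate": params, "se": se},
        index=pd.Index(levels, name="sample_type"),
    )
    contrasts = _single_step_contrasts(params, cov, levels)
    return GlmByTypeResult(data, coef, contrasts, fit)


def count_volume_correlation(
    matrix: AbundanceMatrix, annotations: Sequence[SampleAnnotation]
) -> dict[str, tuple[float, float]]:
    """Pearson r (and p) of detected-protein count vs volume, per scale."""
    ann = annotation_frame(list(annotations))
    if ann["volume_ul"].isna().any():
        raise ValidationError("volume_ul required on every sample")
    counts = (matrix.data > 0).sum(axis=0)
    out: dict[str, tuple[float, float]] = {}
    for scale, group in ann.groupby("scale"):
        c = counts.loc[group.index].to_numpy(dtype=float)
        v = group["volume_ul"].to_numpy(dtype=float)
        if np.ptp(c) == 0 or np.ptp(v) == 0:
            raise TrophoError(f"constant counts or volumes for scale {scale!r}")
        r, p = scipy.stats.pearsonr(c, v)
        out[str(scale)] = (float(r), float(p))
    return out


def core_proteins(matrix: AbundanceMatrix) -> list[str]:
    """Proteins detected (value > 0) in every sample."""
    mask = (matrix.data > 0).all(axis=1)
    return matrix.data.index[mask].tolist()


def pca_scores(
    matrix: AbundanceMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of raw iBAQ values (samples as observations, centered, unscaled).

    Returns per-sample scores for the leading components and the explained
    variance fractions (non-increasing).
    """
    from sklearn.decomposition import PCA

    X = matrix.data.to_numpy().T  # samples x proteins
    limit = min(X.shape)
    if not 1 <= n_components <= limit:
        raise ValidationError(f"n_components must lie in [1, {limit}]")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=matrix.samples, columns=cols),
        pca.explained_variance_ratio_,
    )
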