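"""Empirical-Bayes differential abundance with moderated variances.

Per protein g, an ordinary two-group linear model gives the effect estimate
(the log2 fold change) and a residual variance s_g^2 on d_g degrees of
freedom.  The variances are assumed exchangeable around a scaled-inverse-
chi-square prior with scale s_0^2 and d_0 degrees of freedom; the posterior
variance

    s~_g^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)

replaces s_g^2 in the t statistic, which then has d_0 + d_g degrees of
freedom.  The prior is estimated from the observed variances by moment
matching on the log scale (digamma/trigamma inversion).  Zeros (not
detected) stay missing in this arm — no imputation — so proteins with fewer
than two observed values in either group are reported untested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import digamma, polygamma

from .data import (
    AbundanceMatrix,
    ComparisonDesign,
    SampleAnnotation,
    TrophoError,
    ValidationError,
)
from .frequentist import DifferentialResults, bh_fdr

__all__ = [
    "ModerationPrior",
    "fit_moderation",
    "moderated_test",
    "ModeratedLinearModel",
    "run_ebayes",
]


@dataclass(frozen=True)
class ModerationPrior:
    """Scaled-inverse-chi-square prior on residual variances."""

    d0: float  # prior degrees of freedom; may be 0 (no moderation) or inf
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValidationError("d0 must be non-negative")
        if not self.s0_sq > 0:
            raise ValidationError("s0_sq must be positive")

    def posterior(self, s_sq: np.ndarray | float, df: np.ndarray | float) -> np.ndarray | float:
        """Posterior variance s~^2 = (d0 s0^2 + df s^2)/(d0 + df)."""
        if math.isinf(self.d0):
            return np.broadcast_to(self.s0_sq, np.shape(s_sq)).copy() if np.ndim(s_sq) else self.s0_sq
        return (self.d0 * self.s0_sq + np.asarray(df) * np.asarray(s_sq)) / (self.d0 + np.asarray(df))


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return y


def fit_moderation(
    residual_variances: Sequence[float], residual_df: Sequence[int] | int
) -> ModerationPrior:
    """Estimate (d0, s0^2) by moment matching on log variances.

    log s_g^2 is distributed as log s0^2 plus a log-F(d_g, d0) variable; the
    excess of the empirical variance of e_g = log s_g^2 - digamma(d_g/2) +
    log(d_g/2) over its sampling component trigamma(d_g/2) identifies d0 via
    trigamma inversion.  No excess dispersion means a degenerate prior:
    d0 = infinity with every posterior variance equal to s0^2.
    """
    s2 = np.asarray(residual_variances, dtype=float)
    df = np.broadcast_to(np.asarray(residual_df, dtype=float), s2.shape)
    ok = (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 3:
        raise TrophoError("need at least 3 positive residual variances")
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    excess = e.var(ddof=1) - float(np.mean(polygamma(1, df / 2.0)))
    if excess <= 0:
        return ModerationPrior(d0=math.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def _group_stats(tmatrix: pd.DataFrame, ids_a: list[str], ids_b: list[str]):
    """Per-protein two-group OLS pieces from a matrix with missing entries."""
    A = tmatrix[ids_a].to_numpy()
    B = tmatrix[ids_b].to_numpy()
    na = (~np.isnan(A)).sum(axis=1)
    nb = (~np.isnan(B)).sum(axis=1)
    sum_a = np.nansum(A, axis=1)
    sum_b = np.nansum(B, axis=1)
    ma = np.where(na > 0, sum_a / np.maximum(na, 1), np.nan)
    mb = np.where(nb > 0, sum_b / np.maximum(nb, 1), np.nan)
    with np.errstate(invalid="ignore"):
        ssa = np.nansum((A - ma[:, None]) ** 2, axis=1)
        ssb = np.nansum((B - mb[:, None]) ** 2, axis=1)
    df = na + nb - 2
    eligible = (na >= 2) & (nb >= 2)
    s_sq = np.full(len(tmatrix), np.nan)
    s_sq[eligible] = (ssa + ssb)[eligible] / df[eligible]
    beta = mb - ma
    v = 1.0 / np.maximum(na, 1) + 1.0 / np.maximum(nb, 1)
    return beta, s_sq, df.astype(float), v, eligible


def moderated_test(
    tmatrix: pd.DataFrame,
    design: ComparisonDesign,
    annotations: Sequence[SampleAnnotation] | None = None,
    ids_a: list[str] | None = None,
    ids_b: list[str] | None = None,
    prior: ModerationPrior | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Moderated t-tests on a median-normalised log2 matrix with missing values.

    Group membership comes from ``annotations`` (or explicit id lists).
    ``prior=None`` estimates the moderation prior from the eligible
    proteins' residual variances; passing ``ModerationPrior(0, ...)``
    reproduces the ordinary two-sample t-test exactly.  A protein is
    significant iff BH q <= ``alpha`` AND |log2fc| >= design.log2fc_cutoff.
    Untested proteins (fewer than 2 observations in either group) carry NaN
    statistics and significant = False.
    """
    if ids_a is None or ids_b is None:
        if annotations is None:
            raise ValidationError("need annotations or explicit group id lists")
        ids_a, ids_b = design.group_samples(list(annotations))
    missing = set(ids_a + ids_b) - set(tmatrix.columns)
    if missing:
        raise ValidationError(f"design samples absent from matrix: {sorted(missing)[:5]}")
    beta, s_sq, df, v, eligible = _group_stats(tmatrix, ids_a, ids_b)
    if eligible.sum() == 0:
        raise TrophoError("no protein has >= 2 observed values in both groups")
    if prior is None:
        prior = fit_moderation(s_sq[eligible], df[eligible])

    stat = np.full(len(tmatrix), np.nan)
    p = np.full(len(tmatrix), np.nan)
    if prior.d0 == 0:
        post_var = s_sq[eligible]
        total_df = df[eligible]
    else:
        post_var = np.asarray(prior.posterior(s_sq[eligible], df[eligible]))
        total_df = df[eligible] + prior.d0
    with np.errstate(divide="ignore"):
        t = beta[eligible] / np.sqrt(post_var * v[eligible])
    if math.isinf(prior.d0):
        pe = 2.0 * scipy.stats.norm.sf(np.abs(t))
    else:
        pe = 2.0 * scipy.stats.t.sf(np.abs(t), total_df)
    stat[eligible], p[eligible] = t, pe

    q = np.full(len(tmatrix), np.nan)
    q[eligible] = bh_fdr(p[eligible])
    significant = eligible & (q <= alpha) & (np.abs(beta) >= design.log2fc_cutoff)
    return pd.DataFrame(
        {
            "statistic": stat,
            "p_value": p,
            "q_value": q,
            "log2fc": beta,
            "significant": significant,
            "tested": eligible,
            "method": "ebayes",
        },
        index=pd.Index(tmatrix.index, name="protein_id"),
    )


class ModeratedLinearModel:
    """Empirical-Bayes arm: log2 with zeros missing, per-sample median
    normalisation, moderated two-group t-tests, BH + fold-change gate."""

    def __init__(
        self,
        matrix: AbundanceMatrix,
        annotations: Sequence[SampleAnnotation],
        design: ComparisonDesign,
    ):
        self.matrix = matrix
        self.annotations = list(annotations)
        self.design = design

    def fit(
        self, prior: ModerationPrior | None = None, alpha: float = 0.05
    ) -> DifferentialResults:
        from .preprocess import log2_median_center

        ids_a, ids_b = self.design.group_samples(self.annotations)
        sub = self.matrix.select_samples(ids_a + ids_b)
        tmatrix = log2_median_center(sub)
        table = moderated_test(
            tmatrix, self.design, ids_a=ids_a, ids_b=ids_b, prior=prior, alpha=alpha
        )
        fitted_prior = prior
        if fitted_prior is None:
            beta, s_sq, df, v, eligible = _group_stats(tmatrix, ids_a, ids_b)
            fitted_prior = fit_moderation(s_sq[eligible], df[eligible])
        n_tested = int(table["tested"].sum())
        return DifferentialResults(
            table,
            self.design,
            "ebayes",
            n_tested,
            sub.n_proteins,
            extra={
                "prior_df_d0": fitted_prior.d0,
                "prior_var_s0_sq": fitted_prior.s0_sq,
                "n_untested": sub.n_proteins - n_tested,
                "gate": f"q <= {alpha} and |log2fc| >= {self.design.log2fc_cutoff}",
            },
        )


def run_ebayes(
    matrix: AbundanceMatrix,
    annotations: Sequence[SampleAnnotation],
    design: ComparisonDesign,
    prior: ModerationPrior | None = None,
    alpha: float = 0.05,
) -> DifferentialResults:
    """Functional wrapper over :class:`ModeratedLinearModel`."""
    return ModeratedLinearModel(matrix, annotations, design).fit(prior=prior, alpha=alpha)
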