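"""Frequentist differential abundance: S0 statistics and permutation FDR.

The test statistic is the fold-change-regularised two-sample statistic

    d_g = (mean_b - mean_a) / (se_g + s0)

where ``se_g`` is the pooled-variance standard error of the mean difference
and the constant ``s0`` (default 2) damps proteins whose significance rests
on a vanishing variance rather than a meaningful effect.  Significance is
assessed either by a permutation-based false discovery rate (relabelling
group assignments, or sign-flipping within pairs for paired designs) or —
for the single-individual datasets — by Welch t-tests with
Benjamini-Hochberg adjustment at a stricter threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .data import (
    AbundanceMatrix,
    ComparisonDesign,
    SampleAnnotation,
    TrophoError,
    ValidationError,
)
from .preprocess import (
    PreprocessConfig,
    impute_downshifted,
    log2_median_center,
    presence_filter,
)

__all__ = [
    "s0_statistic",
    "paired_s0_statistic",
    "bh_fdr",
    "permutation_fdr",
    "FrequentistDifferential",
    "DifferentialResults",
    "run_frequentist",
    "two_way_anova",
    "AnovaResults",
]


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def s0_statistic(group_a: Sequence[float], group_b: Sequence[float], s0: float) -> float:
    """S0-regularised two-sample statistic (mean_b - mean_a)/(se + s0)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if s0 < 0:
        raise ValidationError("s0 must be non-negative")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if se + s0 == 0.0:
        raise TrophoError("zero pooled SD with s0 = 0: statistic undefined")
    return float((b.mean() - a.mean()) / (se + s0))


def paired_s0_statistic(diffs: Sequence[float], s0: float) -> float:
    """Paired analogue on per-pair differences (b - a)."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValidationError("need at least 2 pairs")
    se = d.std(ddof=1) / math.sqrt(d.size)
    if se + s0 == 0.0:
        raise TrophoError("zero SD of differences with s0 = 0: statistic undefined")
    return float(d.mean() / (se + s0))


def _d_for_masks(V: np.ndarray, masks: np.ndarray, s0: float) -> np.ndarray:
    """S0 statistics for all proteins under many group-b membership masks.

    V is proteins x samples (complete); masks is n_assignments x n_samples
    boolean.  Returns n_assignments x n_proteins.
    """
    n = V.shape[1]
    M = masks.astype(float).T  # n x k
    Mc = (~masks).astype(float).T
    nb = masks.sum(axis=1).astype(float)  # k
    na = n - nb
    V2 = V**2
    # both groups summed directly (not via complement) so that swapping the
    # two groups yields the bit-identical |d| — ties in the permutation null
    # are then counted consistently
    Sb, Sqb = V @ M, V2 @ M  # p x k
    Sa, Sqa = V @ Mc, V2 @ Mc
    ma, mb = Sa / na[None, :], Sb / nb[None, :]
    ssa = np.maximum(Sqa - na[None, :] * ma**2, 0.0)
    ssb = np.maximum(Sqb - nb[None, :] * mb**2, 0.0)
    sp2 = (ssa + ssb) / (na + nb - 2)[None, :]
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb)[None, :])
    return ((mb - ma) / (se + s0)).T


def _paired_d_for_signs(D: np.ndarray, signs: np.ndarray, s0: float) -> np.ndarray:
    """Paired S0 statistics under many sign-flip patterns.

    D is proteins x pairs of differences; signs is k x pairs of +-1.
    Sign flips leave per-pair squared values unchanged, so the variance is
    computed from the flipped mean and the constant sum of squares.
    """
    m = D.shape[1]
    mean = (D @ signs.T) / m  # p x k
    Sq = (D**2).sum(axis=1)[:, None]
    var = np.maximum(Sq - m * mean**2, 0.0) / (m - 1)
    se = np.sqrt(var / m)
    return ((mean) / (se + s0)).T


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------

def _enumerate_masks(n: int, nb: int, n_permutations: int, seed: int) -> tuple[np.ndarray, bool]:
    """Distinct group-b membership masks: exhaustive if few, else sampled.

    The observed assignment (last nb samples in group b, by construction of
    the caller) is always included.  Sampling is without replacement among
    distinct assignments.
    """
    total = math.comb(n, nb)
    observed = np.zeros(n, dtype=bool)
    observed[n - nb:] = True
    if total <= n_permutations:
        masks = np.zeros((total, n), dtype=bool)
        for i, combo in enumerate(itertools.combinations(range(n), nb)):
            masks[i, list(combo)] = True
        # observed assignment first: its row doubles as the observed statistic,
        # keeping identity ties in the null bit-identical
        obs_row = int(np.nonzero((masks == observed).all(axis=1))[0][0])
        masks[[0, obs_row]] = masks[[obs_row, 0]]
        return masks, True
    rng = np.random.default_rng(seed)
    seen = {tuple(observed.tolist())}
    masks = [observed]
    while len(masks) < n_permutations:
        m = np.zeros(n, dtype=bool)
        m[rng.choice(n, size=nb, replace=False)] = True
        key = tuple(m.tolist())
        if key not in seen:
            seen.add(key)
            masks.append(m)
    return np.asarray(masks), False


def _enumerate_signs(m: int, n_permutations: int, seed: int) -> tuple[np.ndarray, bool]:
    total = 2**m
    if total <= n_permutations:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=m)))
        return signs, True
    rng = np.random.default_rng(seed)
    identity = np.ones(m)
    seen = {tuple(identity.tolist())}
    signs = [identity]
    while len(signs) < n_permutations:
        s = rng.choice([-1.0, 1.0], size=m)
        key = tuple(s.tolist())
        if key not in seen:
            seen.add(key)
            signs.append(s)
    return np.asarray(signs), False


def _fdr_from_null(obs_abs: np.ndarray, null_abs: np.ndarray) -> np.ndarray:
    """Permutation FDR per protein, monotonised (q non-increasing in |d|).

    At candidate threshold t the FDR estimate is
    (mean over permutations of #{null |d| >= t}) / #{observed |d| >= t},
    clipped to [0, 1]; each protein's q is the smallest estimate over all
    candidate thresholds at which it would still be called.
    """
    n_perm = null_abs.shape[0]
    flat_null = np.sort(null_abs.ravel())
    order = np.argsort(obs_abs)  # ascending
    q = np.empty_like(obs_abs)
    running = np.inf
    n_obs = obs_abs.size
    for rank, g in enumerate(order):
        t = obs_abs[g]
        n_null_ge = flat_null.size - np.searchsorted(flat_null, t, side="left")
        r = n_obs - rank  # observed statistics >= t
        fdr = min((n_null_ge / n_perm) / r, 1.0) if r > 0 else 0.0
        running = min(running, fdr)
        q[g] = running
    return q


def permutation_fdr(
    tmatrix: pd.DataFrame,
    annotations: Sequence[SampleAnnotation],
    design: ComparisonDesign,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-based FDR on a complete (imputed) log2 matrix.

    Unpaired designs relabel group assignments (exhaustively when the number
    of distinct assignments does not exceed ``n_permutations``); paired
    designs sign-flip within pairs.  Returns a differential table with the
    signed statistic, a per-protein permutation p, the monotonised q, the
    log2 fold change (mean_b - mean_a) and the significance call at
    ``design.alpha_perm``.
    """
    if np.isnan(tmatrix.to_numpy()).any():
        raise ValidationError("permutation_fdr requires a complete (imputed) matrix")
    if design.paired:
        pairs = design.pairs(list(annotations))
        D = (
            tmatrix[[b for _, b in pairs]].to_numpy()
            - tmatrix[[a for a, _ in pairs]].to_numpy()
        )
        if D.shape[1] < 2:
            raise ValidationError("need at least 2 pairs")
        signs, _ = _enumerate_signs(D.shape[1], n_permutations, seed)
        identity = int(np.nonzero((signs == 1.0).all(axis=1))[0][0])
        signs[[0, identity]] = signs[[identity, 0]]
        stats = _paired_d_for_signs(D, signs, design.s0)
        obs = stats[0]
        log2fc = D.mean(axis=1)
    else:
        ids_a, ids_b = design.group_samples(list(annotations))
        if len(ids_a) < 2 or len(ids_b) < 2:
            raise ValidationError("need at least 2 samples per group")
        V = tmatrix[ids_a + ids_b].to_numpy()
        masks, _ = _enumerate_masks(V.shape[1], len(ids_b), n_permutations, seed)
        stats = _d_for_masks(V, masks, design.s0)
        obs = stats[0]  # masks[0] is the observed assignment
        log2fc = V[:, len(ids_a):].mean(axis=1) - V[:, : len(ids_a)].mean(axis=1)

    null_abs = np.abs(stats)
    obs_abs = np.abs(obs)
    q = _fdr_from_null(obs_abs, null_abs)
    p_per_protein = (null_abs >= obs_abs[None, :]).mean(axis=0)
    return pd.DataFrame(
        {
            "statistic": obs,
            "p_value": p_per_protein,
            "q_value": q,
            "log2fc": log2fc,
            "significant": q <= design.alpha_perm,
            "method": "frequentist",
        },
        index=pd.Index(tmatrix.index, name="protein_id"),
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResults:
    """Differential-abundance results for one comparison and one arm."""

    table: pd.DataFrame
    design: ComparisonDesign
    method: str
    n_tested: int
    n_input: int
    extra: dict = field(default_factory=dict)

    @property
    def significant_proteins(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()

    def summary(self) -> str:
        lines = [
            f"{self.method} differential abundance: "
            f"{self.design.group_b} vs {self.design.group_a}",
            f"  proteins in input:   {self.n_input}",
            f"  proteins tested:     {self.n_tested}",
            f"  significant:         {len(self.significant_proteins)}",
        ]
        for k, v in self.extra.items():
            lines.append(f"  {k}: {v}")
        top = self.table.loc[self.table["significant"]].copy()
        if len(top):
            top = top.reindex(top["statistic"].abs().sort_values(ascending=False).index)
            lines.append(top.head(10).to_string())
        return "\n".join(lines)


class FrequentistDifferential:
    """Frequentist arm: presence filter, log2/median-center, MNAR imputation,
    then permutation FDR (colony scale) or Welch t + BH (individual scale)."""

    def __init__(
        self,
        matrix: AbundanceMatrix,
        annotations: Sequence[SampleAnnotation],
        design: ComparisonDesign,
        config: PreprocessConfig | None = None,
    ):
        self.matrix = matrix
        self.annotations = list(annotations)
        self.design = design
        self.config = config or PreprocessConfig(presence_fraction=design.presence_fraction)

    def _auto_method(self) -> str:
        ids_a, ids_b = self.design.group_samples(self.annotations)
        scales = {
            a.scale for a in self.annotations if a.sample_id in set(ids_a + ids_b)
        }
        return "bh" if scales == {"individual"} else "permutation"

    def fit(
        self,
        n_permutations: int = 1000,
        seed: int | None = None,
        method: str | None = None,
    ) -> DifferentialResults:
        method = method or self._auto_method()
        if method not in ("permutation", "bh"):
            raise ValueError(f"unknown method {method!r}")
        ids_a, ids_b = self.design.group_samples(self.annotations)
        sub = self.matrix.select_samples(ids_a + ids_b)
        filtered = presence_filter(sub, self.config.presence_fraction)
        if filtered.n_proteins == 0:
            table = pd.DataFrame(
                columns=["statistic", "p_value", "q_value", "log2fc", "significant", "method"]
            )
            return DifferentialResults(table, self.design, "frequentist", 0, sub.n_proteins)
        centered = log2_median_center(filtered)
        config = self.config
        if seed is not None:
            config = PreprocessConfig(
                presence_fraction=config.presence_fraction,
                impute_shift_sd=config.impute_shift_sd,
                impute_width_sd=config.impute_width_sd,
                seed=seed,
            )
        complete = impute_downshifted(centered, config)
        if method == "permutation":
            table = permutation_fdr(
                complete,
                self.annotations,
                self.design,
                n_permutations=n_permutations,
                seed=config.seed,
            )
            extra = {"fdr": f"permutation <= {self.design.alpha_perm}", "s0": self.design.s0}
        else:
            table = self._welch_bh(complete, ids_a, ids_b)
            extra = {"fdr": f"Benjamini-Hochberg <= {self.design.alpha_bh}"}
        return DifferentialResults(
            table, self.design, "frequentist", filtered.n_proteins, sub.n_proteins, extra
        )

    def _welch_bh(self, complete: pd.DataFrame, ids_a: list[str], ids_b: list[str]) -> pd.DataFrame:
        A = complete[ids_a].to_numpy()
        B = complete[ids_b].to_numpy()
        if self.design.paired:
            res = scipy.stats.ttest_rel(B, A, axis=1)
        else:
            res = scipy.stats.ttest_ind(B, A, axis=1, equal_var=False)
        q = bh_fdr(res.pvalue)
        return pd.DataFrame(
            {
                "statistic": res.statistic,
                "p_value": res.pvalue,
                "q_value": q,
                "log2fc": B.mean(axis=1) - A.mean(axis=1),
                "significant": q <= self.design.alpha_bh,
                "method": "frequentist",
            },
            index=pd.Index(complete.index, name="protein_id"),
        )


def run_frequentist(
    matrix: AbundanceMatrix,
    annotations: Sequence[SampleAnnotation],
    design: ComparisonDesign,
    config: PreprocessConfig | None = None,
    n_permutations: int = 1000,
    method: str | None = None,
) -> DifferentialResults:
    """Functional wrapper over :class:`FrequentistDifferential`."""
    return FrequentistDifferential(matrix, annotations, design, config).fit(
        n_permutations=n_permutations, method=method
    )


# ---------------------------------------------------------------------------
# two-way ANOVA (individual dataset: colony x behaviour)
# ---------------------------------------------------------------------------

@dataclass
class AnovaResults:
    table: pd.DataFrame
    n_tested: int

    def summary(self) -> str:
        sig = {
            f: int((self.table[f"q_{f}"] < 0.05).sum())
            for f in ("colony", "behavior", "interaction")
        }
        return (
            f"two-way ANOVA on {self.n_tested} proteins; "
            + ", ".join(f"{k}: {v} at q<0.05" for k, v in sig.items())
        )


def two_way_anova(
    matrix: AbundanceMatrix,
    annotations: Sequence[SampleAnnotation],
    config: PreprocessConfig | None = None,
) -> AnovaResults:
    """Per-protein colony x behaviour ANOVA with type-II sums of squares.

    Behaviour is the sample_type label; values are preprocessed exactly as
    for the frequentist tests (presence filter, log2 median-centering, MNAR
    imputation).  BH adjustment is applied across proteins within each
    factor.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    config = config or PreprocessConfig()
    frame = pd.DataFrame(
        {
            "colony": [a.colony_id for a in annotations],
            "behavior": [a.sample_type for a in annotations],
        },
        index=[a.sample_id for a in annotations],
    )
    if frame["colony"].isna().any():
        raise ValidationError("two_way_anova requires colony_id on every sample")
    cells = frame.groupby(["colony", "behavior"]).size().unstack(fill_value=0)
    if (cells == 0).any().any():
        raise ValidationError(f"empty colony x behavior cell(s):\n{cells}")

    sub = matrix.select_samples(frame.index.tolist())
    filtered = presence_filter(sub, config.presence_fraction)
    complete = impute_downshifted(log2_median_center(filtered), config)

    rows = {}
    for protein in complete.index:
        dat = frame.copy()
        dat["y"] = complete.loc[protein, dat.index].to_numpy()
        fit = ols("y ~ C(colony) * C(behavior)", data=dat).fit()
        aov = sm.stats.anova_lm(fit, typ=2)
        rows[protein] = {
            "F_colony": aov.loc["C(colony)", "F"],
            "F_behavior": aov.loc["C(behavior)", "F"],
            "F_interaction": aov.loc["C(colony):C(behavior)", "F"],
            "p_colony": aov.loc["C(colony)", "PR(>F)"],
            "p_behavior": aov.loc["C(behavior)", "PR(>F)"],
            "p_interaction": aov.loc["C(colony):C(behavior)", "PR(>F)"],
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "protein_id"
    for f in ("colony", "behavior", "interaction"):
        table[f"q_{f}"] = bh_fdr(table[f"p_{f}"].to_numpy())
    return AnovaResults(table, len(table))
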