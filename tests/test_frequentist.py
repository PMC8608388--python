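import itertools
import math
import statistics

import numpy as np
import pandas as pd
import pytest

from tropho import (
    AbundanceMatrix,
    ComparisonDesign,
    PreprocessConfig,
    SampleAnnotation,
    TrophoError,
    ValidationError,
    bh_fdr,
    permutation_fdr,
    run_frequentist,
    s0_statistic,
    two_way_anova,
)
from tropho.frequentist import paired_s0_statistic
from tropho.simulate import SyntheticSpec, generate


# ---------------------------------------------------------------------------
# independent oracles (plain-python enumeration)
# ---------------------------------------------------------------------------

def oracle_d(a, b, s0):
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * statistics.variance(a) + (nb - 1) * statistics.variance(b)) / (
        na + nb - 2
    )
    se = math.sqrt(sp2 * (1 / na + 1 / nb))
    return (statistics.mean(b) - statistics.mean(a)) / (se + s0)


def oracle_permutation_q(V, na, s0, paired=False):
    """Brute-force exhaustive permutation FDR with naive loops.

    V: list of per-protein value lists (group a first).  Returns per-protein
    (observed d, q) using the same FDR definition: at threshold t,
    (mean #null >= t over assignments) / (#observed >= t), each protein's q
    the minimum estimate over thresholds at which it is still called.
    """
    n = len(V[0])
    if paired:
        m = n // 2
        assignments = list(itertools.product([1, -1], repeat=m))

        def stat(vals, signs):
            diffs = [s * (vals[m + i] - vals[i]) for i, s in enumerate(signs)]
            se = statistics.stdev(diffs) / math.sqrt(m)
            return statistics.mean(diffs) / (se + s0)

        obs = [stat(v, tuple([1] * m)) for v in V]
        null = [[abs(stat(v, s)) for v in V] for s in assignments]
    else:
        assignments = list(itertools.combinations(range(n), n - na))

        def stat(vals, b_idx):
            b = [vals[i] for i in b_idx]
            a = [vals[i] for i in range(n) if i not in b_idx]
            return oracle_d(a, b, s0)

        obs = [stat(v, tuple(range(na, n))) for v in V]
        null = [[abs(stat(v, c)) for v in V] for c in assignments]

    obs_abs = [abs(d) for d in obs]
    raw = {}
    for t in obs_abs:
        n_null = sum(1 for row in null for x in row if x >= t)
        r = sum(1 for x in obs_abs if x >= t)
        raw[t] = min(n_null / len(assignments) / r, 1.0)
    q = [min(raw[t] for t in obs_abs if t <= obs_abs[g]) for g in range(len(V))]
    return obs, q


def _tmatrix(V):
    V = np.asarray(V, dtype=float)
    return pd.DataFrame(
        V,
        index=[f"P{g}" for g in range(V.shape[0])],
        columns=[f"x{j}" for j in range(V.shape[1])],
    )


def _annotations(na, nb, pair=False):
    ann = []
    for i in range(na):
        ann.append(SampleAnnotation(f"x{i}", "A", pair_key=f"k{i}" if pair else None))
    for i in range(nb):
        ann.append(
            SampleAnnotation(f"x{na + i}", "B", pair_key=f"k{i}" if pair else None)
        )
    return ann


# ---------------------------------------------------------------------------
# S0 statistic
# ---------------------------------------------------------------------------

class TestS0Statistic:
    def test_worked_example_matches_hand_arithmetic(self):
        assert s0_statistic([1, 2, 3], [4, 5, 6], 0) == pytest.approx(3.674, abs=1e-3)
        assert s0_statistic([1, 2, 3], [4, 5, 6], 2) == pytest.approx(1.065, abs=1e-3)

    def test_matches_oracle_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(2, 6)).tolist()
            b = rng.normal(1, 2, rng.integers(2, 6)).tolist()
            s0 = float(rng.uniform(0, 3))
            assert s0_statistic(a, b, s0) == pytest.approx(oracle_d(a, b, s0), rel=1e-12)

    def test_antisymmetric_under_group_swap(self):
        assert s0_statistic([4, 5, 6], [1, 2, 3], 0) == pytest.approx(-3.674, abs=1e-3)

    def test_large_s0_shrinks_to_zero(self):
        assert abs(s0_statistic([1, 2, 3], [400, 500, 600], 1e12)) < 1e-9

    def test_zero_variance_with_zero_s0_is_error(self):
        with pytest.raises(TrophoError):
            s0_statistic([1, 1, 1], [2, 2, 2], 0)
        assert np.isfinite(s0_statistic([1, 1, 1], [2, 2, 2], 2))


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

class TestBhFdr:
    def test_worked_example(self):
        out = bh_fdr([0.01, 0.04, 0.03, 0.002])
        assert np.allclose(out, [0.02, 0.04, 0.04, 0.008])

    def test_order_invariance_and_dominates_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        perm = rng.permutation(40)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))
        assert (bh_fdr(p) >= p - 1e-15).all()

    def test_degenerate_inputs(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)
        assert bh_fdr([0.7])[0] == 0.7
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------

class TestPermutationFdr:
    def test_single_protein_worked_example(self):
        table = permutation_fdr(
            _tmatrix([[1, 2, 3, 10, 11, 12]]),
            _annotations(3, 3),
            ComparisonDesign("A", "B", s0=0.0),
            n_permutations=1000,
        )
        # exhaustive over C(6,3)=20 assignments; 2 reproduce the extreme |d|
        assert table["q_value"].iloc[0] == pytest.approx(0.1)
        assert not table["significant"].iloc[0]

    def test_exhaustive_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(12):
            na = int(rng.integers(2, 5))
            nb = int(rng.integers(2, 5))
            p = int(rng.integers(1, 6))
            V = rng.normal(0, 1, size=(p, na + nb))
            V[0, na:] += 2.0
            table = permutation_fdr(
                _tmatrix(V),
                _annotations(na, nb),
                ComparisonDesign("A", "B", s0=1.0),
                n_permutations=10_000,
            )
            obs, q = oracle_permutation_q(V.tolist(), na, 1.0)
            assert np.allclose(table["statistic"], obs, atol=1e-9)
            assert np.allclose(table["q_value"], q, atol=1e-9)

    def test_paired_exhaustive_matches_oracle(self):
        rng = np.random.default_rng(8)
        m = 5
        V = rng.normal(0, 1, size=(4, 2 * m))
        V[0, m:] += 3.0
        table = permutation_fdr(
            _tmatrix(V),
            _annotations(m, m, pair=True),
            ComparisonDesign("A", "B", paired=True, s0=0.5),
            n_permutations=10_000,
        )
        obs, q = oracle_permutation_q(V.tolist(), m, 0.5, paired=True)
        assert np.allclose(table["statistic"], obs, atol=1e-9)
        assert np.allclose(table["q_value"], q, atol=1e-9)

    def test_q_values_non_increasing_in_statistic(self):
        rng = np.random.default_rng(9)
        V = rng.normal(0, 1, size=(40, 12))
        table = permutation_fdr(
            _tmatrix(V), _annotations(6, 6), ComparisonDesign("A", "B"), 500, seed=1
        )
        ordered = table.reindex(
            table["statistic"].abs().sort_values(ascending=False).index
        )
        assert (np.diff(ordered["q_value"]) >= -1e-12).all()

    def test_incomplete_matrix_rejected(self):
        t = _tmatrix([[1, 2, 3, 4]])
        t.iloc[0, 0] = np.nan
        with pytest.raises(ValidationError):
            permutation_fdr(t, _annotations(2, 2), ComparisonDesign("A", "B"))


# ---------------------------------------------------------------------------
# full frequentist arm
# ---------------------------------------------------------------------------

class TestRunFrequentist:
    def test_perfect_signal_protein_is_significant(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(14, 0.2, size=(30, 12))
        vals[0, 6:] *= 2.0**6  # one protein shifted by 6 log2 units
        matrix = AbundanceMatrix.from_arrays(
            vals, [f"P{i}" for i in range(30)], [f"x{j}" for j in range(12)]
        )
        res = run_frequentist(
            matrix, _annotations(6, 6), ComparisonDesign("A", "B"), PreprocessConfig(seed=0)
        )
        assert "P0" in res.significant_proteins
        assert res.n_tested == 30

    def test_null_data_mostly_empty(self):
        hits = 0
        for run in range(3):
            matrix, ann, _ = generate(
                SyntheticSpec(n_proteins=120, n_samples_per_group=8, n_da=0, seed=300 + run)
            )
            res = run_frequentist(
                matrix, ann, ComparisonDesign("A", "B"), PreprocessConfig(seed=run)
            )
            hits += len(res.significant_proteins) > 0
        assert hits <= 1

    def test_individual_scale_switches_to_bh(self):
        matrix, ann, _ = generate(
            SyntheticSpec(n_proteins=60, n_samples_per_group=8, n_da=6, scale="individual", seed=2)
        )
        res = run_frequentist(matrix, ann, ComparisonDesign("A", "B"))
        assert res.extra["fdr"].startswith("Benjamini")
        assert res.table["p_value"].between(0, 1).all()

    def test_paired_design_detects_pure_shift(self):
        rng = np.random.default_rng(6)
        m = 8
        vals = rng.lognormal(14, 0.5, size=(25, 2 * m))
        vals[3, m:] = vals[3, :m] * 2.0**4  # paired shift, zero pair noise
        matrix = AbundanceMatrix.from_arrays(
            vals, [f"P{i}" for i in range(25)], [f"x{j}" for j in range(2 * m)]
        )
        res = run_frequentist(
            matrix,
            _annotations(m, m, pair=True),
            ComparisonDesign("A", "B", paired=True),
            PreprocessConfig(seed=0),
        )
        assert "P3" in res.significant_proteins

    def test_paired_statistic_oracle(self):
        d = [1.0, 1.5, 0.5, 2.0]
        se = statistics.stdev(d) / 2
        assert paired_s0_statistic(d, 0.7) == pytest.approx(
            statistics.mean(d) / (se + 0.7), rel=1e-12
        )


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

def _individual_annotations(n_colonies, reps):
    ann = []
    for c in range(n_colonies):
        for b, role in enumerate(["Nurse", "Forager"]):
            for r in range(reps):
                ann.append(
                    SampleAnnotation(
                        f"c{c}{role[0]}{r}",
                        role,
                        colony_id=f"C{c}",
                        scale="individual",
                    )
                )
    return ann


class TestTwoWayAnova:
    def _matrix_from(self, build, ann, n_proteins, seed):
        rng = np.random.default_rng(seed)
        cols = [a.sample_id for a in ann]
        vals = np.empty((n_proteins, len(cols)))
        for g in range(n_proteins):
            for j, a in enumerate(ann):
                vals[g, j] = build(g, a, rng)
        return AbundanceMatrix.from_arrays(
            np.exp2(vals + 20), [f"P{g}" for g in range(n_proteins)], cols
        )

    def test_pure_behavior_effect(self):
        # behaviour shifts a minority of proteins so per-sample median
        # centering leaves the effect intact
        ann = _individual_annotations(3, 3)
        m = self._matrix_from(
            lambda g, a, rng: (3.0 if a.sample_type == "Forager" and g < 6 else 0.0)
            + 0.05 * rng.normal(),
            ann,
            24,
            seed=1,
        )
        res = two_way_anova(m, ann)
        assert (res.table["q_behavior"].iloc[:6] < 1e-6).all()
        assert (res.table["F_interaction"].iloc[:6] < 2.0).all()

    def test_planted_interaction_recovered(self):
        ann = _individual_annotations(2, 4)
        def build(g, a, rng):
            y = 0.3 * rng.normal()
            if g < 20 and a.colony_id == "C0" and a.sample_type == "Forager":
                y += 3.0  # colony-specific behavioural shift
            return y
        m = self._matrix_from(build, ann, 60, seed=2)
        res = two_way_anova(m, ann)
        hits = (res.table["q_interaction"].iloc[:20] < 0.05).sum()
        assert hits >= 15

    def test_null_interaction_p_approximately_uniform(self):
        ann = _individual_annotations(3, 3)
        m = self._matrix_from(lambda g, a, rng: rng.normal(), ann, 300, seed=3)
        res = two_way_anova(m, ann)
        frac = (res.table["p_interaction"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.04

    def test_empty_cell_is_error(self):
        ann = _individual_annotations(2, 2)
        ann = [a for a in ann if not (a.colony_id == "C0" and a.sample_type == "Nurse")]
        m = self._matrix_from(lambda g, a, rng: rng.normal(), ann, 5, seed=4)
        with pytest.raises(ValidationError):
            two_way_anova(m, ann)
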