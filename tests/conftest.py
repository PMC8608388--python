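import numpy as np
import pandas as pd
import pytest

from tropho import AbundanceMatrix, ComparisonDesign, SampleAnnotation


@pytest.fixture
def protein_groups_tsv(tmp_path):
    """proteinGroups-dialect fixture: 5 rows covering flags, scores, empty cells.

    Of the five proteins only P1 (score 120) and P5 (score exactly 70)
    survive the standard filter; P2 is a contaminant, P3 a decoy, P4 scores
    49.5.  One iBAQ cell of P1 is empty (encodes not-detected).
    """
    rows = [
        "Majority protein IDs\tScore\tPotential contaminant\tReverse\tOnly identified by site\tiBAQ s1\tiBAQ s2",
        "P1;P1b\t120\t\t\t\t1000000\t",
        "CON__P2\t90\t+\t\t\t500\t600",
        "REV__P3\t80\t\t+\t\t0\t0",
        "P4\t49.5\t\t\t\t200\t300",
        "P5\t70\t\t\t\t40000\t50000",
    ]
    path = tmp_path / "proteinGroups.tsv"
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def metadata_csv(tmp_path):
    path = tmp_path / "metadata.csv"
    path.write_text(
        "sample_id,sample_type,colony_id,volume_ul,pair_key,scale\n"
        "s1,Field,c1,3.5,k1,colony\n"
        "s2,Lab,c1,2.0,k1,colony\n"
        "s3,Field,c2,4.0,k2,colony\n"
        "s4,Lab,c2,1.5,k2,colony\n"
    )
    return path


@pytest.fixture
def two_group_annotations():
    def make(n_a, n_b, scale="colony"):
        return [
            SampleAnnotation(f"a{i}", "A", scale=scale) for i in range(n_a)
        ] + [SampleAnnotation(f"b{i}", "B", scale=scale) for i in range(n_b)]

    return make


@pytest.fixture
def small_matrix():
    """4 proteins x 4 samples with one never-detected-everywhere protein."""
    values = np.array(
        [
            [100.0, 200.0, 300.0, 400.0],
            [10.0, 0.0, 30.0, 40.0],
            [1.0, 2.0, 0.0, 0.0],
            [5e6, 6e6, 7e6, 8e6],
        ]
    )
    return AbundanceMatrix.from_arrays(
        values, ["P1", "P2", "P3", "P4"], ["a0", "a1", "b0", "b1"]
    )


@pytest.fixture
def default_design():
    return ComparisonDesign("A", "B")
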