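"""Two-of-three consensus over the frequentist, empirical-Bayes and
random-forest significance calls, with Venn partitioning.

Each arm tests a different protein universe (the frequentist arm only
presence-filtered proteins, the moderated-t arm only proteins with enough
observations, the forest arm everything it was given); a protein untested
by an arm counts as not significant in that arm.  A protein is in the
consensus set when at least two arms call it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data import TrophoError

__all__ = ["ConsensusResult", "combine", "venn_counts", "VENN_REGIONS"]

_ARMS = ("frequentist", "ebayes", "rf")
#: the seven exclusive regions of a three-set Venn diagram
VENN_REGIONS = (
    "frequentist_only",
    "ebayes_only",
    "rf_only",
    "frequentist_ebayes",
    "frequentist_rf",
    "ebayes_rf",
    "all_three",
)


def _significant_set(table) -> set[str]:
    if isinstance(table, (set, frozenset, list)):
        return set(table)
    if hasattr(table, "table"):  # a Results object
        table = table.table
    if isinstance(table, pd.DataFrame):
        for col in ("significant", "selected"):
            if col in table.columns:
                return set(table.index[table[col].astype(bool)])
        raise TrophoError("table has no 'significant' or 'selected' column")
    raise TrophoError(f"cannot extract significance flags from {type(table)}")


def _universe(table) -> set[str]:
    if isinstance(table, (set, frozenset, list)):
        return set(table)
    if hasattr(table, "table"):
        table = table.table
    return set(table.index)


@dataclass
class ConsensusResult:
    """Joined significance flags and Venn partition of the three arms."""

    table: pd.DataFrame
    venn: dict[str, int]

    @property
    def consensus_proteins(self) -> list[str]:
        return self.table.index[self.table["consensus"]].tolist()

    def summary(self) -> str:
        sizes = {a: int(self.table[f"sig_{a}"].sum()) for a in _ARMS}
        lines = [
            "two-of-three consensus",
            "  per-arm significant: "
            + ", ".join(f"{a}={n}" for a, n in sizes.items()),
            f"  consensus (>=2 arms): {len(self.consensus_proteins)}",
            "  Venn regions: "
            + ", ".join(f"{k}={v}" for k, v in self.venn.items() if v),
        ]
        return "\n".join(lines)


def combine(freq, ebayes, rf) -> ConsensusResult:
    """Overlay three per-arm results into the 2-of-3 consensus table.

    Inputs may be differential tables (with a boolean ``significant`` or
    ``selected`` column), Results objects carrying one, or plain sets of
    significant protein ids (then the universe is that set).
    """
    tables = {"frequentist": freq, "ebayes": ebayes, "rf": rf}
    universes = {a: _universe(t) for a, t in tables.items()}
    if not set.intersection(*universes.values()):
        raise TrophoError("the three arms share no proteins: nothing to combine")
    sig = {a: _significant_set(t) for a, t in tables.items()}
    all_proteins = sorted(set.union(*universes.values()))
    df = pd.DataFrame(index=pd.Index(all_proteins, name="protein_id"))
    for a in _ARMS:
        df[f"sig_{a}"] = [p in sig[a] for p in all_proteins]
    df["n_methods"] = df[[f"sig_{a}" for a in _ARMS]].sum(axis=1)
    df["consensus"] = df["n_methods"] >= 2
    return ConsensusResult(df, venn_counts(df))


def venn_counts(table: pd.DataFrame) -> dict[str, int]:
    """Counts of the seven exclusive Venn regions of the three arms."""
    f = table["sig_frequentist"].to_numpy(dtype=bool)
    e = table["sig_ebayes"].to_numpy(dtype=bool)
    r = table["sig_rf"].to_numpy(dtype=bool)
    return {
        "frequentist_only": int((f & ~e & ~r).sum()),
        "ebayes_only": int((~f & e & ~r).sum()),
        "rf_only": int((~f & ~e & r).sum()),
        "frequentist_ebayes": int((f & e & ~r).sum()),
        "frequentist_rf": int((f & ~e & r).sum()),
        "ebayes_rf": int((~f & e & r).sum()),
        "all_three": int((f & e & r).sum()),
    }
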