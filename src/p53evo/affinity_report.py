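"""Summary analytics over a table of measured MDM2/p53TAD affinities.

The packaged fixture holds the measured dissociation constants for the
human reference interaction and 12 fish p53TAD/MDM2 interactions: for each
species (and teleost paralog) the canonical-motif peptide affinity, the
cross-species affinities against human MDM2 or the human peptide, and the
full-length transactivation-domain affinity.  The analytics answer the
questions this table is built for: how much the disordered flanking regions
change affinity (fold change motif -> full length), how many extant motifs
sit in a given affinity band, how many interactions tighten with flanks,
and how correlated motif and full-length affinities are.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Numeric K_D columns recognised by the analytics.
KD_COLUMNS = (
    "kd_motif_native",
    "kd_vs_human_mdm2",
    "kd_human_peptide",
    "kd_fulllength_native",
    "kd_fulllength_prior",
)


class MissingValueError(ValueError):
    pass


@dataclass
class AffinityTable:
    """Species x affinity-measurement table (all K_D values in uM)."""

    data: pd.DataFrame

    def __post_init__(self):
        required = {"label", "species", "motif_seq", *KD_COLUMNS[:1]}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"affinity table missing columns: {sorted(missing)}")
        for col in KD_COLUMNS:
            if col in self.data.columns:
                vals = self.data[col].dropna()
                if (vals <= 0).any():
                    raise ValueError(f"column {col} contains nonpositive K_D values")

    # -- access -------------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "AffinityTable":
        return cls(pd.read_csv(path, comment="#"))

    @classmethod
    def packaged_fixture(cls) -> "AffinityTable":
        with resources.files("p53evo.data").joinpath(
            "table1_affinities.csv"
        ).open() as fh:
            return cls(pd.read_csv(fh, comment="#"))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def labels(self) -> list[str]:
        return list(self.data["label"])

    def row(self, label: str) -> pd.Series:
        hit = self.data[self.data["label"] == label]
        if hit.empty:
            raise KeyError(f"no row labelled {label!r}")
        return hit.iloc[0]

    def fish_rows(self) -> pd.DataFrame:
        """The non-human rows (the extant fish interactions)."""
        return self.data[self.data["species"] != "Homo sapiens"]

    def subset(self, which: str) -> pd.DataFrame:
        if which == "all":
            return self.data
        if which == "fish":
            return self.fish_rows()
        if which == "human":
            return self.data[self.data["species"] == "Homo sapiens"]
        raise ValueError("subset must be 'all', 'fish' or 'human'")

    # -- analytics ----------------------------------------------------------

    def fold_change(
        self,
        label: str,
        from_col: str = "kd_motif_native",
        to_col: str = "kd_fulllength_native",
    ) -> float:
        """Affinity gain K_D(from)/K_D(to); > 1 means `to` binds tighter."""
        row = self.row(label)
        for col in (from_col, to_col):
            if col not in self.data.columns:
                raise KeyError(f"unknown column {col!r}")
            if pd.isna(row[col]):
                raise MissingValueError(f"{label!r} has no value in {col!r}")
        return float(row[from_col] / row[to_col])

    def fold_changes(
        self,
        from_col: str = "kd_motif_native",
        to_col: str = "kd_fulllength_native",
        subset: str = "all",
    ) -> pd.Series:
        df = self.subset(subset)
        both = df.dropna(subset=[from_col, to_col])
        return pd.Series(
            (both[from_col] / both[to_col]).to_numpy(),
            index=both["label"].to_numpy(),
            name=f"{from_col}/{to_col}",
        )

    def count_in_range(
        self, column: str, lo: float, hi: float, subset: str = "fish"
    ) -> int:
        """Rows with ``lo <= K_D <= hi`` (closed interval) in ``column``."""
        if column not in self.data.columns:
            raise KeyError(f"unknown column {column!r}")
        if lo > hi:
            raise ValueError("lo must not exceed hi")
        vals = self.subset(subset)[column].dropna()
        return int(((vals >= lo) & (vals <= hi)).sum())

    def count_improved(
        self,
        from_col: str = "kd_motif_native",
        to_col: str = "kd_fulllength_native",
        subset: str = "fish",
    ) -> tuple[int, list[str]]:
        """How many interactions tighten from motif to full length.

        Returns ``(count, exceptions)`` where exceptions are the labels of
        rows (with both values present) that did *not* improve (strict
        inequality required to count as improved).
        """
        df = self.subset(subset).dropna(subset=[from_col, to_col])
        improved = df[to_col] < df[from_col]
        exceptions = list(df.loc[~improved, "label"])
        return int(improved.sum()), exceptions

    def motif_vs_fulllength_correlation(
        self,
        scale: str = "linear",
        subset: str = "fish",
        from_col: str = "kd_motif_native",
        to_col: str = "kd_fulllength_native",
    ) -> dict:
        """Squared Pearson correlation between motif and full-length K_Ds.

        ``scale`` is ``"linear"`` or ``"log"`` (base-10 on both columns).
        Returns a dict with ``r2`` plus the subset/scale metadata, so the
        convention behind the number travels with it.
        """
        if scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")
        df = self.subset(subset).dropna(subset=[from_col, to_col])
        if len(df) < 3:
            raise ValueError("need at least 3 paired rows for a correlation")
        x = df[from_col].to_numpy(float)
        y = df[to_col].to_numpy(float)
        if scale == "log":
            x, y = np.log10(x), np.log10(y)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return {"r2": np.nan, "scale": scale, "subset": subset,
                    "n": len(df), "degenerate": True}
        r, _ = stats.pearsonr(x, y)
        return {"r2": float(r**2), "scale": scale, "subset": subset,
                "n": len(df), "degenerate": False}

    def summary(self) -> dict:
        """The headline analytics in one dict (used by the report CLI)."""
        folds = self.fold_changes(subset="all")
        fish_folds = self.fold_changes(subset="fish")
        n_improved, exceptions = self.count_improved()
        return {
            "n_rows": len(self.data),
            "n_fish_rows": len(self.fish_rows()),
            "max_fold_change": float(folds.max()),
            "max_fold_change_label": str(folds.idxmax()),
            "min_fish_fold_change": float(fish_folds.min()),
            "human_fold_change": self.fold_change("H. sapiens"),
            "n_fish_improved_fulllength": n_improved,
            "not_improved": exceptions,
            "n_fish_motif_kd_in_0.6_4.5": self.count_in_range(
                "kd_motif_native", 0.6, 4.5, subset="fish"
            ),
            "motif_vs_fulllength_r2_linear": self.motif_vs_fulllength_correlation(
                "linear"
            )["r2"],
            "motif_vs_fulllength_r2_log": self.motif_vs_fulllength_correlation(
                "log"
            )["r2"],
        }


def fold_change(table: AffinityTable, label: str, from_col: str, to_col: str) -> float:
    return table.fold_change(label, from_col, to_col)


def count_in_range(table, column, lo, hi, subset="fish") -> int:
    return table.count_in_range(column, lo, hi, subset)


def count_improved(table, subset="fish") -> tuple[int, list[str]]:
    return table.count_improved(subset=subset)


def motif_vs_fulllength_correlation(table, scale="linear", subset="fish") -> dict:
    return table.motif_vs_fulllength_correlation(scale=scale, subset=subset)
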