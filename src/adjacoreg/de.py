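"""Differential-expression tables, deregulated gene selection, control sets.

A DE table holds per-gene log2 fold change (mutant/wild type) and a
*P*-value. Deregulated genes are those beyond a fold threshold (default
``|log2FC| >= 0.8``, i.e. 1.74-fold) at ``p <= 0.05``. The control set is
the opposite cohort: the genes with the smallest absolute fold changes,
sign-balanced about zero, used as the null cohort in the adjacency test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

__all__ = [
    "DERecord",
    "SignedDESet",
    "as_de_frame",
    "read_de_table",
    "write_de_table",
    "select_deregulated",
    "build_control_set",
]

DE_COLUMNS = ("gene_id", "log2fc", "p_value")

DEFAULT_MIN_ABS_LOG2FC = 0.8  # == log2(1.74-fold)
DEFAULT_MAX_P = 0.05


@dataclass(frozen=True)
class DERecord:
    gene_id: str
    log2fc: float
    p_value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2fc):
            raise ValueError(f"gene {self.gene_id}: log2fc must be finite")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(
                f"gene {self.gene_id}: p_value {self.p_value} outside [0, 1]"
            )


@dataclass(frozen=True)
class SignedDESet:
    """Deregulated genes with direction: gene_id -> sign in {+1, -1}."""

    signs: Mapping[str, int]
    min_abs_log2fc: float
    max_p: float

    @property
    def n_up(self) -> int:
        return sum(1 for s in self.signs.values() if s > 0)

    @property
    def n_down(self) -> int:
        return sum(1 for s in self.signs.values() if s < 0)

    def __len__(self) -> int:
        return len(self.signs)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.signs

    def sign(self, gene_id: str) -> int:
        return self.signs[gene_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.signs.items()), columns=["gene_id", "sign"]
        )


DETableLike = Union[pd.DataFrame, Iterable[DERecord]]


def as_de_frame(table: DETableLike) -> pd.DataFrame:
    """Coerce a DE table (DataFrame or DERecord iterable) to a DataFrame."""
    if isinstance(table, pd.DataFrame):
        missing = set(DE_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"DE table missing columns {sorted(missing)}")
        df = table.loc[:, list(DE_COLUMNS)].copy()
    else:
        df = pd.DataFrame(
            [(r.gene_id, r.log2fc, r.p_value) for r in table],
            columns=list(DE_COLUMNS),
        )
    df["gene_id"] = df["gene_id"].astype(str)
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_id in DE table: {dups[:5]}")
    if not np.isfinite(df["log2fc"].to_numpy(dtype=float)).all():
        raise ValueError("DE table contains non-finite log2fc")
    p = df["p_value"].to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("DE table contains p_value outside [0, 1]")
    return df


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a DE table TSV with header ``gene_id  log2fc  p_value``."""
    return as_de_frame(pd.read_csv(path, sep="\t"))


def write_de_table(table: DETableLike, path: str | Path) -> None:
    as_de_frame(table).to_csv(path, sep="\t", index=False)


def select_deregulated(
    table: DETableLike,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    max_p: float = DEFAULT_MAX_P,
) -> SignedDESet:
    """Select genes with ``|log2fc| >= min_abs_log2fc`` and ``p <= max_p``.

    Both boundaries are inclusive. The sign of each member is the sign of
    its log2 fold change.
    """
    if min_abs_log2fc <= 0:
        raise ValueError("min_abs_log2fc must be positive")
    if max_p < 0:
        raise ValueError("max_p must be non-negative")
    df = as_de_frame(table)
    mask = (df["log2fc"].abs() >= min_abs_log2fc) & (df["p_value"] <= max_p)
    selected = df.loc[mask]
    signs = {
        gid: (1 if fc > 0 else -1)
        for gid, fc in zip(selected["gene_id"], selected["log2fc"])
    }
    return SignedDESet(signs=signs, min_abs_log2fc=min_abs_log2fc, max_p=max_p)


def build_control_set(
    table: DETableLike,
    target_size: int,
    excluded_ids: Iterable[str] = (),
    mean_tolerance: float = 0.05,
) -> list[str]:
    """Pick ``target_size`` genes with minimal ``|log2fc|``, sign-balanced.

    Genes are taken alternately from the positive-fold and negative-fold
    pools in order of increasing ``|log2fc|`` (ties broken by gene_id), so
    the up/down counts differ by at most one. Genes in ``excluded_ids``
    (normally the deregulated set) and genes with log2fc exactly 0 are
    never used. The resulting mean log2 fold change must lie within
    ``mean_tolerance`` of zero.

    Returns gene ids sorted lexicographically.
    """
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    df = as_de_frame(table)
    excluded = set(excluded_ids)
    pool = df.loc[~df["gene_id"].isin(excluded) & (df["log2fc"] != 0.0)].copy()
    pool["absfc"] = pool["log2fc"].abs()
    pool = pool.sort_values(["absfc", "gene_id"], kind="mergesort")
    pos = pool.loc[pool["log2fc"] > 0]
    neg = pool.loc[pool["log2fc"] < 0]

    n_pos = (target_size + 1) // 2  # positives get the odd extra pick
    n_neg = target_size // 2
    if len(pos) < n_pos or len(neg) < n_neg:
        raise ValueError(
            "insufficient control candidates: need "
            f"{n_pos} positive (have {len(pos)}) and {n_neg} negative "
            f"(have {len(neg)})"
        )
    chosen = pd.concat([pos.head(n_pos), neg.head(n_neg)])
    mean_fc = float(chosen["log2fc"].mean())
    if abs(mean_fc) > mean_tolerance:
        raise ValueError(
            f"control set mean log2fc {mean_fc:.4f} exceeds tolerance "
            f"{mean_tolerance}; fold changes are not symmetric about zero"
        )
    return sorted(chosen["gene_id"])
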