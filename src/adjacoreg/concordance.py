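"""Cross-study directional gene-list concordance.

Given a reference list of genes reported as up- or down-regulated in one
experiment, how many of them respond in a second (query) experiment?

*Overall* concordance counts reference genes significantly changed in the
query in either direction; *strict* concordance requires the direction to
match the reference expectation. Reference genes never measured in the
query stay in the denominator (an option drops them), which mirrors how
such percentages are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .de import DETableLike, SignedDESet, as_de_frame

__all__ = [
    "DirectionalGeneList",
    "ConcordanceResult",
    "read_gene_lists",
    "overall_concordance",
    "strict_concordance",
    "concordance_matrix",
]

UNSIGNED = 0  # expected-direction marker for genes listed without a sign


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DirectionalGeneList:
    """A reference gene list with expected signs (+1, -1 or 0=unsigned)."""

    study_id: str
    members: Mapping[str, int]
    cluster_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene list {self.study_id!r} is empty")
        bad = {s for s in self.members.values() if s not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"invalid expected signs {bad}; use +1, -1 or 0")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ConcordanceResult:
    """Concordance of one reference list against one query experiment.

    Percentages are stored unrounded; ``overall_pct_display`` /
    ``strict_pct_display`` give the integer form used in reports.
    """

    study_id: str
    cluster_label: Optional[str]
    n_reference: int
    n_query_up: int
    n_query_down: int
    overall_pct: float
    n_strict: Optional[int] = None
    strict_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_query_up + self.n_query_down > self.n_reference:
            raise ValueError("significant counts exceed reference size")
        if self.strict_pct is not None and self.strict_pct > self.overall_pct + 1e-9:
            raise ValueError("strict concordance cannot exceed overall")

    @property
    def overall_pct_display(self) -> int:
        return int(round_half_up(self.overall_pct))

    @property
    def strict_pct_display(self) -> Optional[int]:
        if self.strict_pct is None:
            return None
        return int(round_half_up(self.strict_pct))


def read_gene_lists(path: str | Path) -> list[DirectionalGeneList]:
    """Read reference lists from TSV: gene_id, sign, study_id[, cluster_label]."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "study_id": str})
    required = {"gene_id", "sign", "study_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene-list TSV missing columns {sorted(missing)}")
    if "cluster_label" not in df.columns:
        df["cluster_label"] = None
    lists = []
    for (study, cluster), grp in df.groupby(
        ["study_id", "cluster_label"], dropna=False, sort=True
    ):
        members = dict(zip(grp["gene_id"], grp["sign"].astype(int)))
        lists.append(
            DirectionalGeneList(
                study_id=str(study),
                members=members,
                cluster_label=None if pd.isna(cluster) else str(cluster),
            )
        )
    return lists


def overall_concordance(
    reference: DirectionalGeneList,
    query: DETableLike,
    min_abs_log2fc: float = 0.0,
    max_p: float = 0.05,
    drop_unmeasured: bool = False,
) -> ConcordanceResult:
    """Fraction of reference genes significantly changed in the query.

    A reference gene counts as up (down) when its query record passes
    ``p <= max_p`` with ``log2fc`` above (below) the fold threshold in
    magnitude; by default any nonzero fold at ``p <= 0.05`` qualifies.
    When the reference carries signs, strict concordance (query sign ==
    expected sign among the significant genes) is reported as well.
    """
    df = as_de_frame(query)
    measured = df.set_index("gene_id")
    n_ref = len(reference)
    if drop_unmeasured:
        n_ref = sum(1 for g in reference.members if g in measured.index)
        if n_ref == 0:
            raise ValueError("no reference gene measured in query")

    n_up = n_down = 0
    n_strict = 0
    any_signed = any(s != UNSIGNED for s in reference.members.values())
    for gene, expected in reference.members.items():
        if gene not in measured.index:
            continue
        fc = float(measured.at[gene, "log2fc"])
        p = float(measured.at[gene, "p_value"])
        if p > max_p or abs(fc) < min_abs_log2fc or fc == 0.0:
            continue
        observed = 1 if fc > 0 else -1
        if observed > 0:
            n_up += 1
        else:
            n_down += 1
        if expected != UNSIGNED and observed == expected:
            n_strict += 1

    overall = 100.0 * (n_up + n_down) / n_ref
    return ConcordanceResult(
        study_id=reference.study_id,
        cluster_label=reference.cluster_label,
        n_reference=n_ref,
        n_query_up=n_up,
        n_query_down=n_down,
        overall_pct=overall,
        n_strict=n_strict if any_signed else None,
        strict_pct=(100.0 * n_strict / n_ref) if any_signed else None,
    )


def strict_concordance(
    reference: DirectionalGeneList,
    query_signed: SignedDESet,
) -> ConcordanceResult:
    """Direction-matched concordance against an already-selected query set.

    Every reference member must carry an expected sign. A reference gene
    is overall-concordant when it appears in the query set at all, and
    strictly concordant when its query sign equals the expected sign.
    """
    unsigned = [g for g, s in reference.members.items() if s == UNSIGNED]
    if unsigned:
        raise ValueError(
            f"{len(unsigned)} reference gene(s) have no expected sign "
            "(use overall_concordance for unsigned lists)"
        )
    n_up = n_down = n_strict = 0
    for gene, expected in reference.members.items():
        if gene not in query_signed:
            continue
        observed = query_signed.sign(gene)
        if observed > 0:
            n_up += 1
        else:
            n_down += 1
        if observed == expected:
            n_strict += 1
    n_ref = len(reference)
    return ConcordanceResult(
        study_id=reference.study_id,
        cluster_label=reference.cluster_label,
        n_reference=n_ref,
        n_query_up=n_up,
        n_query_down=n_down,
        overall_pct=100.0 * (n_up + n_down) / n_ref,
        n_strict=n_strict,
        strict_pct=100.0 * n_strict / n_ref,
    )


def concordance_matrix(
    lists: Iterable[DirectionalGeneList],
    query: DETableLike,
    min_abs_log2fc: float = 0.0,
    max_p: float = 0.05,
) -> pd.DataFrame:
    """One concordance row per reference list, ordered by (study, cluster)."""
    lists = list(lists)
    if not lists:
        raise ValueError("need at least one reference list")
    df = as_de_frame(query)
    rows = []
    for ref in sorted(lists, key=lambda l: (l.study_id, l.cluster_label or "")):
        res = overall_concordance(ref, df, min_abs_log2fc, max_p)
        rows.append(
            {
                "study_id": res.study_id,
                "cluster_label": res.cluster_label,
                "n_reference": res.n_reference,
                "n_query_up": res.n_query_up,
                "n_query_down": res.n_query_down,
                "overall_pct": res.overall_pct,
                "overall_pct_display": res.overall_pct_display,
                "n_strict": res.n_strict,
                "strict_pct": res.strict_pct,
            }
        )
    return pd.DataFrame(rows)
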