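"""Adjacent co-regulation detection and enrichment statistics.

The central question: do significantly deregulated genes cluster at
immediately adjacent chromosomal positions more often than chance, and in
the same direction? Three complementary answers are computed:

* a Pearson chi-square on the 2x2 table (deregulated vs control cohort) x
  (member of a same-sign adjacent run: yes/no), df=1, no continuity
  correction;
* a binomial sign model: under independent deregulation, an adjacent pair
  of deregulated genes is sign-concordant with probability p^2 + q^2 and
  discordant with probability 2pq (p = fraction up-regulated), so observed
  discordant pairs predict the chance number of concordant runs;
* a label-permutation null that shuffles which catalogue positions carry
  the deregulation labels.

A *co-regulated set* is a maximal run of >=2 genes at consecutive
catalogue ranks, all deregulated in the same direction, after removing
adjacent links between members of the same duplicate family (duplicated
regulatory elements trivially explain co-regulation). A *discordant pair*
is a consecutive-rank pair of deregulated genes with opposite signs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .annotation import GeneCatalogue
from .de import DETableLike, SignedDESet, as_de_frame, select_deregulated

__all__ = [
    "CoregulatedSet",
    "DiscordantPair",
    "AdjacencyReport",
    "exclude_duplicates",
    "find_coregulated_sets",
    "strand_composition",
    "span_statistics",
    "adjacency_chi2",
    "binomial_sign_null",
    "permutation_null",
    "run_adjacency_analysis",
]


@dataclass(frozen=True)
class CoregulatedSet:
    """A maximal same-sign run of adjacent deregulated genes."""

    chromosome: str
    members: tuple[str, ...]  # genomic order
    direction: int  # +1 or -1
    strands: tuple[str, ...]
    span_bp: int  # max end - min start + 1

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a co-regulated set needs >= 2 members")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if len(self.strands) != len(self.members):
            raise ValueError("strands must match members")
        if self.span_bp < 1:
            raise ValueError("span_bp must be >= 1")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class DiscordantPair:
    """Two adjacent deregulated genes with opposite fold-change signs."""

    chromosome: str
    gene_a: str
    gene_b: str
    sign_a: int
    sign_b: int

    def __post_init__(self) -> None:
        if self.sign_a * self.sign_b != -1:
            raise ValueError("discordant pair requires opposite signs")


@dataclass
class AdjacencyReport:
    """Full statistic bundle for one adjacency analysis."""

    n_up_sets: int
    n_down_sets: int
    n_discordant_pairs: int
    n_duplicate_excluded: int
    opposite_strand_fraction: float  # NaN when no within-set pairs
    mean_span_bp: float  # NaN when no sets
    median_span_bp: float
    n_de_genes: int
    n_de_genes_in_sets: int
    n_control_genes: int
    n_control_genes_in_sets: int
    chi2_stat: float
    chi2_p: float
    expected_concordant: float
    enrichment_ratio: float  # inf when expected undefined (0 discordant)
    binomial_p: float
    permutation_p: Optional[float] = None
    permutation_null_mean: Optional[float] = None
    permutation_null_sd: Optional[float] = None

    @property
    def n_sets(self) -> int:
        return self.n_up_sets + self.n_down_sets

    def to_dict(self) -> dict:
        out = dict(self.__dict__)
        out["n_sets"] = self.n_sets
        return out


# -- detection ---------------------------------------------------------------


def exclude_duplicates(
    adjacent_candidate_pairs: Iterable[tuple[str, str]],
    family_map: Mapping[str, str],
) -> tuple[list[tuple[str, str]], int]:
    """Drop candidate pairs whose two members share a ``family_id``.

    Genes absent from ``family_map`` belong to no family and are never
    excluded. Returns the retained pairs and the number excluded.
    """
    retained: list[tuple[str, str]] = []
    n_excluded = 0
    for a, b in adjacent_candidate_pairs:
        fam_a = family_map.get(a)
        fam_b = family_map.get(b)
        if fam_a is not None and fam_a == fam_b:
            n_excluded += 1
        else:
            retained.append((a, b))
    return retained, n_excluded


def find_coregulated_sets(
    catalogue: GeneCatalogue,
    de_set: SignedDESet,
    family_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[CoregulatedSet], list[DiscordantPair], int]:
    """Detect maximal same-sign adjacent runs and discordant pairs.

    Every deregulated gene must be present in the catalogue. Runs are
    broken wherever an adjacent same-sign link joins two members of the
    same duplicate family; such links are counted as excluded. A gene may
    terminate a concordant run and still participate in a discordant pair.

    Returns ``(sets, discordant_pairs, n_duplicate_excluded)``.
    """
    family_map = family_map or {}
    missing = [g for g in de_set.signs if g not in catalogue]
    if missing:
        raise KeyError(
            f"{len(missing)} deregulated gene(s) absent from catalogue: "
            f"{sorted(missing)[:10]}"
        )

    sets: list[CoregulatedSet] = []
    discordant: list[DiscordantPair] = []
    n_excluded = 0

    for chrom in catalogue.chromosomes:
        genes = catalogue.genes_on(chrom)
        signs = [de_set.signs.get(g.gene_id, 0) for g in genes]
        # Concordant adjacency links surviving duplicate exclusion.
        link = [False] * max(len(genes) - 1, 0)
        for i in range(len(genes) - 1):
            sa, sb = signs[i], signs[i + 1]
            if sa != 0 and sa == sb:
                fam_a = family_map.get(genes[i].gene_id)
                fam_b = family_map.get(genes[i + 1].gene_id)
                if fam_a is not None and fam_a == fam_b:
                    n_excluded += 1
                else:
                    link[i] = True
            elif sa != 0 and sb != 0 and sa != sb:
                discordant.append(
                    DiscordantPair(
                        chromosome=chrom,
                        gene_a=genes[i].gene_id,
                        gene_b=genes[i + 1].gene_id,
                        sign_a=sa,
                        sign_b=sb,
                    )
                )
        # Maximal chains of linked genes.
        i = 0
        while i < len(link):
            if link[i]:
                j = i
                while j < len(link) and link[j]:
                    j += 1
                run = genes[i : j + 1]
                sets.append(
                    CoregulatedSet(
                        chromosome=chrom,
                        members=tuple(g.gene_id for g in run),
                        direction=signs[i],
                        strands=tuple(g.strand for g in run),
                        span_bp=max(g.end for g in run)
                        - min(g.start for g in run)
                        + 1,
                    )
                )
                i = j
            else:
                i += 1
    return sets, discordant, n_excluded


def strand_composition(sets: Sequence[CoregulatedSet]) -> float:
    """Fraction of within-set adjacent gene pairs on opposite strands.

    Counted over all consecutive member pairs of all sets. Returns NaN
    (not 0) when there are no pairs, so an undefined fraction is never
    mistaken for "all same strand".
    """
    n_pairs = 0
    n_opposite = 0
    for s in sets:
        for a, b in zip(s.strands, s.strands[1:]):
            n_pairs += 1
            if a != b:
                n_opposite += 1
    if n_pairs == 0:
        return math.nan
    return n_opposite / n_pairs


def span_statistics(sets: Sequence[CoregulatedSet]) -> tuple[float, float]:
    """Mean and median genomic span (bp) over sets; error on empty input."""
    if not sets:
        raise ValueError("span_statistics requires at least one set")
    spans = np.array([s.span_bp for s in sets], dtype=float)
    return float(spans.mean()), float(np.median(spans))


# -- statistics --------------------------------------------------------------


def adjacency_chi2(
    n_de_in_sets: int,
    n_de_total: int,
    n_ctrl_in_sets: int,
    n_ctrl_total: int,
) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on the 2x2 table
    {cohort: deregulated, control} x {member of same-sign adjacent set}.
    """
    if min(n_de_in_sets, n_de_total, n_ctrl_in_sets, n_ctrl_total) < 0:
        raise ValueError("counts must be non-negative")
    if n_de_in_sets > n_de_total or n_ctrl_in_sets > n_ctrl_total:
        raise ValueError("members cannot exceed totals")
    table = np.array(
        [
            [n_de_in_sets, n_de_total - n_de_in_sets],
            [n_ctrl_in_sets, n_ctrl_total - n_ctrl_in_sets],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    assert dof == 1
    return float(chi2), float(p)


def binomial_sign_null(
    n_up_sets: int,
    n_down_sets: int,
    n_discordant: int,
    n_up_genes: int,
    n_down_genes: int,
) -> tuple[float, float, float]:
    """Chance model for sign-concordant vs discordant adjacent pairs.

    With ``p = n_up_genes / (n_up_genes + n_down_genes)`` and ``q = 1-p``,
    an adjacent pair of independently deregulated genes is concordant with
    probability ``p^2 + q^2`` and discordant with probability ``2pq``. The
    observed discordant count then predicts the chance number of
    concordant cases: ``expected = n_discordant * (p^2+q^2) / (2pq)``.

    Returns ``(expected_concordant, enrichment_ratio, binomial_p)`` where
    ``binomial_p`` is the exact upper-tail probability of seeing at least
    the observed number of concordant cases among concordant+discordant
    trials. With zero discordant pairs the expectation is undefined and
    the ratio is reported as ``inf`` (``nan`` if there are also no sets).
    """
    for name, v in [
        ("n_up_sets", n_up_sets),
        ("n_down_sets", n_down_sets),
        ("n_discordant", n_discordant),
        ("n_up_genes", n_up_genes),
        ("n_down_genes", n_down_genes),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    n_genes = n_up_genes + n_down_genes
    if n_genes == 0:
        raise ValueError("need at least one deregulated gene")
    p = n_up_genes / n_genes
    q = 1.0 - p
    p_conc = p * p + q * q
    p_disc = 2.0 * p * q
    n_conc = n_up_sets + n_down_sets

    if n_discordant == 0 or p_disc == 0.0:
        expected = math.nan
        ratio = math.inf if n_conc > 0 else math.nan
    else:
        expected = n_discordant * p_conc / p_disc
        ratio = n_conc / expected

    n_trials = n_conc + n_discordant
    if n_trials == 0:
        binom_p = 1.0
    else:
        binom_p = float(stats.binom.sf(n_conc - 1, n_trials, p_conc))
    return expected, ratio, binom_p


# -- permutation null --------------------------------------------------------


def _count_concordant_sets(signs: np.ndarray) -> int:
    """Number of maximal same-sign runs of >=2 in a sign array.

    Chromosome boundaries must be encoded as 0-sign sentinels.
    """
    if signs.size < 2:
        return 0
    link = (signs[:-1] == signs[1:]) & (signs[:-1] != 0)
    if not link.any():
        return 0
    starts = link & ~np.concatenate(([False], link[:-1]))
    return int(starts.sum())


def _sign_layout(catalogue: GeneCatalogue) -> tuple[list[str], np.ndarray]:
    """Catalogue gene ids in rank order plus slot indices in a padded array.

    The padded array has a 0 sentinel between chromosomes so that runs
    never cross a chromosome boundary.
    """
    gene_ids: list[str] = []
    slots: list[int] = []
    pos = 0
    for chrom in catalogue.chromosomes:
        for g in catalogue.genes_on(chrom):
            gene_ids.append(g.gene_id)
            slots.append(pos)
            pos += 1
        pos += 1  # sentinel
    return gene_ids, np.array(slots, dtype=np.int64)


def permutation_null(
    catalogue: GeneCatalogue,
    de_table: DETableLike,
    thresholds: tuple[float, float] = (0.8, 0.05),
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Label-permutation null for the concordant set count.

    Deregulation labels (keeping the observed numbers of up and down
    genes) are reassigned uniformly at random over catalogue positions;
    the total number of same-sign adjacent runs is recomputed each time.
    ``empirical_p = (1 + #{null >= observed}) / (n_perm + 1)``.

    Returns ``(empirical_p, null_mean, null_sd)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for a meaningful empirical p")
    de_set = select_deregulated(de_table, *thresholds)
    sets, _discordant, _nex = find_coregulated_sets(catalogue, de_set)
    observed = len(sets)

    gene_ids, slots = _sign_layout(catalogue)
    n_genes = len(gene_ids)
    padded_len = int(slots[-1]) + 1 if n_genes else 0

    labels = np.zeros(n_genes, dtype=np.int8)
    labels[: de_set.n_up] = 1
    labels[de_set.n_up : de_set.n_up + de_set.n_down] = -1

    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=np.int64)
    padded = np.zeros(padded_len + 1, dtype=np.int8)
    for i in range(n_perm):
        padded[:] = 0
        padded[slots] = rng.permutation(labels)
        null_counts[i] = _count_concordant_sets(padded)

    empirical_p = (1 + int((null_counts >= observed).sum())) / (n_perm + 1)
    return empirical_p, float(null_counts.mean()), float(null_counts.std(ddof=1))


# -- composition -------------------------------------------------------------


def _genes_in_sets(sets: Sequence[CoregulatedSet]) -> set[str]:
    out: set[str] = set()
    for s in sets:
        out.update(s.members)
    return out


def run_adjacency_analysis(
    catalogue: GeneCatalogue,
    de_table: DETableLike,
    min_abs_log2fc: float = 0.8,
    max_p: float = 0.05,
    family_map: Optional[Mapping[str, str]] = None,
    control_size: Optional[int] = None,
    n_perm: int = 0,
    seed: int = 0,
) -> AdjacencyReport:
    """Run the full adjacency analysis and bundle every statistic.

    ``control_size`` defaults to the size of the deregulated set (the
    study design pairs cohorts of comparable size). Set ``n_perm >= 99``
    to add the permutation null to the report.
    """
    df = as_de_frame(de_table)
    de_set = select_deregulated(df, min_abs_log2fc, max_p)
    family_map = dict(family_map or {})

    sets, discordant, n_excluded = find_coregulated_sets(
        catalogue, de_set, family_map
    )
    n_up_sets = sum(1 for s in sets if s.direction > 0)
    n_down_sets = len(sets) - n_up_sets

    if sets:
        mean_span, median_span = span_statistics(sets)
    else:
        mean_span = median_span = math.nan
    opp_frac = strand_composition(sets)

    de_in_sets = _genes_in_sets(sets)

    # Control cohort: smallest-|fc| genes, sign-balanced, deregulated genes
    # excluded; their adjacency is scored identically (sign = sign of fc).
    n_ctrl = control_size if control_size is not None else len(de_set)
    chi2_stat = chi2_p = math.nan
    n_ctrl_in_sets = 0
    ctrl_ids: list[str] = []
    if n_ctrl > 0 and len(de_set) > 0:
        from .de import build_control_set

        ctrl_ids = build_control_set(df, n_ctrl, excluded_ids=de_set.signs)
        fc = dict(zip(df["gene_id"], df["log2fc"]))
        ctrl_signs = {g: (1 if fc[g] > 0 else -1) for g in ctrl_ids}
        ctrl_set = SignedDESet(
            signs=ctrl_signs, min_abs_log2fc=0.0, max_p=1.0
        )
        ctrl_sets, _, _ = find_coregulated_sets(catalogue, ctrl_set, family_map)
        n_ctrl_in_sets = len(_genes_in_sets(ctrl_sets))
        try:
            chi2_stat, chi2_p = adjacency_chi2(
                len(de_in_sets), len(de_set), n_ctrl_in_sets, len(ctrl_ids)
            )
        except ValueError:
            pass  # zero margin (e.g. no set members anywhere): undefined

    if len(de_set) > 0 and (de_set.n_up + de_set.n_down) > 0:
        expected, ratio, binom_p = binomial_sign_null(
            n_up_sets, n_down_sets, len(discordant), de_set.n_up, de_set.n_down
        )
    else:
        expected = ratio = binom_p = math.nan

    report = AdjacencyReport(
        n_up_sets=n_up_sets,
        n_down_sets=n_down_sets,
        n_discordant_pairs=len(discordant),
        n_duplicate_excluded=n_excluded,
        opposite_strand_fraction=opp_frac,
        mean_span_bp=mean_span,
        median_span_bp=median_span,
        n_de_genes=len(de_set),
        n_de_genes_in_sets=len(de_in_sets),
        n_control_genes=len(ctrl_ids),
        n_control_genes_in_sets=n_ctrl_in_sets,
        chi2_stat=chi2_stat,
        chi2_p=chi2_p,
        expected_concordant=expected,
        enrichment_ratio=ratio,
        binomial_p=binom_p,
    )
    if n_perm >= 99:
        emp_p, null_mean, null_sd = permutation_null(
            catalogue, df, (min_abs_log2fc, max_p), n_perm=n_perm, seed=seed
        )
        report.permutation_p = emp_p
        report.permutation_null_mean = null_mean
        report.permutation_null_sd = null_sd
    return report
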