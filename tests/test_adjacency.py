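"""Adjacent co-regulation detection and its three null models."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from adjacoreg import (
    adjacency_chi2,
    binomial_sign_null,
    exclude_duplicates,
    find_coregulated_sets,
    permutation_null,
    run_adjacency_analysis,
    span_statistics,
    strand_composition,
)
from adjacoreg.adjacency import CoregulatedSet

from conftest import de_frame, linear_catalogue, make_catalogue, signed_set


# -- independent oracle: exhaustive enumeration over contiguous windows ------


def enumerate_sets_bruteforce(catalogue, de_set, family_map=None):
    """Maximal same-sign windows by checking every contiguous window.

    Independent of the scan implementation: examines all O(n^2) windows
    of each chromosome and keeps those whose genes are all deregulated
    with one sign, whose internal links survive duplicate exclusion, and
    which cannot be extended either way.
    """
    family_map = family_map or {}

    def linked(a, b):
        sa = de_set.signs.get(a.gene_id, 0)
        sb = de_set.signs.get(b.gene_id, 0)
        if sa == 0 or sa != sb:
            return False
        fa, fb = family_map.get(a.gene_id), family_map.get(b.gene_id)
        return not (fa is not None and fa == fb)

    found = []
    for chrom in catalogue.chromosomes:
        genes = catalogue.genes_on(chrom)
        n = len(genes)
        for i in range(n):
            for j in range(i + 1, n):
                window = genes[i : j + 1]
                if not all(linked(a, b) for a, b in zip(window, window[1:])):
                    continue
                if i > 0 and linked(genes[i - 1], genes[i]):
                    continue
                if j + 1 < n and linked(genes[j], genes[j + 1]):
                    continue
                found.append(tuple(g.gene_id for g in window))
    return sorted(found)


def enumerate_discordant_bruteforce(catalogue, de_set):
    out = []
    for chrom in catalogue.chromosomes:
        genes = catalogue.genes_on(chrom)
        for a, b in zip(genes, genes[1:]):
            sa = de_set.signs.get(a.gene_id, 0)
            sb = de_set.signs.get(b.gene_id, 0)
            if sa != 0 and sb != 0 and sa != sb:
                out.append((a.gene_id, b.gene_id))
    return sorted(out)


class TestFindCoregulatedSets:
    def test_no_de_genes(self):
        cat = linear_catalogue(5)
        sets, disc, nex = find_coregulated_sets(cat, signed_set({}))
        assert (sets, disc, nex) == ([], [], 0)

    def test_hand_enumeration_six_genes(self):
        # signs (+, +, none, -, -, +): one up set, one down set, one
        # discordant pair sharing g5 with the down set
        cat = linear_catalogue(6)
        de = signed_set({"g1": 1, "g2": 1, "g4": -1, "g5": -1, "g6": 1})
        sets, disc, _ = find_coregulated_sets(cat, de)
        assert [(s.members, s.direction) for s in sets] == [
            (("g1", "g2"), 1),
            (("g4", "g5"), -1),
        ]
        assert [(d.gene_a, d.gene_b) for d in disc] == [("g5", "g6")]

    def test_three_gene_run_is_one_set_not_two_pairs(self):
        cat = linear_catalogue(3)
        sets, _, _ = find_coregulated_sets(cat, signed_set({"g1": 1, "g2": 1, "g3": 1}))
        assert len(sets) == 1 and sets[0].members == ("g1", "g2", "g3")

    def test_de_gene_missing_from_catalogue_listed(self):
        with pytest.raises(KeyError, match="ghost"):
            find_coregulated_sets(linear_catalogue(3), signed_set({"ghost": 1}))

    def test_duplicate_family_breaks_run(self):
        cat = make_catalogue(
            {"chr1": [("a", 1, 100, "+", "f1"), ("b", 200, 300, "+", "f1"),
                      ("c", 400, 500, "+")]}
        )
        de = signed_set({"a": 1, "b": 1, "c": 1})
        sets, _, nex = find_coregulated_sets(cat, de, cat.family_map())
        assert nex == 1
        assert [s.members for s in sets] == [("b", "c")]

    def test_runs_do_not_cross_chromosomes(self):
        cat = make_catalogue(
            {"chr1": [("a", 1, 100, "+")], "chr2": [("b", 1, 100, "+")]}
        )
        sets, _, _ = find_coregulated_sets(cat, signed_set({"a": 1, "b": 1}))
        assert sets == []

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_exhaustive_enumeration_on_small_catalogues(self, trial):
        """Oracle equivalence on random catalogues of <= 12 genes."""
        rng = np.random.default_rng(500 + trial)
        n = int(rng.integers(2, 13))
        n_chr1 = int(rng.integers(1, n + 1))
        layout = {}
        pos = 1
        genes = []
        for i in range(n):
            chrom = "chr1" if i < n_chr1 else "chr2"
            strand = "+" if rng.random() < 0.5 else "-"
            fam = f"f{int(rng.integers(0, 3))}" if rng.random() < 0.3 else None
            genes.append((chrom, (f"g{i}", pos, pos + 50, strand, fam)))
            pos += 100
        for chrom, g in genes:
            layout.setdefault(chrom, []).append(g)
        cat = make_catalogue(layout)
        signs = {
            f"g{i}": int(rng.choice([-1, 1]))
            for i in range(n)
            if rng.random() < 0.6
        }
        de = signed_set(signs)
        fam_map = cat.family_map()
        sets, disc, _ = find_coregulated_sets(cat, de, fam_map)
        assert sorted(s.members for s in sets) == enumerate_sets_bruteforce(
            cat, de, fam_map
        )
        assert sorted((d.gene_a, d.gene_b) for d in disc) == (
            enumerate_discordant_bruteforce(cat, de)
        )

    @pytest.mark.parametrize("trial", range(10))
    def test_partition_and_pair_conservation(self, trial):
        rng = np.random.default_rng(900 + trial)
        cat = linear_catalogue(30)
        signs = {
            f"g{i}": int(rng.choice([-1, 1]))
            for i in range(1, 31)
            if rng.random() < 0.5
        }
        sets, _, _ = find_coregulated_sets(cat, signed_set(signs))
        seen = set()
        n_pairs_inside = 0
        for s in sets:
            assert not (set(s.members) & seen), "sets overlap"
            seen.update(s.members)
            n_pairs_inside += len(s) - 1
        # every same-sign consecutive DE pair lies inside exactly one set
        genes = [g.gene_id for g in cat]
        concordant_pairs = sum(
            1
            for a, b in zip(genes, genes[1:])
            if signs.get(a, 0) != 0 and signs.get(a, 0) == signs.get(b, 0)
        )
        assert n_pairs_inside == concordant_pairs


class TestExcludeDuplicates:
    def test_empty_family_map_keeps_all(self):
        pairs = [("a", "b"), ("c", "d")]
        assert exclude_duplicates(pairs, {}) == (pairs, 0)

    def test_same_family_pair_removed_and_counted(self):
        pairs = [("a", "b"), ("c", "d"), ("e", "f")]
        fam = {"c": "fam1", "d": "fam1", "e": "fam2"}
        retained, n = exclude_duplicates(pairs, fam)
        assert retained == [("a", "b"), ("e", "f")] and n == 1


class TestDescriptiveStats:
    def _set(self, strands, span=1000):
        return CoregulatedSet(
            chromosome="chr1",
            members=tuple(f"m{i}" for i in range(len(strands))),
            direction=1,
            strands=tuple(strands),
            span_bp=span,
        )

    def test_all_same_strand_fraction_zero(self):
        assert strand_composition([self._set("++"), self._set("--")]) == 0.0

    def test_counting_mixed_strands(self):
        # sets (+,-,+) and (+,+): 3 within-set pairs... use explicit 4-pair case
        sets = [self._set("+-+"), self._set("++-")]
        # pairs: (+,-), (-,+), (+,+), (+,-) -> 3 of 4 opposite
        assert strand_composition(sets) == 0.75

    def test_empty_input_is_nan_not_zero(self):
        assert math.isnan(strand_composition([]))

    def test_span_mean_median(self):
        sets = [self._set("++", span=4000), self._set("++", span=12000)]
        assert span_statistics(sets) == (8000.0, 8000.0)
        with pytest.raises(ValueError):
            span_statistics([])

    def test_span_from_coordinates(self):
        cat = make_catalogue({"chr1": [("a", 100, 500, "+"), ("b", 700, 1099, "+")]})
        sets, _, _ = find_coregulated_sets(cat, signed_set({"a": 1, "b": 1}))
        assert sets[0].span_bp == 1000


class TestAdjacencyChi2:
    def test_null_table(self):
        chi2, p = adjacency_chi2(5, 50, 5, 50)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_hand_coded_pearson_formula(self):
        # oracle: chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        a, b = 102, 1073 - 102
        c, d = 4, 1078 - 4
        n = a + b + c + d
        chi2_oracle = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        p_oracle = sps.chi2.sf(chi2_oracle, 1)
        chi2, p = adjacency_chi2(102, 1073, 4, 1078)
        assert chi2 == pytest.approx(chi2_oracle, rel=1e-12)
        assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            adjacency_chi2(0, 10, 0, 10)

    def test_members_cannot_exceed_totals(self):
        with pytest.raises(ValueError):
            adjacency_chi2(11, 10, 0, 10)


class TestBinomialSignNull:
    def test_study_counts_give_threefold_enrichment(self):
        expected, ratio, p = binomial_sign_null(27, 24, 14, 559, 514)
        # oracle: direct arithmetic with p = 559/1073
        pr = 559 / 1073
        pc = pr * pr + (1 - pr) ** 2
        assert expected == pytest.approx(14 * pc / (1 - pc), rel=1e-12)
        assert expected == pytest.approx(14.05, abs=0.005)
        assert ratio == pytest.approx(3.63, abs=0.005)
        assert ratio > 3
        assert p == pytest.approx(sps.binom.sf(50, 65, pc), rel=1e-9)

    def test_symmetric_null_ratio_is_one(self):
        expected, ratio, _ = binomial_sign_null(5, 5, 10, 100, 100)
        assert expected == pytest.approx(10.0) and ratio == pytest.approx(1.0)

    def test_zero_discordant_flagged_unbounded(self):
        expected, ratio, p = binomial_sign_null(3, 2, 0, 50, 50)
        assert math.isnan(expected) and math.isinf(ratio)
        assert 0 <= p <= 1

    def test_probabilities_in_range(self):
        for args in [(1, 0, 1, 10, 1), (0, 0, 0, 5, 5), (10, 10, 2, 30, 70)]:
            _, ratio, p = binomial_sign_null(*args)
            assert 0 <= p <= 1
            assert ratio >= 0 or math.isnan(ratio)


class TestPermutationNull:
    def _clustered(self):
        # two strong adjacent blocks among 400 genes: label shuffles
        # almost never reproduce two concordant runs by chance
        cat = linear_catalogue(400)
        up, down = {1, 2, 3}, {201, 202, 203}
        rows = []
        for i in range(1, 401):
            if i in up:
                rows.append((f"g{i}", 3.0, 1e-6))
            elif i in down:
                rows.append((f"g{i}", -3.0, 1e-6))
            else:
                rows.append((f"g{i}", 0.0, 0.9))
        return cat, de_frame(rows)

    def test_saturated_significance(self):
        cat, de = self._clustered()
        p, _, _ = permutation_null(cat, de, n_perm=199, seed=1)
        assert p == pytest.approx(1 / 200)

    def test_same_seed_bit_identical(self):
        cat, de = self._clustered()
        assert permutation_null(cat, de, n_perm=99, seed=42) == permutation_null(
            cat, de, n_perm=99, seed=42
        )

    def test_too_few_permutations_rejected(self):
        cat, de = self._clustered()
        with pytest.raises(ValueError):
            permutation_null(cat, de, n_perm=50, seed=0)


class TestRunAdjacencyAnalysis:
    def test_empty_de_set_zeroed_with_flags(self):
        cat = linear_catalogue(10)
        de = de_frame([(f"g{i}", 0.0, 0.9) for i in range(1, 11)])
        report = run_adjacency_analysis(cat, de)
        assert report.n_sets == 0 and report.n_discordant_pairs == 0
        assert math.isnan(report.chi2_p) and math.isnan(report.binomial_p)
        assert math.isnan(report.opposite_strand_fraction)

    def test_report_counts_consistent(self):
        cat = linear_catalogue(50)
        rows = []
        for i in range(1, 51):
            if i in (3, 4, 20, 21, 22):
                rows.append((f"g{i}", 2.5, 1e-5))
            elif i in (40, 41):
                rows.append((f"g{i}", -2.5, 1e-5))
            else:
                rows.append((f"g{i}", float(np.sin(i)) * 0.2, 0.8))
        report = run_adjacency_analysis(cat, de_frame(rows))
        assert (report.n_up_sets, report.n_down_sets) == (2, 1)
        assert report.n_de_genes_in_sets == 7
        assert report.n_sets == report.n_up_sets + report.n_down_sets
        assert 0 <= report.chi2_p <= 1 and report.chi2_stat >= 0
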