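import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cismodules.analyses import (
    aggregate_group_attributes,
    extra_gene_search,
    hypergeometric_enrichment,
    partition_by_orientation,
    proximal_majority_flag,
    quartile_fractions,
)
from cismodules.discovery import build_module
from cismodules.model import (
    ModuleAttributes,
    MotifModel,
    MotifOccurrence,
    UpstreamRegion,
)
from cismodules.scan import scan_region
from cismodules.stats import sig_value, total_scan_windows


def occ_at_distance(distance, gene="g", motif="PAC", length=800):
    end = length - distance
    return MotifOccurrence(gene, motif, end - 6, end, "+", 0, distance)


class TestQuartileFractions:
    def test_hand_computed_bins(self):
        occs = [occ_at_distance(d) for d in (50, 150, 250, 650)]
        assert quartile_fractions(occs, 800) == pytest.approx(
            [0.5, 0.25, 0.0, 0.25]
        )

    def test_all_proximal(self):
        occs = [occ_at_distance(0) for _ in range(3)]
        assert quartile_fractions(occs, 800) == [1.0, 0.0, 0.0, 0.0]

    def test_boundary_is_half_open(self):
        # distance exactly 200 belongs to the second bin
        assert quartile_fractions([occ_at_distance(200)], 800) == [
            0.0, 1.0, 0.0, 0.0,
        ]

    @given(st.lists(st.integers(0, 794), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_fractions_sum_to_one(self, distances):
        occs = [occ_at_distance(d) for d in distances]
        assert sum(quartile_fractions(occs, 800)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_empty_error(self):
        with pytest.raises(ValueError):
            quartile_fractions([], 800)

    def test_indivisible_length_error(self):
        with pytest.raises(ValueError):
            quartile_fractions([occ_at_distance(0)], 801)

    def test_missing_distance_error(self):
        occ = MotifOccurrence("g", "PAC", 0, 6, "+", 0, None)
        with pytest.raises(ValueError, match="distance_to_atg"):
            quartile_fractions([occ], 800)


class TestProximalMajorityFlag:
    def test_pac_row(self):
        assert proximal_majority_flag([0.76, 0.11, 0.07, 0.06]) is True

    def test_tie_is_false(self):
        assert proximal_majority_flag([0.25, 0.25, 0.25, 0.25]) is False

    def test_distal_majority_false(self):
        assert proximal_majority_flag([0.1, 0.6, 0.2, 0.1]) is False


def attrs_with(order="RRPE-PAC", **overrides):
    base = dict(
        order=order, sig_first=250.0, sig_second=250.0, abc=0.0,
        position_score=0.5, coverage=0.5, orientation_f_same=0.5,
        n_occurrences=10, median_gap=12.0, median_upstream_position=-118.0,
        module_score=0.5,
    )
    base.update(overrides)
    return ModuleAttributes(**base)


class TestAggregateGroupAttributes:
    def test_mean_module_score(self):
        members = [
            ("sp1", attrs_with(module_score=0.5)),
            ("sp2", attrs_with(module_score=0.6)),
        ]
        grouping = {"sp1": "Scer-like", "sp2": "Scer-like"}
        (summary,) = aggregate_group_attributes(members, grouping)
        assert summary.means["module_score"] == pytest.approx(0.55)
        assert summary.n_members == 2

    def test_abc_display_shift(self):
        (summary,) = aggregate_group_attributes(
            [("sp1", attrs_with(abc=-0.26))], {"sp1": "Ncra-like"}
        )
        assert summary.abc_display == pytest.approx(0.74)
        assert summary.means["abc"] == pytest.approx(-0.26)

    def test_upstream_display_absolute(self):
        (summary,) = aggregate_group_attributes(
            [("sp1", attrs_with(median_upstream_position=-118.0))],
            {"sp1": "Scer-like"},
        )
        assert summary.upstream_display == pytest.approx(118.0)

    def test_groups_split_by_order(self):
        members = [
            ("sp1", attrs_with(order="RRPE-PAC")),
            ("sp1", attrs_with(order="PAC-RRPE")),
        ]
        summaries = aggregate_group_attributes(members, {"sp1": "Scer-like"})
        assert [s.order for s in summaries] == ["PAC-RRPE", "RRPE-PAC"]

    def test_unknown_label_error(self):
        with pytest.raises(ValueError, match="unknown group label"):
            aggregate_group_attributes([("sp1", attrs_with())], {})


def module(gene, order):
    first_name, second_name = order.split("-")
    first = MotifOccurrence(gene, first_name, 10, 16, "+", 0)
    second = MotifOccurrence(gene, second_name, 30, 36, "+", 0)
    return build_module(first, second, 800)


class TestPartitionByOrientation:
    def test_exclusive_assignment(self):
        modules = [
            module("g1", "RRPE-PAC"),
            module("g2", "RRPE-PAC"), module("g2", "PAC-RRPE"),
            module("g3", "PAC-RRPE"),
        ]
        genes = ["g1", "g2", "g3", "g4"]
        s1, s2, excluded = partition_by_orientation(
            genes, modules, "RRPE-PAC", "PAC-RRPE"
        )
        assert s1 == {"g1"}
        assert s2 == {"g3"}
        assert excluded == {"g2", "g4"}

    def test_subsets_disjoint_and_covered(self):
        rng = np.random.default_rng(1)
        modules = []
        genes = [f"g{i}" for i in range(30)]
        for gene in genes:
            for _ in range(int(rng.integers(0, 3))):
                modules.append(module(
                    gene, ["RRPE-PAC", "PAC-RRPE"][int(rng.integers(2))]
                ))
        s1, s2, excluded = partition_by_orientation(
            genes, modules, "RRPE-PAC", "PAC-RRPE"
        )
        assert not s1 & s2
        assert s1 | s2 | excluded == set(genes)
        with_module = {m.gene_id for m in modules}
        assert (s1 | s2) <= with_module

    def test_identical_orders_error(self):
        with pytest.raises(ValueError):
            partition_by_orientation([], [], "A-B", "A-B")


def enumeration_tail(big_n, big_k, small_n, k):
    """Oracle: exhaustive enumeration of subsets with >= k marked genes."""
    favorable = sum(
        1
        for subset in itertools.combinations(range(big_n), small_n)
        if sum(1 for gene in subset if gene < big_k) >= k
    )
    return favorable / math.comb(big_n, small_n)


class TestHypergeometricEnrichment:
    def test_exact_combinatorial_example(self):
        universe = [f"g{i}" for i in range(100)]
        annotations = {f"g{i}": {"T"} for i in range(10)}
        subset = [f"g{i}" for i in range(5)]
        (result,) = hypergeometric_enrichment(subset, universe, annotations)
        expected = (
            math.comb(10, 5) * math.comb(90, 0) / math.comb(100, 5)
        )
        assert result.p_value == pytest.approx(expected, rel=1e-9)
        assert result.enriched

    def test_absent_term_not_enriched(self):
        universe = [f"g{i}" for i in range(20)]
        annotations = {"g19": {"T"}}
        results = hypergeometric_enrichment(
            ["g0", "g1"], universe, annotations
        )
        (term,) = results
        assert term.p_value == pytest.approx(1.0)
        assert not term.enriched

    def test_subset_equals_universe(self):
        universe = [f"g{i}" for i in range(10)]
        annotations = {"g0": {"T"}, "g1": {"T"}}
        (result,) = hypergeometric_enrichment(universe, universe, annotations)
        assert result.p_value == pytest.approx(1.0)

    def test_stray_subset_gene_error(self):
        with pytest.raises(ValueError, match="absent"):
            hypergeometric_enrichment(["gX"], ["g1"], {})

    @pytest.mark.parametrize("seed", range(6))
    def test_enumeration_oracle_small_universe(self, seed):
        rng = np.random.default_rng(seed)
        big_n = int(rng.integers(4, 13))
        big_k = int(rng.integers(1, big_n + 1))
        small_n = int(rng.integers(1, big_n + 1))
        universe = [f"g{i}" for i in range(big_n)]
        annotations = {f"g{i}": {"T"} for i in range(big_k)}
        subset = [
            f"g{i}"
            for i in rng.choice(big_n, small_n, replace=False)
        ]
        k = sum(1 for g in subset if g in annotations)
        (result,) = hypergeometric_enrichment(subset, universe, annotations)
        expected = enumeration_tail(big_n, big_k, small_n, k)
        assert result.p_value == pytest.approx(expected, rel=1e-9)

    def test_sorted_by_p(self):
        universe = [f"g{i}" for i in range(30)]
        annotations = {
            "g0": {"rare", "common"}, "g1": {"rare", "common"},
            **{f"g{i}": {"common"} for i in range(2, 30)},
        }
        results = hypergeometric_enrichment(["g0", "g1"], universe, annotations)
        assert [r.term for r in results] == ["rare", "common"]


def region_with_sites(gene, n_sites, length=200, motif="GATGAG"):
    seq = ["T"] * length
    for i in range(n_sites):
        start = 10 + i * 20
        seq[start:start + 6] = motif
    return UpstreamRegion(gene, "".join(seq))


class TestExtraGeneSearch:
    PAC = MotifModel("PAC", "GATGAG")

    def make_pool(self):
        gene_set = [region_with_sites(f"s{i}", 1) for i in range(5)]
        candidates = [
            region_with_sites("c0", 3),
            region_with_sites("c1", 1),
            region_with_sites("c2", 0),
            region_with_sites("c3", 2),
        ]
        return gene_set, candidates

    def test_zero_occurrence_never_added(self):
        gene_set, candidates = self.make_pool()
        results = extra_gene_search(
            gene_set, candidates, self.PAC, p0=1e-4, max_added=10
        )
        assert "c2" not in {r.gene_id for r in results}

    def test_max_added_zero(self):
        gene_set, candidates = self.make_pool()
        assert extra_gene_search(
            gene_set, candidates, self.PAC, p0=1e-4, max_added=0
        ) == []

    def test_empty_pool(self):
        gene_set, _ = self.make_pool()
        assert extra_gene_search(gene_set, [], self.PAC, p0=1e-4) == []

    def test_sig_strictly_increasing(self):
        gene_set, candidates = self.make_pool()
        results = extra_gene_search(
            gene_set, candidates, self.PAC, p0=1e-4, max_added=10
        )
        assert results
        sigs = [r.sig_after for r in results]
        assert all(b > a for a, b in zip(sigs, sigs[1:])) or len(sigs) == 1
        # strictly above the starting Sig
        k0 = sum(len(scan_region(r, self.PAC)) for r in gene_set)
        n0 = total_scan_windows(gene_set, 6)
        assert sigs[0] > sig_value(k0, n0, 1e-4)

    def test_greedy_matches_brute_force(self):
        gene_set, candidates = self.make_pool()
        p0 = 1e-4
        results = extra_gene_search(
            gene_set, candidates, self.PAC, p0=p0, max_added=10
        )

        # independent oracle: recompute every step's best single addition
        k = sum(len(scan_region(r, self.PAC)) for r in gene_set)
        n = total_scan_windows(gene_set, 6)
        pool = {
            r.gene_id: (
                len(scan_region(r, self.PAC)),
                total_scan_windows([r], 6),
            )
            for r in candidates
            if scan_region(r, self.PAC)
        }
        current = sig_value(k, n, p0)
        expected_order = []
        while pool:
            best = max(
                sorted(pool),
                key=lambda g: sig_value(k + pool[g][0], n + pool[g][1], p0),
            )
            best_sig = sig_value(k + pool[best][0], n + pool[best][1], p0)
            if best_sig <= current:
                break
            expected_order.append(best)
            k += pool[best][0]
            n += pool[best][1]
            current = best_sig
            del pool[best]
        assert [r.gene_id for r in results] == expected_order

    def test_overlapping_ids_error(self):
        gene_set, _ = self.make_pool()
        with pytest.raises(ValueError, match="disjoint"):
            extra_gene_search(gene_set, gene_set, self.PAC, p0=1e-4)

    def test_partner_modules_reported(self):
        rrpe = MotifModel("RRPE", "AAAAATTTT")
        seq = ["C"] * 200
        seq[100:109] = "AAAAATTTT"
        seq[120:126] = "GATGAG"
        candidate = UpstreamRegion("c0", "".join(seq))
        gene_set = [region_with_sites(f"s{i}", 1) for i in range(3)]
        results = extra_gene_search(
            gene_set, [candidate], self.PAC, p0=1e-4,
            partner=rrpe, max_gap=200,
        )
        (result,) = results
        assert result.modules
        assert result.modules[0].order_label == "RRPE-PAC"
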