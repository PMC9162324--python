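"""Tests for shared/private classification, folding, binning and filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from balsel.sites import (
    SiteRecord,
    apply_min_count_filter,
    bgc_filter,
    bin_by_frequency,
    classify_shared_private,
    expected_random_overlap,
    fold_maf,
    group_by_gene_set,
    split_by_recombination,
)


def make_site(f1, f2, func_class="nonsynonymous", gene="g1", ref="A", alt="T",
              pos=1, recomb=None, gene_sets=frozenset()):
    return SiteRecord(
        chrom="1", pos=pos, ref_allele=ref, alt_allele=alt,
        freq_by_pop={"p1": f1, "p2": f2}, func_class=func_class, gene_id=gene,
        recomb_rate=recomb, gene_sets=gene_sets,
    )


class TestFoldMaf:
    @pytest.mark.parametrize("f, expected", [(0.5, 0.5), (0.9, 0.1), (0.0, 0.0)])
    def test_examples(self, f, expected):
        assert fold_maf(f) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            fold_maf(1.2)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_idempotent_and_symmetric(self, f):
        assert fold_maf(fold_maf(f)) == fold_maf(f)
        assert fold_maf(f) == pytest.approx(fold_maf(1.0 - f), abs=1e-12)
        assert 0.0 <= fold_maf(f) <= 0.5


class TestClassification:
    def test_private_focal(self):
        [cs] = classify_shared_private([make_site(0.3, 0.0)], "p1", "p2", "p1")
        assert cs.category == "private_pop1"
        assert cs.focal_maf == pytest.approx(0.3)

    def test_shared_with_folding(self):
        [cs] = classify_shared_private([make_site(0.6, 0.2)], "p1", "p2", "p1")
        assert cs.category == "shared"
        assert cs.focal_maf == pytest.approx(0.4)

    def test_fixed_difference_and_monomorphic(self):
        cats = [
            cs.category
            for cs in classify_shared_private(
                [make_site(1.0, 0.0), make_site(0.0, 0.0), make_site(1.0, 1.0)],
                "p1", "p2", "p1",
            )
        ]
        assert cats == ["fixed_difference", "monomorphic", "monomorphic"]

    def test_every_site_gets_exactly_one_category(self, rng):
        grid = np.round(rng.integers(0, 11, size=(300, 2)) / 10, 1)
        sites = [make_site(f1, f2, pos=i + 1) for i, (f1, f2) in enumerate(grid)]
        classified = classify_shared_private(sites, "p1", "p2", "p1")
        assert len(classified) == len(sites)
        for cs in classified:
            f1, f2 = cs.site.freq_by_pop["p1"], cs.site.freq_by_pop["p2"]
            seg1, seg2 = 0 < f1 < 1, 0 < f2 < 1
            expected = (
                "shared" if seg1 and seg2
                else "private_pop1" if seg1
                else "private_pop2" if seg2
                else "monomorphic" if f1 == f2
                else "fixed_difference"
            )
            assert cs.category == expected

    def test_missing_frequency_rejected(self):
        bad = SiteRecord("1", 5, "A", "T", {"p1": 0.4}, "synonymous", "g")
        out = classify_shared_private([bad, make_site(0.2, 0.2)], "p1", "p2", "p1")
        assert len(out) == 1

    def test_focal_swap_changes_only_private_side_and_folding(self, rng):
        grid = rng.uniform(0, 1, size=(100, 2))
        sites = [make_site(f1, f2, pos=i + 1) for i, (f1, f2) in enumerate(grid)]
        c1 = classify_shared_private(sites, "p1", "p2", "p1")
        c2 = classify_shared_private(sites, "p1", "p2", "p2")
        for a, b in zip(c1, c2):
            assert a.category == b.category
            assert a.focal_maf == pytest.approx(fold_maf(a.site.freq_by_pop["p1"]))
            assert b.focal_maf == pytest.approx(fold_maf(b.site.freq_by_pop["p2"]))


class TestBinning:
    def test_single_low_frequency_shared_site(self):
        [cs] = classify_shared_private([make_site(0.05, 0.3)], "p1", "p2", "p1")
        binned = bin_by_frequency([cs])
        assert binned.per_bin[0].s_n == 1
        assert binned.total.total == 1
        assert binned.combined_above.total == 0

    def test_pooled_bin_equals_sum_of_upper_bins(self):
        sites = [make_site(f, 0.3, pos=i + 1) for i, f in enumerate([0.15, 0.25, 0.45])]
        classified = classify_shared_private(sites, "p1", "p2", "p1")
        binned = bin_by_frequency(classified)
        upper = sum(t.total for t in binned.per_bin[1:])
        assert binned.combined_above.total == upper == 3

    def test_maf_exactly_point_one_is_in_lowest_bin(self):
        # half-open bins (lo, hi]: 0.1 belongs to the first bin, not ">0.1"
        [cs] = classify_shared_private([make_site(0.1, 0.3)], "p1", "p2", "p1")
        binned = bin_by_frequency([cs])
        assert binned.per_bin[0].s_n == 1
        assert binned.combined_above.total == 0

    def test_maf_half_in_top_bin(self):
        [cs] = classify_shared_private([make_site(0.5, 0.3)], "p1", "p2", "p1")
        binned = bin_by_frequency([cs])
        assert binned.per_bin[4].s_n == 1

    def test_conservation_over_random_sites(self, rng):
        sites = [
            make_site(
                rng.uniform(), rng.uniform(),
                func_class=rng.choice(["nonsynonymous", "synonymous", "other"]),
                pos=i + 1,
            )
            for i in range(10_000)
        ]
        classified = classify_shared_private(sites, "p1", "p2", "p1")
        binned = bin_by_frequency(classified)
        countable = sum(
            1
            for cs in classified
            if cs.category in ("shared", "private_pop1")
            and cs.site.func_class in ("nonsynonymous", "synonymous")
        )
        assert binned.total.total == countable
        for attr in ("s_n", "s_s", "r_n", "r_s"):
            assert getattr(binned.combined_above, attr) == sum(
                getattr(t, attr) for t in binned.per_bin[1:]
            )

    def test_other_class_excluded(self):
        [cs] = classify_shared_private(
            [make_site(0.3, 0.3, func_class="other")], "p1", "p2", "p1"
        )
        assert bin_by_frequency([cs]).total.total == 0

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            bin_by_frequency([], bin_width=0.13)


class TestMinCountFilter:
    def test_thresholds(self):
        sites = []
        pos = 1
        for fc, n in (("nonsynonymous", 25), ("synonymous", 25)):
            for _ in range(n):
                sites.append(make_site(0.15, 0.3, func_class=fc, pos=pos)); pos += 1
                sites.append(make_site(0.15, 0.0, func_class=fc, pos=pos)); pos += 1
        classified = classify_shared_private(sites, "p1", "p2", "p1")
        binned = bin_by_frequency(classified)
        passed = apply_min_count_filter(binned, 20)
        assert passed.flagged[1] is False  # (25,25,25,25) at threshold 20
        assert passed.flagged[0] is True  # empty bin flagged, not deleted
        assert len(passed.per_bin) == 5
        nothing = apply_min_count_filter(binned, 0)
        assert not any(nothing.flagged)

    def test_any_cell_below_threshold_flags(self):
        sites = [make_site(0.15, 0.3, "nonsynonymous", pos=i + 1) for i in range(19)]
        sites += [make_site(0.15, 0.3, "synonymous", pos=100 + i) for i in range(100)]
        sites += [make_site(0.15, 0.0, "nonsynonymous", pos=300 + i) for i in range(100)]
        sites += [make_site(0.15, 0.0, "synonymous", pos=500 + i) for i in range(100)]
        binned = bin_by_frequency(classify_shared_private(sites, "p1", "p2", "p1"))
        assert apply_min_count_filter(binned, 20).flagged[1] is True


class TestBgcFilter:
    @pytest.mark.parametrize(
        "ref, alt, kept",
        [("A", "T", True), ("A", "G", False), ("C", "G", True), ("G", "C", True),
         ("T", "A", True), ("C", "T", False)],
    )
    def test_pairs(self, ref, alt, kept):
        out = bgc_filter([make_site(0.2, 0.2, ref=ref, alt=alt)])
        assert (len(out) == 1) is kept

    def test_idempotent(self, rng):
        alleles = ["A", "C", "G", "T"]
        sites = []
        for i in range(200):
            ref, alt = rng.choice(alleles, size=2, replace=False)
            sites.append(make_site(0.2, 0.2, ref=ref, alt=alt, pos=i + 1))
        once = bgc_filter(sites)
        assert bgc_filter(once) == once


class TestRecombinationSplit:
    def test_four_genes(self):
        sites = [
            make_site(0.2, 0.2, gene=g, recomb=r, pos=i + 1)
            for i, (g, r) in enumerate([("a", 1), ("b", 2), ("c", 3), ("d", 4)])
        ]
        low, high = split_by_recombination(sites)
        assert {s.gene_id for s in low} == {"a", "b"}
        assert {s.gene_id for s in high} == {"c", "d"}

    def test_ties_go_low(self):
        sites = [make_site(0.2, 0.2, gene=g, recomb=1.0, pos=i + 1)
                 for i, g in enumerate("abcd")]
        low, high = split_by_recombination(sites)
        assert len(low) == 4 and len(high) == 0

    def test_median_property(self, rng):
        rates = {f"g{i}": float(r) for i, r in enumerate(rng.uniform(0, 1, 1001))}
        sites = [make_site(0.2, 0.2, gene=g, pos=i + 1)
                 for i, g in enumerate(rates)]
        low, high = split_by_recombination(sites, gene_rates=rates)
        # continuous rates: no ties; low gets the median itself
        assert abs(len(low) - len(high)) <= 1

    def test_missing_rate_excluded(self):
        sites = [make_site(0.2, 0.2, gene="a", recomb=1.0, pos=1),
                 make_site(0.2, 0.2, gene="b", recomb=None, pos=2)]
        low, high = split_by_recombination(sites)
        assert all(s.gene_id == "a" for s in low + high)


class TestGeneSets:
    def _classified(self, rng, n=400):
        sites = [
            make_site(rng.uniform(), rng.uniform(),
                      func_class=rng.choice(["nonsynonymous", "synonymous"]),
                      gene=f"g{i % 20}", pos=i + 1)
            for i in range(n)
        ]
        return classify_shared_private(sites, "p1", "p2", "p1")

    def test_partition_conservation(self, rng):
        classified = self._classified(rng)
        set_map = {f"g{i}": ["even" if i % 2 == 0 else "odd"] for i in range(20)}
        grouped = group_by_gene_set(classified, set_map, min_polys_above_01=0)
        total = bin_by_frequency(classified).total.total
        assert grouped["even"].total.total + grouped["odd"].total.total == total

    def test_sparse_set_flagged(self, rng):
        classified = self._classified(rng, n=60)
        grouped = group_by_gene_set(
            classified, {f"g{i}": ["all"] for i in range(20)}, min_polys_above_01=100
        )
        assert grouped["all"].combined_flagged is (grouped["all"].combined_above.total < 100)

    def test_empty_set_absent_and_complement(self, rng):
        classified = self._classified(rng)
        set_map = {"g0": ["hla"]}
        grouped = group_by_gene_set(
            classified, set_map, min_polys_above_01=0, complement_of="hla"
        )
        assert "hla" in grouped and "non_hla" in grouped
        total = bin_by_frequency(classified).total.total
        assert grouped["hla"].total.total + grouped["non_hla"].total.total == total


class TestExpectedRandomOverlap:
    def test_chance_overlap_of_candidate_scan(self):
        raw, rounded = expected_random_overlap(514, 0.079)
        assert raw == pytest.approx(40.606)
        assert rounded == 41

    @pytest.mark.parametrize("n, f, expected", [(0, 0.5, 0.0), (100, 0.5, 50.0)])
    def test_simple(self, n, f, expected):
        assert expected_random_overlap(n, f)[0] == pytest.approx(expected)

    def test_validation(self):
        with pytest.raises(ValueError):
            expected_random_overlap(-1, 0.5)
        with pytest.raises(ValueError):
            expected_random_overlap(10, 1.5)
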