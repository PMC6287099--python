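"""Pooled heterozygosity, windowed Fst, Z-transforms and the DAG/TAG
classification rules."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweepkit.errors import ConfigError, ContractError
from sweepkit.io_formats import GeneModel
from sweepkit.sweep_scan import (
    classify_dags,
    classify_tags,
    crossref_qtl,
    fst_windows,
    hudson_fst_components,
    pooled_heterozygosity,
    tile_windows,
    z_transform,
)

from conftest import make_site, make_table

W = [("chr1", 0, 100_000)]


def _pool_site(pos, ads):
    gts = [(0, 1)] * len(ads)
    return make_site(pos, gts, ads=ads)


class TestPooledHeterozygosity:
    def test_symmetric_single_site_gives_half(self):
        table = make_table([_pool_site(10, [(15, 15)])], samples=["s1"])
        hp = pooled_heterozygosity(table, ["s1"], W)
        assert hp[0] == pytest.approx(0.5)

    def test_monomorphic_pool_gives_zero(self):
        table = make_table([make_site(10, [(0, 0)], ads=[(30, 0)])], samples=["s1"])
        hp = pooled_heterozygosity(table, ["s1"], W)
        assert hp[0] == 0.0

    def test_two_site_window_matches_printed_formula(self):
        table = make_table(
            [_pool_site(10, [(30, 10)]), _pool_site(20, [(30, 10)])], samples=["s1"]
        )
        hp = pooled_heterozygosity(table, ["s1"], W)
        # 2 * (30+30) * (10+10) / (30+30+10+10)^2
        assert hp[0] == pytest.approx(0.375)

    def test_empty_window_list_raises(self):
        with pytest.raises(ConfigError):
            pooled_heterozygosity(make_table([]), ["s1"], [])

    def test_no_snps_in_window_is_nan(self):
        table = make_table([_pool_site(200_000, [(9, 9)])], samples=["s1"])
        hp = pooled_heterozygosity(table, ["s1"], W)
        assert np.isnan(hp[0])

    def test_genotype_fallback_when_depths_absent(self):
        table = make_table([make_site(10, [(0, 1), (0, 1)])])
        hp = pooled_heterozygosity(table, ["s1", "s2"], W)
        assert hp[0] == pytest.approx(0.5)  # 2 ref + 2 alt alleles

    @given(maj=st.integers(0, 200), mi=st.integers(0, 200))
    @settings(max_examples=80, deadline=None)
    def test_range_and_allele_label_invariance(self, maj, mi):
        table = make_table([_pool_site(10, [(maj, mi)])], samples=["s1"])
        hp = pooled_heterozygosity(table, ["s1"], W)[0]
        swapped = pooled_heterozygosity(
            make_table([_pool_site(10, [(mi, maj)])], samples=["s1"]), ["s1"], W
        )[0]
        if maj + mi == 0:
            assert np.isnan(hp)
        else:
            assert 0.0 <= hp <= 0.5
            assert hp == pytest.approx(swapped)


def _two_group_site(pos, gts_a, gts_b):
    return make_site(pos, list(gts_a) + list(gts_b))


class TestFst:
    samples = ["a1", "a2", "b1", "b2"]

    def _table(self, sites):
        return make_table(sites, samples=self.samples)

    def test_fixed_difference_gives_one(self):
        sites = [_two_group_site(p, [(0, 0), (0, 0)], [(1, 1), (1, 1)]) for p in (10, 20)]
        fst = fst_windows(self._table(sites), ["a1", "a2"], ["b1", "b2"], W)
        assert fst[0] == pytest.approx(1.0)

    def test_equal_frequencies_give_zero_mean(self):
        # identical configurations in both groups: expectation-corrected
        # Hudson numerator is negative-to-zero; ratio ~ 0
        sites = [_two_group_site(p, [(0, 1), (0, 1)], [(0, 1), (0, 1)]) for p in (10, 20)]
        fst = fst_windows(self._table(sites), ["a1", "a2"], ["b1", "b2"], W)
        assert fst[0] <= 0.0 + 1e-12

    def test_monomorphic_across_both_groups_skipped(self):
        sites = [_two_group_site(10, [(0, 0), (0, 0)], [(0, 0), (0, 0)])]
        fst = fst_windows(self._table(sites), ["a1", "a2"], ["b1", "b2"], W)
        assert np.isnan(fst[0])

    def test_random_panels_match_per_site_hudson_oracle(self, rng):
        sites, num_sum, den_sum = [], 0.0, 0.0
        for i in range(200):
            ga = [tuple(sorted(rng.integers(0, 2, 2))) for _ in range(2)]
            gb = [tuple(sorted(rng.integers(0, 2, 2))) for _ in range(2)]
            p1 = sum(a for g in ga for a in g) / 4
            p2 = sum(a for g in gb for a in g) / 4
            if p1 == p2 and p1 in (0, 1):
                continue
            sites.append(_two_group_site(10 * i, ga, gb))
            # independent textbook Hudson estimator
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / 3 - p2 * (1 - p2) / 3
            den = p1 * (1 - p2) + p2 * (1 - p1)
            num_sum += num
            den_sum += den
        fst = fst_windows(self._table(sites), ["a1", "a2"], ["b1", "b2"], W)
        assert fst[0] == pytest.approx(num_sum / den_sum, abs=1e-12)

    def test_wc_estimator_closed_forms(self):
        sites = [_two_group_site(p, [(0, 0), (0, 0)], [(1, 1), (1, 1)]) for p in (10, 20)]
        fst = fst_windows(self._table(sites), ["a1", "a2"], ["b1", "b2"], W, estimator="wc")
        assert fst[0] == pytest.approx(1.0)

    def test_group_absent_raises(self):
        with pytest.raises(KeyError):
            fst_windows(self._table([]), ["zz"], ["b1"], W)

    def test_insufficient_calls_per_group_skips_site(self):
        sites = [_two_group_site(10, [(0, 1), None], [(0, 0), (1, 1)])]
        fst = fst_windows(self._table(sites), ["a1", "a2"], ["b1", "b2"], W)
        assert np.isnan(fst[0])


class TestZTransform:
    def test_two_point_case_sample_sd(self):
        z = z_transform([-1.0, 1.0])
        assert z == pytest.approx([-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_mean_zero_sd_one(self, rng):
        z = z_transform(rng.normal(3, 5, 100_000))
        assert abs(np.mean(z)) < 1e-9
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_two_pass_oracle(self, rng):
        x = rng.normal(0, 2, 10_000)
        mean = sum(x) / len(x)
        sd = (sum((v - mean) ** 2 for v in x) / (len(x) - 1)) ** 0.5
        assert np.allclose(z_transform(x), (x - mean) / sd, atol=1e-9)

    def test_nan_passthrough(self):
        z = z_transform([1.0, np.nan, 3.0])
        assert np.isnan(z[1]) and np.isfinite(z[0])

    def test_zero_variance_raises(self):
        with pytest.raises(ContractError):
            z_transform([2.0, 2.0, 2.0])


def _stats(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "zhp", "zfst"])


GENES = [GeneModel(f"g{i}", "chr1", 100_000 * i + 10_000, 100_000 * i + 30_000, "+",
                   cds=[(100_000 * i + 10_000, 100_000 * i + 10_003, 0)]) for i in range(5)]


class TestClassifyDags:
    @pytest.mark.parametrize(
        "zhp,zfst,flagged",
        [(-3.5, 1.0, True), (0.0, 3.2, True), (-2.9, 2.9, False),
         (-3.0, 0.0, True), (0.0, 3.0, True)],
    )
    def test_or_rule_with_inclusive_thresholds(self, zhp, zfst, flagged):
        stats = _stats([("chr1", 0, 100_000, zhp, zfst)])
        calls, dags = classify_dags(stats, GENES)
        assert bool(calls) == flagged
        if flagged:
            assert dags.gene_id.tolist() == ["g0"]

    def test_monotone_in_zfst_cut(self, rng):
        stats = _stats([("chr1", i * 100_000, (i + 1) * 100_000,
                         rng.normal(), rng.normal()) for i in range(40)])
        flagged_hi = {(c.chrom, c.start) for c in classify_dags(stats, GENES, zfst_cut=2.0)[0]}
        flagged_lo = {(c.chrom, c.start) for c in classify_dags(stats, GENES, zfst_cut=1.0)[0]}
        assert flagged_hi <= flagged_lo

    def test_sag_overlap_reported(self):
        stats = _stats([("chr1", 0, 100_000, -4.0, 0.0)])
        _, dags = classify_dags(stats, GENES, sag_gene_sets={"dairy": {"g0"}, "meat": set()})
        assert dags.sag_sets.iloc[0] == "dairy"


class TestClassifyTags:
    def _stats(self, zfst, xpehh):
        n = len(zfst)
        return pd.DataFrame({
            "chrom": ["chr1"] * n,
            "start": np.arange(n) * 100_000,
            "end": (np.arange(n) + 1) * 100_000,
            "zfst": zfst,
            "xpehh": xpehh,
        })

    def test_and_rule(self):
        zfst = [4.2, 4.2] + [0.0] * 198
        xpehh = [5.0, 1.0] + [2.0] * 198  # top 1% (k=2) = window 0 and a zfst-failing window
        calls, tags = classify_tags(self._stats(zfst, xpehh), GENES)
        assert [(c.start, c.end) for c in calls] == [(0, 100_000)]
        assert tags.gene_id.tolist() == ["g0"]

    def test_high_zfst_low_xpehh_not_flagged(self):
        zfst = [4.2] + [0.0] * 199
        xpehh = [1.0] + [2.0] * 199     # 5th-percentile-ish rank
        calls, _ = classify_tags(self._stats(zfst, xpehh), GENES)
        assert calls == []

    def test_flagged_count_bounded_by_top_fraction(self, rng):
        for _ in range(10):
            n = int(rng.integers(100, 500))
            zfst = rng.normal(4.5, 0.1, n)  # everything passes the zfst arm
            xpehh = rng.normal(0, 1, n)
            calls, _ = classify_tags(self._stats(zfst, xpehh), GENES)
            assert len(calls) <= int(np.ceil(0.01 * n))

    def test_missing_xpehh_column_raises(self):
        stats = _stats([("chr1", 0, 100_000, 0.0, 5.0)])
        with pytest.raises(ContractError, match="XP-EHH"):
            classify_tags(stats, GENES)

    def test_nan_xpehh_windows_excluded_from_ranking(self):
        zfst = [4.2, 4.2] + [0.0] * 98
        xpehh = [np.nan, 3.0] + [0.0] * 98
        calls, _ = classify_tags(self._stats(zfst, xpehh), GENES)
        assert [(c.start) for c in calls] == [100_000]


class TestCrossrefQtl:
    def test_overlap_and_chromosome_separation(self):
        qtl = pd.DataFrame(
            [("chr1", 5_000, 40_000, "q1"), ("chr2", 0, 1_000_000, "q2")],
            columns=["chrom", "start", "end", "name"],
        )
        df = crossref_qtl(GENES[:2], qtl)
        assert df[df.gene_id == "g0"].qtl_ids.iloc[0] == "q1"
        assert df[df.gene_id == "g1"].n_qtl.iloc[0] == 0

    def test_random_sets_match_quadratic_oracle(self, rng):
        genes = []
        for i in range(100):
            start = int(rng.integers(0, 900_000))
            genes.append(GeneModel(f"r{i}", "chr1", start, start + int(rng.integers(1_000, 30_000)),
                                   "+", cds=[(start, start + 3, 0)]))
        rows = []
        for j in range(50):
            start = int(rng.integers(0, 900_000))
            rows.append(("chr1", start, start + int(rng.integers(5_000, 80_000)), f"q{j}"))
        qtl = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        df = crossref_qtl(genes, qtl).set_index("gene_id")
        for g in genes:
            expected = sorted(
                name for _, s, e, name in rows if s < g.end and g.start < e
            )
            assert df.loc[g.gene_id, "qtl_ids"] == ",".join(expected)


def test_tile_windows_covers_chromosome():
    tiles = tile_windows({"chr1": 250_000}, 100_000)
    assert tiles == [("chr1", 0, 100_000), ("chr1", 100_000, 200_000), ("chr1", 200_000, 300_000)]
    with pytest.raises(ConfigError):
        tile_windows({"chr1": 100}, 0)
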