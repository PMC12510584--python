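"""Intron clustering, filtering, pruning and differential usage."""

import numpy as np
import pandas as pd
import pytest

from livpm import introns, io as lio, simulate
from tests.conftest import make_meta


def make_introns(rows):
    """rows: (name, start, end) on one contig/strand."""
    return pd.DataFrame(
        [(n, "chr1", s, e, "+") for n, s, e in rows],
        columns=["name", "contig", "start", "end", "strand"],
    ).set_index("name")


def make_counts(introns_df, per_sample_counts):
    return pd.DataFrame(
        per_sample_counts, index=introns_df.index,
        columns=[f"s{i}" for i in range(np.asarray(per_sample_counts).shape[1])],
    )


def brute_force_components(introns_df):
    """Independent connected-components oracle: BFS over shared endpoints."""
    names = list(introns_df.index)
    endpoints = {
        n: {
            (introns_df.loc[n, "contig"], introns_df.loc[n, "strand"], introns_df.loc[n, "start"]),
            (introns_df.loc[n, "contig"], introns_df.loc[n, "strand"], introns_df.loc[n, "end"]),
        }
        for n in names
    }
    seen, comps = set(), []
    for start in names:
        if start in seen:
            continue
        comp, queue = [], [start]
        seen.add(start)
        while queue:
            cur = queue.pop()
            comp.append(cur)
            for other in names:
                if other not in seen and endpoints[cur] & endpoints[other]:
                    seen.add(other)
                    queue.append(other)
        comps.append(sorted(comp))
    return sorted(comps)


class TestReadJunctions:
    def test_zero_fill_and_identity(self, tmp_path):
        t1 = pd.DataFrame([["chr1", 100, 200, "i1", 7, "+"]],
                          columns=["contig", "start", "end", "name", "count", "strand"])
        t2 = pd.DataFrame(
            [["chr1", 100, 200, "i1", 3, "+"], ["chr1", 100, 300, "i2", 5, "+"]],
            columns=["contig", "start", "end", "name", "count", "strand"],
        )
        paths = lio.write_junctions({"a": t1, "b": t2}, tmp_path)
        counts, table = introns.read_junctions(paths)
        assert counts.shape == (2, 2)
        assert counts.loc["chr1:100-200:+", "a"] == 7
        assert counts.loc["chr1:100-300:+", "a"] == 0
        assert counts.loc["chr1:100-300:+", "b"] == 5

    def test_malformed_row_reports_file_and_line(self, tmp_path):
        path = tmp_path / "bad.junc.tsv"
        path.write_text("chr1\t100\t200\ti1\t7\t+\nchr1\tnotanumber\t300\ti2\t2\t+\n")
        with pytest.raises(ValueError, match=r"bad\.junc\.tsv at line 2"):
            introns.read_junctions({"a": str(path)})

    def test_five_file_fixture_matches_hand_table(self, tmp_path, rng):
        base = [("chr1", 100, 200, "+"), ("chr1", 100, 350, "+"), ("chr2", 50, 120, "-")]
        expected = {}
        tables = {}
        for s in range(5):
            picks = rng.choice(3, size=rng.integers(1, 4), replace=False)
            rows = []
            for j in picks:
                c, st_, e, strand = base[j]
                n = int(rng.integers(1, 50))
                rows.append([c, st_, e, f"i{j}", n, strand])
                expected[(f"{c}:{st_}-{e}:{strand}", f"samp{s}")] = n
            tables[f"samp{s}"] = pd.DataFrame(
                rows, columns=["contig", "start", "end", "name", "count", "strand"]
            )
        paths = lio.write_junctions(tables, tmp_path)
        counts, _ = introns.read_junctions(paths)
        for intron in counts.index:
            for samp in counts.columns:
                assert counts.loc[intron, samp] == expected.get((intron, samp), 0)


class TestBuildClusters:
    def test_shared_start_defines_cluster(self):
        tab = make_introns([("i1", 100, 200), ("i2", 100, 300)])
        counts = make_counts(tab, [[30], [30]])
        cs = introns.build_clusters(counts, tab)
        assert len(cs.clusters) == 1
        assert sorted(next(iter(cs.clusters.values()))) == ["i1", "i2"]

    def test_transitive_chain_single_cluster(self):
        rows = [(f"i{k}", 100 * (k + 1), 100 * (k + 2)) for k in range(5)]
        tab = make_introns(rows)
        counts = make_counts(tab, np.full((5, 1), 20))
        cs = introns.build_clusters(counts, tab)
        assert len(cs.clusters) == 1
        assert sorted(next(iter(cs.clusters.values()))) == [f"i{k}" for k in range(5)]

    @pytest.mark.parametrize("span,kept", [(500_000, True), (500_001, False)])
    def test_span_bound(self, span, kept):
        tab = make_introns([("big", 100, 100 + span), ("i1", 100, 200), ("i2", 100, 300)])
        counts = make_counts(tab, np.full((3, 1), 40))
        cs = introns.build_clusters(counts, tab)
        members = set().union(*cs.clusters.values())
        assert ("big" in members) == kept

    def test_min_intron_length(self):
        tab = make_introns([("tiny", 100, 149), ("i1", 100, 200), ("i2", 100, 300)])
        counts = make_counts(tab, np.full((3, 1), 40))
        cs = introns.build_clusters(counts, tab)
        assert "tiny" not in set().union(*cs.clusters.values())

    def test_low_read_support_dropped(self):
        tab = make_introns([("i1", 100, 200), ("i2", 100, 300)])
        counts = make_counts(tab, [[25], [24]])  # total 49 < 50
        cs = introns.build_clusters(counts, tab)
        assert len(cs.clusters) == 0
        assert "low_read_support" in cs.removed_clusters.values()

    def test_opposite_strands_never_cluster(self):
        tab = pd.DataFrame(
            [("p", "chr1", 100, 200, "+"), ("m", "chr1", 100, 200, "-")],
            columns=["name", "contig", "start", "end", "strand"],
        ).set_index("name")
        counts = make_counts(tab, [[60], [60]])
        cs = introns.build_clusters(counts, tab)
        for members in cs.clusters.values():
            assert not {"p", "m"} <= set(members)


class TestFilterIntrons:
    def _set(self, tab, counts):
        cs = introns.build_clusters(counts, tab, min_cluster_reads=0)
        return cs

    def test_zero_fraction_boundary_inclusive(self):
        tab = make_introns([("i1", 100, 200), ("i2", 100, 300)])
        row = np.full(100, 10)
        row_zero = row.copy()
        row_zero[:25] = 0  # exactly 25% zero
        counts = make_counts(tab, np.vstack([row_zero, row]))
        cs = introns.filter_introns(self._set(tab, counts), counts)
        assert cs.flags.get("i1") == "high_zero_rate"
        assert "i2" not in cs.flags

    @pytest.mark.parametrize("share,expect_flag", [(0.04, True), (0.05, False)])
    def test_contribution_boundary(self, share, expect_flag):
        tab = make_introns([("small", 100, 200), ("big", 100, 300)])
        total = 10_000
        counts = make_counts(
            tab, np.array([[int(total * share)], [int(total * (1 - share))]])
        )
        cs = introns.filter_introns(self._set(tab, counts), counts, max_zero_fraction=1.1)
        assert ("small" in cs.flags) == expect_flag

    def test_contributions_computed_before_removal(self):
        # the high-zero intron still counts toward cluster totals
        tab = make_introns([("z", 100, 200), ("a", 100, 300), ("b", 100, 400)])
        z = np.zeros(10, dtype=int)
        z[:5] = 100
        counts = make_counts(tab, np.vstack([z, np.full(10, 6), np.full(10, 94)]))
        cs = introns.filter_introns(self._set(tab, counts), counts)
        # a contributes 60/(500+60+940) = 4% of the pre-removal total -> flagged
        assert cs.flags.get("z") == "high_zero_rate"
        assert cs.flags.get("a") == "low_contribution"


class TestReassessAndPrune:
    def _cluster_set(self, rows, flags=()):
        tab = make_introns(rows)
        cs = introns.IntronClusterSet(introns=tab)
        cs.clusters["c1"] = list(tab.index)
        for f in flags:
            cs.flags[f] = "high_zero_rate"
        return cs

    def test_components_2_2_1_yield_two_clusters(self):
        rows = [
            ("a1", 100, 200), ("a2", 100, 300),          # component of 2
            ("b1", 1000, 1100), ("b2", 1000, 1200),      # component of 2
            ("c1", 5000, 5100),                          # singleton
        ]
        cs = introns.reassess_and_prune(self._cluster_set(rows))
        assert len(cs.clusters) == 2
        assert cs.flags.get("c1") == "pruned_subgraph"
        kept = sorted(tuple(sorted(v)) for v in cs.clusters.values())
        assert kept == [("a1", "a2"), ("b1", "b2")]

    def test_connected_cluster_unchanged(self):
        rows = [("i1", 100, 200), ("i2", 100, 300), ("i3", 200, 300)]
        cs = introns.reassess_and_prune(self._cluster_set(rows))
        assert list(cs.clusters.values()) == [["i1", "i2", "i3"]]

    def test_single_edge_removed(self):
        rows = [("i1", 100, 200), ("i2", 100, 300)]
        cs = introns.reassess_and_prune(self._cluster_set(rows, flags=["i2"]))
        assert cs.clusters == {}
        assert cs.removed_clusters["c1"] == "single_edge"

    def test_all_singletons_removed(self):
        rows = [("i1", 100, 200), ("i2", 1000, 1100), ("i3", 5000, 5100)]
        cs = introns.reassess_and_prune(self._cluster_set(rows))
        assert cs.clusters == {}

    def test_unequal_components_largest_kept(self):
        rows = [
            ("a1", 100, 200), ("a2", 100, 300), ("a3", 200, 300),
            ("b1", 1000, 1100), ("b2", 1000, 1200),
        ]
        cs = introns.reassess_and_prune(self._cluster_set(rows))
        assert len(cs.clusters) == 1
        assert sorted(next(iter(cs.clusters.values()))) == ["a1", "a2", "a3"]
        assert cs.flags.get("b1") == "pruned_subgraph"

    def test_size_filter_over_ten(self):
        rows = [(f"i{k}", 100, 200 + 10 * k) for k in range(12)]  # 12-intron star
        cs = introns.reassess_and_prune(self._cluster_set(rows))
        assert cs.clusters == {}
        assert cs.removed_clusters["c1"] == "size_filtered"

    def test_idempotence_on_random_fixtures(self, rng):
        for trial in range(20):
            rows = []
            for k in range(int(rng.integers(2, 10))):
                anchor = int(rng.integers(1, 6)) * 1000
                rows.append((f"t{trial}i{k}", anchor, anchor + 100 + 50 * k))
            cs0 = self._cluster_set(rows, flags=[rows[0][0]] if rng.uniform() < 0.4 else [])
            once = introns.reassess_and_prune(cs0)
            twice = introns.reassess_and_prune(once)
            assert {k: sorted(v) for k, v in once.clusters.items()} == {
                k: sorted(v) for k, v in twice.clusters.items()
            }

    def test_matches_brute_force_oracle_on_random_fixtures(self, rng):
        for trial in range(50):
            rows = []
            n = int(rng.integers(2, 11))
            for k in range(n):
                anchor = int(rng.integers(1, 5)) * 1000
                end = anchor + int(rng.integers(1, 8)) * 100
                rows.append((f"r{trial}i{k}", anchor, end))
            tab = make_introns(rows)
            tab = tab[~tab.duplicated(subset=["start", "end"])]
            cs = introns.IntronClusterSet(introns=tab)
            cs.clusters["c1"] = list(tab.index)
            pruned = introns.reassess_and_prune(cs)
            comps = brute_force_components(tab)
            sizes = [len(c) for c in comps]
            best = max(sizes)
            if best == 1 or (len(comps) == 1 and not 2 <= sizes[0] <= 10):
                expected = []
            else:
                expected = sorted(tuple(c) for c in comps if len(c) == best and 2 <= len(c) <= 10)
            got = sorted(tuple(sorted(v)) for v in pruned.clusters.values())
            assert got == expected, f"trial {trial}"

    def test_retained_clusters_connected(self, small_bundle, tmp_path):
        paths = lio.write_junctions(small_bundle.junctions, tmp_path)
        counts, tab = introns.read_junctions(paths)
        cs = introns.build_clusters(counts, tab)
        cs = introns.filter_introns(cs, counts)
        cs = introns.reassess_and_prune(cs)
        assert cs.clusters
        for members in (cs.retained_introns(c) for c in cs.clusters):
            assert len(brute_force_components(cs.introns.loc[members])) == 1
            assert 2 <= len(members) <= 10

    def test_flag_provenance_partition(self, small_bundle, tmp_path):
        paths = lio.write_junctions(small_bundle.junctions, tmp_path)
        counts, tab = introns.read_junctions(paths)
        cs = introns.reassess_and_prune(introns.filter_introns(introns.build_clusters(counts, tab), counts))
        retained = set().union(*(cs.retained_introns(c) for c in cs.clusters))
        assert retained.isdisjoint(cs.flags)


class TestUsageRatios:
    def _fixture(self):
        tab = make_introns([("i1", 100, 200), ("i2", 100, 300), ("i3", 100, 400)])
        cs = introns.IntronClusterSet(introns=tab)
        cs.clusters["c1"] = list(tab.index)
        meta = make_meta(2, 2)
        counts = pd.DataFrame(
            [[10, 10, 5, 5], [5, 5, 10, 10], [5, 5, 5, 5]],
            index=tab.index, columns=meta.sample_id,
        )
        return cs, counts, meta

    def test_ratio_and_higher_group(self):
        cs, counts, meta = self._fixture()
        usage = introns.usage_ratios(cs, counts, meta).set_index("intron")
        assert usage.loc["i1", "usage_ratio"] == pytest.approx(2.0)
        assert usage.loc["i1", "higher_group"] == "LIV"
        assert usage.loc["i2", "higher_group"] == "PM"
        assert usage.loc["i3", "usage_ratio"] == pytest.approx(1.0)
        assert usage.loc["i3", "higher_group"] == "tie"

    def test_usages_sum_to_one_per_group(self):
        cs, counts, meta = self._fixture()
        usage = introns.usage_ratios(cs, counts, meta)
        assert usage["liv_usage"].sum() == pytest.approx(1.0)
        assert usage["pm_usage"].sum() == pytest.approx(1.0)
        np.testing.assert_allclose(usage["liv_usage"], [0.5, 0.25, 0.25])

    def test_zero_group_total_flagged(self):
        cs, counts, meta = self._fixture()
        counts.loc[:, meta.loc[meta.liv_pm_status == "PM", "sample_id"]] = 0
        usage = introns.usage_ratios(cs, counts, meta)
        assert usage["undefined"].all()
        assert usage["usage_ratio"].isna().all()


class TestDifferentialUsage:
    def _cluster(self, liv_usage, pm_usage, n_per_group=30, depth=200, seed=0):
        rng = np.random.default_rng(seed)
        tab = make_introns(
            [(f"i{k}", 100, 200 + 100 * k) for k in range(len(liv_usage))]
        )
        cs = introns.IntronClusterSet(introns=tab)
        cs.clusters["c1"] = list(tab.index)
        meta = make_meta(n_per_group, n_per_group)
        counts = np.empty((len(liv_usage), 2 * n_per_group), dtype=int)
        for j in range(2 * n_per_group):
            p = liv_usage if j < n_per_group else pm_usage
            counts[:, j] = rng.multinomial(depth, p)
        return cs, pd.DataFrame(counts, index=tab.index, columns=meta.sample_id), meta

    def test_strong_shift_significant(self):
        cs, counts, meta = self._cluster([0.9, 0.1], [0.1, 0.9])
        res = introns.test_differential_usage(cs, counts, meta)
        assert res.iloc[0]["tested"]
        assert res.iloc[0]["adjusted_p"] < 0.05

    def test_nine_samples_per_group_untested(self):
        cs, counts, meta = self._cluster([0.5, 0.5], [0.5, 0.5], n_per_group=9)
        res = introns.test_differential_usage(cs, counts, meta)
        assert not res.iloc[0]["tested"]
        assert res.iloc[0]["reason"] == "too_few_samples_per_group"

    def test_null_type_one_error_near_nominal(self):
        rejections = []
        for seed in range(60):
            cs, counts, meta = self._cluster([0.4, 0.6], [0.4, 0.6], seed=seed, depth=150)
            res = introns.test_differential_usage(cs, counts, meta, seed=seed)
            rejections.append(res.iloc[0]["p_value"] < 0.05)
        assert np.mean(rejections) < 0.15

    def test_liv_downsampled_to_one_per_individual(self):
        cs, counts, meta = self._cluster([0.5, 0.5], [0.5, 0.5], n_per_group=12)
        # give every LIV individual a replicate with identical counts
        liv = meta[meta.liv_pm_status == "LIV"]
        extra_meta = liv.assign(sample_id=liv.sample_id + "_rep")
        meta2 = pd.concat([meta, extra_meta], ignore_index=True)
        counts2 = pd.concat(
            [counts, counts[liv.sample_id].rename(columns=lambda s: s + "_rep")], axis=1
        )
        res = introns.test_differential_usage(cs, counts2, meta2, seed=1)
        res_single = introns.test_differential_usage(cs, counts, meta, seed=1)
        # identical replicates: downsampling reproduces the single-sample test
        assert res.iloc[0]["p_value"] == pytest.approx(res_single.iloc[0]["p_value"])


class TestSummarizeUsage:
    @pytest.mark.parametrize(
        "sig,tested,expected", [(7141, 11222, 64.0), (18428, 28001, 66.0), (0, 50, 0.0)]
    )
    def test_percentage_arithmetic(self, sig, tested, expected):
        from livpm.stats import percent_significant

        assert percent_significant(sig, tested) == expected

    def test_summary_counts(self):
        res = pd.DataFrame(
            {
                "cluster": ["a", "b", "c"],
                "tested": [True, True, False],
                "p_value": [0.001, 0.5, np.nan],
            }
        )
        res["adjusted_p"] = [0.002, 0.5, np.nan]
        out = introns.summarize_usage_significance(res)
        assert out["n_clusters_tested"] == 2
        assert out["n_clusters_significant"] == 1
        assert out["percent_clusters"] == 50.0
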