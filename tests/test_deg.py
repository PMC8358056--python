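"""DEG calling thresholds, contrast counting, Venn regions, temporal classes."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from droughtkit import deg
from droughtkit.simulate import SimulationConfig, simulate_deg_table


def make_records(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "tissue", "timepoint", "log2_fold_change", "adjusted_p"]
    )


def brute_force_calls(records, padj_cut=0.05, lfc_cut=1.0):
    """Independent row-by-row filter."""
    out = []
    for _, r in records.iterrows():
        p, lfc = r["adjusted_p"], r["log2_fold_change"]
        if pd.notna(p) and p < padj_cut and lfc > lfc_cut:
            out.append("up")
        elif pd.notna(p) and p < padj_cut and lfc < -lfc_cut:
            out.append("down")
        else:
            out.append("none")
    return out


class TestCallDegs:
    @pytest.mark.parametrize(
        "lfc, padj, expected",
        [
            (1.5, 0.01, "up"),
            (-1.5, 0.01, "down"),
            (1.0, 0.01, "none"),  # strict >
            (-1.0, 0.01, "none"),
            (1.5, 0.05, "none"),  # strict <
            (1.5, np.nan, "none"),  # NA adjusted p is non-significant
            (0.5, 0.001, "none"),
        ],
    )
    def test_threshold_strictness(self, lfc, padj, expected):
        records = make_records([("g1", "leaf", 6, lfc, padj)])
        assert deg.call_degs(records)["direction"].iloc[0] == expected

    def test_matches_brute_force_on_random_table(self, rng):
        n = 10_000
        records = make_records(
            [
                (f"g{i}", "leaf", 6, lfc, padj)
                for i, (lfc, padj) in enumerate(
                    zip(rng.normal(0, 1.5, n), rng.uniform(0, 1, n))
                )
            ]
        )
        calls = deg.call_degs(records)
        assert calls["direction"].tolist() == brute_force_calls(records)

    def test_monotone_in_thresholds(self, rng):
        n = 2000
        records = make_records(
            [
                (f"g{i}", "leaf", 6, lfc, padj)
                for i, (lfc, padj) in enumerate(
                    zip(rng.normal(0, 1.5, n), rng.uniform(0, 1, n))
                )
            ]
        )

        def n_deg(padj_cut, lfc_cut):
            calls = deg.call_degs(records, padj_cut=padj_cut, lfc_cut=lfc_cut)
            return int((calls["direction"] != "none").sum())

        base = n_deg(0.05, 1.0)
        assert n_deg(0.10, 1.0) >= base  # relaxing padj upward
        assert n_deg(0.05, 0.5) >= base  # relaxing lfc downward
        assert n_deg(0.01, 2.0) <= base

    def test_partition(self, rng):
        records = make_records(
            [
                (f"g{i}", "leaf", 6, lfc, padj)
                for i, (lfc, padj) in enumerate(
                    zip(rng.normal(0, 2, 500), rng.uniform(0, 1, 500))
                )
            ]
        )
        calls = deg.call_degs(records)
        assert set(calls["direction"]) <= {"up", "down", "none"}
        assert len(calls) == 500

    def test_column_remap_and_missing_columns(self):
        df = pd.DataFrame(
            {
                "gene_id": ["g1"],
                "tissue": ["leaf"],
                "timepoint": [6],
                "log2FoldChange": [2.0],
                "padj": [0.001],
            }
        )
        calls = deg.call_degs(
            df, columns={"log2_fold_change": "log2FoldChange", "adjusted_p": "padj"}
        )
        assert calls["direction"].iloc[0] == "up"
        with pytest.raises(ValueError, match="missing required columns"):
            deg.call_degs(df)

    def test_invalid_padj_rejected(self):
        with pytest.raises(ValueError):
            deg.call_degs(make_records([("g1", "leaf", 6, 1.0, 1.5)]))


class TestCounting:
    def test_empty_calls(self):
        calls = deg.call_degs(make_records([]))
        assert deg.count_by_contrast(calls).empty

    def test_planted_counts_recovered(self):
        cfg = SimulationConfig(
            seed=7, n_genes=1000, deg_fractions={("leaf", 6): (0.1, 0.05)}
        )
        res = simulate_deg_table(cfg)
        counts = deg.count_by_contrast(deg.call_degs(res["table"]))
        row = counts.iloc[0]
        assert (row["n_up"], row["n_down"], row["n_total"]) == (100, 50, 150)

    def test_duplicate_gene_in_contrast_rejected(self):
        calls = deg.call_degs(
            make_records(
                [("g1", "leaf", 6, 2.0, 0.01), ("g1", "leaf", 6, 1.5, 0.02)]
            )
        )
        with pytest.raises(ValueError, match="duplicate"):
            deg.count_by_contrast(calls)


def brute_force_venn(sets):
    """Enumerate every gene's exact membership pattern."""
    universe = set().union(*sets.values())
    regions = {}
    for r in range(1, len(sets) + 1):
        for patt in combinations(sets, r):
            regions[frozenset(patt)] = 0
    for g in universe:
        patt = frozenset(tp for tp, s in sets.items() if g in s)
        regions[patt] += 1
    return regions, len(universe)


class TestVenn:
    def _calls_from_sets(self, sets):
        rows = []
        for tp, genes in sets.items():
            for g in genes:
                rows.append((g, "leaf", tp, 2.0, 0.01))
        return deg.call_degs(make_records(rows))

    def test_identical_sets(self):
        genes = {f"g{i}" for i in range(20)}
        calls = self._calls_from_sets({tp: genes for tp in (6, 12, 24, 48)})
        v = deg.intersect_contrasts(calls, "leaf")
        assert v.full_intersection == 20
        assert v.union_size == 20
        for patt, n in v.regions.items():
            assert n == (20 if len(patt) == 4 else 0)

    def test_disjoint_sets(self):
        sets = {tp: {f"g{tp}_{i}" for i in range(5)} for tp in (6, 12, 24, 48)}
        v = deg.intersect_contrasts(self._calls_from_sets(sets), "leaf")
        assert v.full_intersection == 0
        assert v.union_size == 20

    def test_random_sets_match_brute_force(self, rng):
        genes = [f"g{i}" for i in range(200)]
        sets = {
            tp: set(rng.choice(genes, size=rng.integers(10, 150), replace=False))
            for tp in (6, 12, 24, 48)
        }
        v = deg.intersect_contrasts(self._calls_from_sets(sets), "leaf")
        expected, union = brute_force_venn(sets)
        assert dict(v.regions) == expected
        assert v.union_size == union
        # conservation: the 15 disjoint regions sum to the union
        assert sum(v.regions.values()) == union
        # each k-way intersection equals direct set algebra
        for r in range(1, 5):
            for patt in combinations((6, 12, 24, 48), r):
                direct = set.intersection(*(sets[tp] for tp in patt))
                assert v.intersection(patt) == len(direct)

    def test_unknown_timepoint_rejected(self):
        calls = self._calls_from_sets({96: {"g1"}})
        with pytest.raises(ValueError, match="unknown timepoints"):
            deg.intersect_contrasts(calls, "leaf")


class TestTemporal:
    def _classify(self, rows):
        return deg.classify_temporal(deg.call_degs(make_records(rows)))

    def test_short_only(self):
        out = self._classify([("g1", "leaf", 6, 2.0, 0.01), ("g1", "leaf", 24, 0.1, 0.9)])
        assert out.loc[0, "short_acting"] and not out.loc[0, "long_acting"]

    def test_both_stages(self):
        out = self._classify(
            [("g1", "leaf", 12, 2.0, 0.01), ("g1", "leaf", 48, -2.0, 0.01)]
        )
        assert out.loc[0, "short_acting"] and out.loc[0, "long_acting"]

    def test_neither(self):
        out = self._classify([("g1", "leaf", 6, 0.2, 0.9)])
        assert not out.loc[0, "short_acting"] and not out.loc[0, "long_acting"]

    def test_per_tissue_classes(self):
        out = self._classify(
            [("g1", "leaf", 6, 2.0, 0.01), ("g1", "rhizome", 48, -2.0, 0.01)]
        )
        leaf = out[out["tissue"] == "leaf"].iloc[0]
        rhiz = out[out["tissue"] == "rhizome"].iloc[0]
        assert leaf["short_acting"] and not leaf["long_acting"]
        assert rhiz["long_acting"] and not rhiz["short_acting"]


class TestCrossTissue:
    def test_disjoint_universes(self):
        leaf = deg.call_degs(make_records([("gA", "leaf", 6, 2.0, 0.01)]))
        rhiz = deg.call_degs(make_records([("gB", "rhizome", 6, 2.0, 0.01)]))
        assert deg.cross_tissue_overlap(leaf, rhiz) == set()

    def test_shared_gene(self):
        leaf = deg.call_degs(make_records([("gA", "leaf", 6, 2.0, 0.01)]))
        rhiz = deg.call_degs(make_records([("gA", "rhizome", 48, -2.0, 0.01)]))
        assert deg.cross_tissue_overlap(leaf, rhiz) == {"gA"}

    def test_planted_overlap_recovered(self, rng):
        shared = {f"s{i}" for i in range(37)}
        leaf_only = {f"l{i}" for i in range(50)}
        rhiz_only = {f"r{i}" for i in range(60)}
        leaf = deg.call_degs(
            make_records([(g, "leaf", 6, 2.0, 0.01) for g in shared | leaf_only])
        )
        rhiz = deg.call_degs(
            make_records([(g, "rhizome", 12, -2.0, 0.01) for g in shared | rhiz_only])
        )
        assert deg.cross_tissue_overlap(leaf, rhiz) == shared
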