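import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pol3dyn import classification as cl
from pol3dyn.scoring import ScoreTable


def make_loci(rows):
    """(locus_id, chrom, start, end) tuples -> locus frame (strand +)."""
    df = pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end"])
    df["strand"] = "+"
    df["locus_type"] = "tRNA"
    df["tss"] = df["start"]
    return df


class TestFlagIsolated:
    def test_single_locus_is_isolated(self):
        assert cl.flag_isolated(make_loci([("a", "chr1", 0, 100)]))["a"]

    def test_boundary_gap(self):
        near = make_loci([("a", "chr1", 0, 100), ("b", "chr1", 1599, 1700)])
        assert not cl.flag_isolated(near).any()  # gap 1499
        exact = make_loci([("a", "chr1", 0, 100), ("b", "chr1", 1600, 1700)])
        assert cl.flag_isolated(exact).all()     # gap 1500, inclusive

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            rows = [(f"L{i}", f"chr{rng.integers(1, 3)}",
                     s := int(rng.integers(0, 30_000)),
                     s + int(rng.integers(50, 300)))
                    for i in range(50)]
            loci = make_loci(rows)
            got = cl.flag_isolated(loci)
            for i, a in loci.iterrows():
                iso = True
                for j, b in loci.iterrows():
                    if i == j or a["chrom"] != b["chrom"]:
                        continue
                    gap = max(b["start"] - a["end"], a["start"] - b["end"])
                    if gap < 1500:
                        iso = False
                assert got[a["locus_id"]] == iso


class TestFlagNearPol2:
    def pol2(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "kind",
                                           "strand"])

    def test_boundary_distance_is_near(self):
        loci = make_loci([("a", "chr1", 10_000, 10_100)])
        feats = self.pol2([("g", "chr1", 10_100 - 1 + 2650, "tss", "+")])
        assert cl.flag_near_pol2(loci, feats)["a"]
        feats_far = self.pol2([("g", "chr1", 10_100 + 2650, "polyA", "+")])
        assert not cl.flag_near_pol2(loci, feats_far)["a"]

    def test_no_features_means_far(self):
        loci = make_loci([("a", "chr1", 0, 100)])
        assert not cl.flag_near_pol2(loci, self.pol2([]))["a"]

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            loci = make_loci([
                (f"L{i}", "chr1", s := int(rng.integers(0, 50_000)), s + 80)
                for i in range(12)
            ])
            feats = self.pol2([
                (f"g{i}", "chr1", int(rng.integers(0, 50_000)),
                 "tss" if i % 2 else "polyA", "+")
                for i in range(6)
            ])
            got = cl.flag_near_pol2(loci, feats)
            for _, a in loci.iterrows():
                d = min(max(a["start"] - p, p - (a["end"] - 1), 0)
                        for p in feats["pos"])
                assert got[a["locus_id"]] == (d <= 2650)


class TestFlagCpg:
    def test_island_within_window(self):
        loci = make_loci([("a", "chr1", 10_000, 10_080)])
        isl = pd.DataFrame([("chr1", 10_999, 11_400)],
                           columns=["chrom", "start", "end"])
        assert cl.flag_cpg(loci, isl)["a"]

    def test_no_islands(self):
        loci = make_loci([("a", "chr1", 10_000, 10_080)])
        assert not cl.flag_cpg(loci, loci.iloc[0:0][["chrom", "start", "end"]])["a"]

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            loci = make_loci([
                (f"L{i}", "chr1", s := int(rng.integers(1_000, 40_000)), s + 80)
                for i in range(10)
            ])
            isl = pd.DataFrame(
                [("chr1", p := int(rng.integers(0, 40_000)),
                  p + int(rng.integers(200, 1_500))) for _ in range(5)],
                columns=["chrom", "start", "end"])
            got = cl.flag_cpg(loci, isl)
            for _, a in loci.iterrows():
                lo, hi = a["tss"] - 1000, a["tss"] + 1000
                hit = any(r.start < hi and r.end > lo for r in isl.itertuples())
                assert got[a["locus_id"]] == hit


def tiny_score_table(scores: pd.DataFrame, thresholds: pd.Series,
                     sheet: pd.DataFrame) -> ScoreTable:
    zeros = scores * 0.0
    return ScoreTable(
        loci=make_loci([(lid, "chr1", 100 * i, 100 * i + 80)
                        for i, lid in enumerate(scores.index)]),
        chip_counts=zeros, input_counts=zeros, scores=scores,
        thresholds=thresholds,
        norm_factors=pd.Series(1.0, index=scores.columns),
        sample_sheet=sheet,
    )


class TestAssignGroups:
    @staticmethod
    def table(score_rows):
        cols = ["RPC4_r1", "H3K4me3_r2", "RPB2_r1"]
        scores = pd.DataFrame(score_rows, columns=cols,
                              index=[f"L{i}" for i in range(len(score_rows))])
        sheet = pd.DataFrame({
            "sample_id": cols,
            "factor": ["RPC4", "H3K4me3", "RPB2"],
            "timepoint": "TP0", "replicate": [1, 2, 1],
            "input_id": "inp",
        })
        return tiny_score_table(scores, pd.Series(1.0, index=cols), sheet)

    rep_map = {"rep1": {"RPC4": "RPC4_r1", "H3K4me3": "H3K4me3_r2",
                        "RPB2": "RPB2_r1"}}

    def test_all_below_threshold_is_no_peak_group(self):
        t = self.table([[0.2, 0.1, 0.0]] * 3)
        assert (cl.assign_groups(t, self.rep_map)["rep1"] == "none").all()

    def test_groups_partition_loci(self):
        t = self.table([[2, 2, 2], [2, 0, 2], [0, 2, 0], [2, 0, 0]])
        g = cl.assign_groups(t, self.rep_map)["rep1"]
        assert list(g) == ["RPC4+H3K4me3+RPB2", "RPC4+RPB2", "H3K4me3", "RPC4"]
        summary = cl.summarize_groups(
            cl.assign_groups(t, self.rep_map), t.loci)
        per_type = summary.groupby(["combo", "locus_type"])
        assert (per_type["count"].sum() == 4).all()
        assert per_type["pct"].sum().iloc[0] == pytest.approx(100.0, abs=0.1)

    def test_missing_sample_is_named(self):
        t = self.table([[2, 2, 2]])
        with pytest.raises(KeyError, match="ghost"):
            cl.assign_groups(t, {"rep1": {"RPC4": "ghost"}})


class TestPermutationTTest:
    def test_identical_groups_give_large_p(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        p = cl.permutation_t_test(x, x[::-1], n_perm=500, seed=1)
        assert p > 0.5

    def test_zero_variance_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert cl.permutation_t_test([1, 1, 1], [1, 1]) == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        """Sampled permutation p agrees with the exact split enumeration."""
        for _ in range(100):
            x = rng.normal(size=3)
            y = rng.normal(loc=rng.normal(), size=2)
            exact = cl.permutation_t_test(x, y, exhaustive=True)
            n_perm = 2000
            p = cl.permutation_t_test(x, y, n_perm=n_perm, seed=12)
            se = math.sqrt(exact * (1 - exact) / n_perm)
            assert abs(p - exact) <= 4 * se + 2 / n_perm

    def test_type_i_error_calibration(self, rng):
        hits = 0
        trials = 600
        for _ in range(trials):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            if cl.permutation_t_test(x, y, n_perm=99,
                                     seed=int(rng.integers(2**31))) <= 0.05:
                hits += 1
        rate = hits / trials
        se = math.sqrt(0.05 * 0.95 / trials)
        assert rate <= 0.05 + 3 * se
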