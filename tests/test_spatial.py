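import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pol3dyn import spatial as sp


def trna(rows):
    df = pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end"])
    df["strand"] = "+"
    df["locus_type"] = "tRNA"
    df["tss"] = df["start"]
    return df


def brute_force_clusters(loci, max_gap=5000, min_size=3):
    """Independent maximal-chain enumeration."""
    out = []
    for chrom in sorted(loci["chrom"].unique()):
        sub = loci[loci["chrom"] == chrom].sort_values("start")
        ids = list(sub["locus_id"])
        members = [[ids[0]]]
        chain_end = int(sub["end"].iloc[0])
        for _, r in list(sub.iterrows())[1:]:
            if r["start"] - chain_end < max_gap:
                members[-1].append(r["locus_id"])
            else:
                members.append([r["locus_id"]])
            chain_end = max(chain_end, int(r["end"]))
        out.extend([m for m in members if len(m) >= min_size])
    return out


class TestCallClusters:
    def test_three_genes_with_small_gaps(self):
        loci = trna([("a", "chr1", 0, 80), ("b", "chr1", 4080, 4160),
                     ("c", "chr1", 8160, 8240)])
        clusters = sp.call_clusters(loci)
        assert len(clusters) == 1
        assert clusters[0].members == ["a", "b", "c"]
        assert (clusters[0].start, clusters[0].end) == (0, 8240)

    def test_broken_chain_yields_no_cluster(self):
        loci = trna([("a", "chr1", 0, 80), ("b", "chr1", 4080, 4160),
                     ("c", "chr1", 10160, 10240), ("d", "chr1", 14240, 14320)])
        assert sp.call_clusters(loci) == []

    def test_boundary_gap_is_exclusive(self):
        loci = trna([("a", "chr1", 0, 80), ("b", "chr1", 5080, 5160),
                     ("c", "chr1", 10160, 10240)])
        assert sp.call_clusters(loci) == []  # gaps exactly 5000

    def test_matches_brute_force_and_input_order_invariance(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 25))
            rows = []
            pos = 0
            for i in range(n):
                pos += int(rng.integers(100, 8000))
                rows.append((f"L{i}", f"chr{rng.integers(1, 3)}", pos, pos + 80))
            loci = trna(rows)
            got = [c.members for c in sp.call_clusters(loci)]
            assert got == brute_force_clusters(loci)
            shuffled = loci.sample(frac=1, random_state=0)
            assert [c.members for c in sp.call_clusters(shuffled)] == got

    def test_clusters_disjoint_and_separated(self, rng):
        rows = []
        pos = 0
        for i in range(60):
            pos += int(rng.integers(100, 7000))
            rows.append((f"L{i}", "chr1", pos, pos + 70))
        clusters = sp.call_clusters(trna(rows))
        seen = set()
        for c in clusters:
            assert not seen & set(c.members)
            seen |= set(c.members)
        for a, b in zip(clusters, clusters[1:]):
            assert b.start - a.end >= 5000


class TestClusterKS:
    def _clusters(self):
        loci = trna([(f"L{i}", "chr1", i * 1000, i * 1000 + 80)
                     for i in range(6)])
        return sp.call_clusters(loci.iloc[:3]), loci

    def test_identical_distributions(self):
        clusters, loci = self._clusters()
        fc = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                       index=[f"L{i}" for i in range(6)])
        res = sp.cluster_ks_tests(fc, clusters,
                                  loci.set_index("locus_id")["chrom"])
        assert res["D"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_extreme_separation(self):
        clusters, loci = self._clusters()
        fc = pd.Series([4.0, 4.1, 4.2, 1.0, 1.1, 1.2],
                       index=[f"L{i}" for i in range(6)])
        res = sp.cluster_ks_tests(fc, clusters,
                                  loci.set_index("locus_id")["chrom"])
        assert res["D"].iloc[0] == pytest.approx(1.0)

    def test_null_type_i_error(self, rng):
        loci = trna([(f"L{i}", "chr1", i * 1000, i * 1000 + 80)
                     for i in range(40)])
        clusters = sp.call_clusters(loci.iloc[:5])
        chrom_of = loci.set_index("locus_id")["chrom"]
        hits = 0
        trials = 400
        for _ in range(trials):
            fc = pd.Series(rng.normal(size=40), index=loci["locus_id"])
            res = sp.cluster_ks_tests(fc, clusters, chrom_of)
            hits += int(res["p"].iloc[0] < 0.05)
        se = math.sqrt(0.05 * 0.95 / trials)
        assert hits / trials <= 0.05 + 3 * se


class TestChromosomeChisq:
    def test_proportional_table_gives_zero(self):
        status = pd.Series(["changing"] * 4 + ["stable"] * 4,
                           index=list("abcdefgh"))
        chrom = pd.Series(["chr1", "chr1", "chr2", "chr2"] * 2,
                          index=list("abcdefgh"))
        chi2, dof, p, _, resid = sp.chromosome_chisq(status, chrom)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert np.allclose(resid, 0.0)

    def test_two_by_two_hand_computation(self):
        # table [[10, 90], [50, 50]]: margins give E=[[30,70],[30,70]],
        # chi2 = 2*(400/30 + 400/70) = 38.0952...
        idx = range(200)
        status = pd.Series(["changing"] * 10 + ["stable"] * 90
                           + ["changing"] * 50 + ["stable"] * 50, index=idx)
        chrom = pd.Series(["chr1"] * 100 + ["chr2"] * 100, index=idx)
        chi2, dof, p, table, _ = sp.chromosome_chisq(status, chrom)
        assert chi2 == pytest.approx(800.0 / 21.0)
        assert dof == 1

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(100):
            n_chrom = int(rng.integers(2, 6))
            counts = rng.integers(1, 40, size=(n_chrom, 2))
            rows = []
            for ci in range(n_chrom):
                rows += [(f"chr{ci}", "changing")] * counts[ci, 0]
                rows += [(f"chr{ci}", "stable")] * counts[ci, 1]
            df = pd.DataFrame(rows, columns=["chrom", "status"])
            chi2, dof, p, table, resid = sp.chromosome_chisq(
                df["status"], df["chrom"])
            obs = table.to_numpy().astype(float)
            exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            brute = ((obs - exp) ** 2 / exp).sum()
            assert chi2 == pytest.approx(brute, rel=1e-12)
            assert np.allclose(resid, (obs - exp) / np.sqrt(exp))

    def test_single_chromosome_errors(self):
        status = pd.Series(["changing", "stable"], index=["a", "b"])
        chrom = pd.Series(["chr1", "chr1"], index=["a", "b"])
        with pytest.raises(ValueError):
            sp.chromosome_chisq(status, chrom)


def brute_force_hypergeom_tail(a, b, k, n):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for j in range(k, min(a, b) + 1):
        total += (math.comb(a, j) * math.comb(n - a, b - j)) / math.comb(n, b)
    return total


class TestOverlapEnrichment:
    def test_published_style_counts(self):
        expected, fold, p = sp.overlap_enrichment(107, 97, 51, 433)
        assert expected == pytest.approx(107 * 97 / 433)
        assert fold == pytest.approx(51 / (107 * 97 / 433))
        assert p < 1e-6

    def test_overlap_at_expectation_has_fold_one(self):
        expected, fold, _ = sp.overlap_enrichment(10, 20, 2, 100)
        assert expected == pytest.approx(2.0)
        assert fold == pytest.approx(1.0)

    def test_matches_enumeration_on_small_universe(self, rng):
        for _ in range(100):
            n = 10
            a, b = int(rng.integers(1, n + 1)), int(rng.integers(1, n + 1))
            k = int(rng.integers(0, min(a, b) + 1))
            _, _, p = sp.overlap_enrichment(min(a, b), max(a, b), k, n)
            assert p == pytest.approx(
                brute_force_hypergeom_tail(min(a, b), max(a, b), k, n),
                rel=1e-9)

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            sp.overlap_enrichment(10, 20, 15, 100)
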