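"""Spatial statistics: tRNA gene clusters and chromosome-level tests.

A tRNA cluster is a maximal run of three or more tRNA genes on one
chromosome, each spaced (edge-to-edge) strictly less than 5 kb from the
next.  Fold-change distributions inside vs outside clusters are compared per
chromosome with two-sample Kolmogorov-Smirnov tests; the association between
chromosome and changing/stable status is tested with a chi-square
independence test; the overlap of two changing-gene sets is assessed with an
upper-tail hypergeometric test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Maximum edge-to-edge gap (bp, exclusive) between consecutive cluster genes.
CLUSTER_MAX_GAP = 5000
#: Minimum number of genes in a cluster.
CLUSTER_MIN_SIZE = 3


@dataclass
class Cluster:
    cluster_id: str
    chrom: str
    members: list[str]           # locus ids, ordered by start
    start: int                   # span of the member bodies
    end: int


def call_clusters(trna_loci: pd.DataFrame, max_gap: int = CLUSTER_MAX_GAP,
                  min_size: int = CLUSTER_MIN_SIZE) -> list[Cluster]:
    """Chain tRNA genes into clusters by a single per-chromosome linear scan.

    Genes are chained while ``start(next) - end(current) < max_gap``; maximal
    chains with at least ``min_size`` members become clusters.  Cluster ids
    are deterministic (chromosome order, then position).
    """
    clusters: list[Cluster] = []
    n = 0
    for chrom in sorted(trna_loci["chrom"].unique()):
        sub = trna_loci[trna_loci["chrom"] == chrom].sort_values(
            ["start", "end"], kind="mergesort"
        )
        chain: list[pd.Series] = []
        chain_end = None

        def flush(chain):
            nonlocal n
            if len(chain) >= min_size:
                n += 1
                clusters.append(Cluster(
                    cluster_id=f"cluster_{n:03d}",
                    chrom=chrom,
                    members=[r["locus_id"] for r in chain],
                    start=int(min(r["start"] for r in chain)),
                    end=int(max(r["end"] for r in chain)),
                ))

        for _, row in sub.iterrows():
            if chain and row["start"] - chain_end < max_gap:
                chain.append(row)
                chain_end = max(chain_end, int(row["end"]))
            else:
                flush(chain)
                chain = [row]
                chain_end = int(row["end"])
        flush(chain)
    return clusters


def clusters_to_frames(clusters: list[Cluster]):
    """(span BED-like frame, membership frame) for text output."""
    span = pd.DataFrame(
        [(c.chrom, c.start, c.end, c.cluster_id, len(c.members))
         for c in clusters],
        columns=["chrom", "start", "end", "cluster_id", "n_members"],
    )
    member = pd.DataFrame(
        [(c.cluster_id, m) for c in clusters for m in c.members],
        columns=["cluster_id", "locus_id"],
    )
    return span, member


def cluster_ks_tests(fold_changes: pd.Series, clusters: list[Cluster],
                     chrom_of: pd.Series) -> pd.DataFrame:
    """Per-cluster KS test of member fold changes vs the non-clustered genes
    of the same chromosome.

    ``fold_changes`` maps locus id to the (log2) occupancy fold change;
    ``chrom_of`` maps locus id to chromosome.  Clusters without at least one
    finite member and one finite outside value are skipped with a log entry.
    """
    clustered_ids = {m for c in clusters for m in c.members}
    rows = []
    for c in clusters:
        inside = fold_changes.reindex(c.members).dropna()
        outside_ids = [
            lid for lid in fold_changes.index
            if chrom_of.get(lid) == c.chrom and lid not in clustered_ids
        ]
        outside = fold_changes.reindex(outside_ids).dropna()
        if len(inside) == 0 or len(outside) == 0:
            logger.info("skipping %s: %d inside / %d outside usable genes",
                        c.cluster_id, len(inside), len(outside))
            continue
        ks = stats.ks_2samp(inside.to_numpy(), outside.to_numpy(),
                            alternative="two-sided", method="asymp")
        rows.append((c.cluster_id, c.chrom, len(inside), len(outside),
                     float(ks.statistic), float(ks.pvalue),
                     bool(ks.pvalue < 0.05)))
    return pd.DataFrame(
        rows, columns=["cluster_id", "chrom", "n_in", "n_out", "D", "p",
                       "significant"],
    )


def chromosome_chisq(status: pd.Series, chrom: pd.Series):
    """Chi-square independence test of changing/stable status vs chromosome.

    ``status`` holds 'changing' / 'stable' per locus.  Returns
    ``(chi2, df, p, table, pearson_residuals)``; the signed residuals
    ``(O - E) / sqrt(E)`` support a mosaic-style report of which chromosomes
    are enriched or depleted in changing genes.
    """
    df = pd.DataFrame({"status": status, "chrom": chrom}).dropna()
    table = pd.crosstab(df["chrom"], df["status"])
    if table.shape[0] < 2:
        raise ValueError("need at least two chromosomes for the test")
    chi2, p, dof, expected = stats.chi2_contingency(
        table.to_numpy(), correction=False
    )
    resid = (table.to_numpy() - expected) / np.sqrt(expected)
    resid = pd.DataFrame(resid, index=table.index, columns=table.columns)
    return float(chi2), int(dof), float(p), table, resid


def overlap_enrichment(set_a: int, set_b: int, overlap: int, universe: int):
    """Expected overlap, fold enrichment, and hypergeometric P(X >= overlap).

    For two gene sets of sizes a and b drawn from a shared universe of N
    genes, the chance expectation is ``a*b/N``.
    """
    if not (0 <= overlap <= min(set_a, set_b) <= max(set_a, set_b) <= universe):
        raise ValueError(
            f"inconsistent counts: a={set_a}, b={set_b}, overlap={overlap}, "
            f"universe={universe}"
        )
    expected = set_a * set_b / universe
    fold = overlap / expected if expected > 0 else np.inf
    p = float(stats.hypergeom.sf(overlap - 1, universe, set_a, set_b))
    return float(expected), float(fold), p


@dataclass
class SpatialReport:
    clusters: list[Cluster]
    ks: pd.DataFrame
    chi2: float = np.nan
    chi2_df: int = 0
    chi2_p: float = np.nan
    chi2_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    chi2_residuals: pd.DataFrame = field(default_factory=pd.DataFrame)


def spatial_analysis(loci: pd.DataFrame, diff: pd.DataFrame,
                     fold_changes: pd.Series,
                     max_gap: int = CLUSTER_MAX_GAP,
                     min_size: int = CLUSTER_MIN_SIZE) -> SpatialReport:
    """Cluster tRNA genes and run the chromosome-level tests.

    ``diff`` is the differential-occupancy result frame (eligible / q
    columns); 'changing' = eligible with q < 0.05, 'stable' = eligible with
    q >= 0.05, below-cutoff loci are excluded from the chi-square table.
    """
    trna = loci[loci["locus_type"] == "tRNA"]
    clusters = call_clusters(trna, max_gap=max_gap, min_size=min_size)
    chrom_of = loci.set_index("locus_id")["chrom"]
    ks = cluster_ks_tests(
        fold_changes.reindex(trna["locus_id"]), clusters, chrom_of
    )
    report = SpatialReport(clusters=clusters, ks=ks)
    eligible = diff[diff["eligible"]]
    if len(eligible):
        status = pd.Series(
            np.where(eligible["q"] < 0.05, "changing", "stable"),
            index=eligible.index,
        )
        try:
            chi2, dof, p, table, resid = chromosome_chisq(
                status, chrom_of.reindex(status.index)
            )
        except ValueError:
            logger.info("chi-square skipped: fewer than two chromosomes")
        else:
            report.chi2, report.chi2_df, report.chi2_p = chi2, dof, p
            report.chi2_table, report.chi2_residuals = table, resid
    return report
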