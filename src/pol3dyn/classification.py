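"""Locus annotation and peak-presence classification.

Loci are annotated from coordinates alone (isolated: no other Pol III locus
within 1.5 kb; near-Pol II: within 2.65 kb of a Pol II TSS or poly-A site;
CpG: an island within 1 kb of the locus TSS) and, per replicate combination,
assigned to one of the eight groups defined by which of the RPC4 / H3K4me3 /
RPB2 occupancy scores exceed their empirical cutoffs.  Score distributions
between groups are compared with a permutation-based Welch t-test.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd

from .scoring import ScoreTable

#: Minimum edge-to-edge distance (bp) for a locus to count as isolated.
MIN_ISOLATION_GAP = 1500
#: Maximum distance (bp) from a locus to a Pol II TSS/poly-A to count as near.
MAX_POL2_DIST = 2650
#: Half-width (bp) of the TSS window searched for CpG islands.
CPG_WINDOW = 1000

#: Factor display order of the eight peak-presence groups.
GROUP_FACTOR_ORDER = ("RPC4", "H3K4me3", "RPB2")
GROUP_ORDER = (
    "RPC4+H3K4me3+RPB2", "RPC4+RPB2", "RPC4+H3K4me3", "H3K4me3+RPB2",
    "RPC4", "RPB2", "H3K4me3", "none",
)


def _pairwise_gap(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Edge-to-edge gap matrix; negative where intervals overlap."""
    return np.maximum(starts[None, :] - ends[:, None],
                      starts[:, None] - ends[None, :])


def flag_isolated(loci: pd.DataFrame, min_gap: int = MIN_ISOLATION_GAP
                  ) -> pd.Series:
    """True for loci at least ``min_gap`` bp (edge-to-edge) from every other
    locus; the boundary distance counts as isolated."""
    out = pd.Series(True, index=loci["locus_id"].values, dtype=bool)
    for _, sub in loci.groupby("chrom"):
        if len(sub) < 2:
            continue
        gaps = _pairwise_gap(sub["start"].to_numpy(dtype=np.int64),
                             sub["end"].to_numpy(dtype=np.int64))
        np.fill_diagonal(gaps, np.iinfo(np.int64).max)
        out[sub["locus_id"].values] = gaps.min(axis=1) >= min_gap
    return out


def _point_interval_dist(points, starts, ends):
    """points x intervals distance matrix (0 inside the half-open interval)."""
    d = np.maximum(starts[None, :] - points[:, None],
                   points[:, None] - (ends[None, :] - 1))
    return np.maximum(d, 0)


def flag_near_pol2(loci: pd.DataFrame, pol2: pd.DataFrame,
                   max_dist: int = MAX_POL2_DIST) -> pd.Series:
    """True where any Pol II feature point (TSS or poly-A) lies within
    ``max_dist`` bp of the locus body, boundary inclusive."""
    out = pd.Series(False, index=loci["locus_id"].values, dtype=bool)
    if len(pol2) == 0:
        return out
    for chrom, sub in loci.groupby("chrom"):
        pts = pol2.loc[pol2["chrom"] == chrom, "pos"].to_numpy(dtype=np.int64)
        if len(pts) == 0:
            continue
        d = _point_interval_dist(pts, sub["start"].to_numpy(dtype=np.int64),
                                 sub["end"].to_numpy(dtype=np.int64))
        out[sub["locus_id"].values] = d.min(axis=0) <= max_dist
    return out


def flag_cpg(loci: pd.DataFrame, cpg: pd.DataFrame,
             window: int = CPG_WINDOW) -> pd.Series:
    """True where a CpG island overlaps ``[tss - window, tss + window)``."""
    out = pd.Series(False, index=loci["locus_id"].values, dtype=bool)
    if len(cpg) == 0:
        return out
    for chrom, sub in loci.groupby("chrom"):
        isl = cpg[cpg["chrom"] == chrom]
        if len(isl) == 0:
            continue
        tss = sub["tss"].to_numpy(dtype=np.int64)
        lo, hi = tss - window, tss + window
        s = isl["start"].to_numpy(dtype=np.int64)
        e = isl["end"].to_numpy(dtype=np.int64)
        hit = (s[None, :] < hi[:, None]) & (e[None, :] > lo[:, None])
        out[sub["locus_id"].values] = hit.any(axis=1)
    return out


def group_label(present: set[str] | list[str]) -> str:
    present = [f for f in GROUP_FACTOR_ORDER if f in set(present)]
    return "+".join(present) if present else "none"


def assign_groups(table: ScoreTable,
                  replicate_map: dict[str, dict[str, str]]) -> pd.DataFrame:
    """Assign each locus its peak-presence group per replicate combination.

    ``replicate_map`` maps a combination name to ``{factor: sample_id}``
    (e.g. which H3K4me3 replicate is paired with RPC4/RPB2 replicate 1).
    Returns a locus x combination frame of group labels.
    """
    above = table.above_cutoff()
    out = {}
    for combo, fmap in replicate_map.items():
        for factor, sid in fmap.items():
            if sid not in above.columns:
                raise KeyError(
                    f"replicate combination {combo!r}: sample {sid!r} "
                    f"(factor {factor}) not present in the score table"
                )
        labels = []
        for lid in above.index:
            present = [f for f, sid in fmap.items() if above.at[lid, sid]]
            labels.append(group_label(present))
        out[combo] = labels
    return pd.DataFrame(out, index=above.index)


def summarize_groups(groups: pd.DataFrame, loci: pd.DataFrame,
                     subset: pd.Series | None = None) -> pd.DataFrame:
    """Counts and percentages per locus type and peak-presence group.

    ``subset`` (boolean per locus_id, e.g. the isolated flag) restricts the
    loci tallied; percentages are per locus-type row and replicate
    combination, as in the published grouping table.
    """
    ltype = loci.set_index("locus_id")["locus_type"]
    rows = []
    for combo in groups.columns:
        lab = groups[combo]
        if subset is not None:
            lab = lab[subset.reindex(lab.index).fillna(False).astype(bool)]
        for t in ltype.loc[lab.index].unique():
            sel = lab[ltype.loc[lab.index] == t]
            n_type = len(sel)
            for g in GROUP_ORDER:
                n = int((sel == g).sum())
                rows.append(
                    (combo, t, g, n,
                     100.0 * n / n_type if n_type else 0.0, n_type)
                )
    return pd.DataFrame(
        rows, columns=["combo", "locus_type", "group", "count", "pct",
                       "n_type"]
    )


def format_group_table(summary: pd.DataFrame) -> str:
    """Pretty text rendering of :func:`summarize_groups` output."""
    lines = []
    for combo, sub in summary.groupby("combo"):
        lines.append(f"[{combo}]")
        header = ["type (n)"] + list(GROUP_ORDER)
        lines.append("\t".join(header))
        for t, tsub in sub.groupby("locus_type"):
            tsub = tsub.set_index("group")
            n_type = int(tsub["n_type"].iloc[0])
            cells = [f"{t} ({n_type})"]
            cells += [
                f"{int(tsub.at[g, 'count'])} ({tsub.at[g, 'pct']:.1f}%)"
                for g in GROUP_ORDER
            ]
            lines.append("\t".join(cells))
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# permutation t-test
# ---------------------------------------------------------------------------

def _welch_t(x_mean, x_var, nx, y_mean, y_var, ny):
    denom = np.sqrt(x_var / nx + y_var / ny)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (x_mean - y_mean) / denom


def permutation_t_test(x, y, n_perm: int = 10_000, seed=None,
                       exhaustive: bool = False) -> float:
    """Two-sided permutation p-value for a difference in means (Welch t).

    Group labels are permuted; the p-value is
    ``(1 + #{permuted |t| >= observed |t|}) / (n_perm + 1)``.  With
    ``exhaustive=True`` all distinct splits are enumerated instead and the
    plain proportion is returned (small samples only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per group")
    if np.var(x) == 0 and np.var(y) == 0:
        warnings.warn("zero variance in both groups; permutation t-test "
                      "is degenerate, returning p=1")
        return 1.0
    nx, ny = len(x), len(y)
    t_obs = _welch_t(x.mean(), x.var(ddof=1), nx, y.mean(), y.var(ddof=1), ny)
    pooled = np.concatenate([x, y])

    if exhaustive:
        n_hits = 0
        n_splits = math.comb(nx + ny, nx)
        for comb in itertools.combinations(range(nx + ny), nx):
            mask = np.zeros(nx + ny, dtype=bool)
            mask[list(comb)] = True
            xs, ys = pooled[mask], pooled[~mask]
            t = _welch_t(xs.mean(), xs.var(ddof=1), nx,
                         ys.mean(), ys.var(ddof=1), ny)
            if not np.isfinite(t) or abs(t) >= abs(t_obs) - 1e-12:
                n_hits += 1
        return n_hits / n_splits

    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm, nx + ny)), axis=1)
    perm = pooled[idx]
    xs, ys = perm[:, :nx], perm[:, nx:]
    t = _welch_t(xs.mean(axis=1), xs.var(axis=1, ddof=1), nx,
                 ys.mean(axis=1), ys.var(axis=1, ddof=1), ny)
    hits = ~np.isfinite(t) | (np.abs(t) >= abs(t_obs) - 1e-12)
    return (1 + int(hits.sum())) / (n_perm + 1)
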