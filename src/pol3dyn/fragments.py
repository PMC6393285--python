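"""Fragment ingestion, redundancy filtering and multi-mapper weighting.

Paired-end ChIP-seq tag pairs resolve either to a unique genomic fragment or,
for tags matching repeated sequence, to several candidate fragments.  Unique
fragments carry weight 1; candidate fragments of a multi-mapped pair share one
unit of weight, split according to how probable each candidate's implied
insert size is under the empirical size distribution of the unique fragments.
Fragments sequenced more than once (identical coordinates) are collapsed to a
single record before any counting.

Fragments are held in a :class:`pandas.DataFrame` with columns
``chrom, start, end, weight, pair_id`` (0-based half-open coordinates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FRAGMENT_COLUMNS = ["chrom", "start", "end", "weight", "pair_id"]

#: Alignment-style cap on candidate positions per tag pair; pairs with more
#: candidates are discarded outright.
MAX_MATCHES = 500

#: Probability floor applied to the empirical size histogram so unseen sizes
#: never receive exactly zero weight.
SIZE_PROB_FLOOR = 1e-6


def _as_frame(frags) -> pd.DataFrame:
    if isinstance(frags, pd.DataFrame):
        return frags
    return pd.DataFrame(list(frags), columns=FRAGMENT_COLUMNS)


def read_fragment_bed(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a 6-column fragment BED (name=pair id, score=weight)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3, 4],
        names=["chrom", "start", "end", "pair_id", "weight"],
        dtype={"chrom": str},
    )
    df = df[FRAGMENT_COLUMNS]
    if sample_id is not None:
        df["sample_id"] = sample_id
    return df


def write_fragment_bed(frags: pd.DataFrame, path) -> None:
    """Write fragments as BED6 (chrom, start, end, pair_id, weight, strand='.')."""
    out = _as_frame(frags)
    bed = pd.DataFrame(
        {
            "chrom": out["chrom"],
            "start": out["start"].astype(int),
            "end": out["end"].astype(int),
            "name": out["pair_id"],
            "score": out["weight"],
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def dedup_fragments(frags) -> pd.DataFrame:
    """Collapse fragments with identical ``(chrom, start, end)`` to one record.

    The result is canonically sorted by chromosome, start, end, making the
    operation independent of input order.  Weights of collapsed duplicates are
    not summed: a fragment sequenced more than once still counts once.
    """
    df = _as_frame(frags)
    if df.empty:
        return df.copy()
    out = (
        df.drop_duplicates(subset=["chrom", "start", "end"], keep="first")
        .sort_values(["chrom", "start", "end"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


@dataclass
class SizeDistribution:
    """Empirical fragment-size probabilities at 1-bp resolution.

    ``probs[size]`` is the floored, renormalized relative frequency of that
    fragment length among unique fragments; lengths never observed fall back
    to ``floor_prob`` (the floored probability mass of an unseen size).
    """

    probs: dict[int, float] = field(repr=False)
    floor_prob: float = SIZE_PROB_FLOOR

    def prob(self, size) -> np.ndarray | float:
        """Probability of one size or an array of sizes."""
        if np.isscalar(size):
            return self.probs.get(int(size), self.floor_prob)
        sizes = np.asarray(size)
        return np.array([self.probs.get(int(s), self.floor_prob) for s in sizes])


def estimate_size_distribution(
    unique_frags, floor: float = SIZE_PROB_FLOOR
) -> SizeDistribution:
    """Empirical size-probability distribution of unique fragments.

    Relative frequencies at 1-bp resolution are floored at ``floor`` and
    renormalized so probabilities still sum to 1 over observed sizes.
    """
    df = _as_frame(unique_frags)
    if df.empty:
        raise ValueError("cannot estimate a size distribution from zero fragments")
    lengths = (df["end"] - df["start"]).to_numpy()
    sizes, counts = np.unique(lengths, return_counts=True)
    freq = counts / counts.sum()
    freq = np.maximum(freq, floor)
    freq = freq / freq.sum()
    return SizeDistribution(
        probs={int(s): float(f) for s, f in zip(sizes, freq)}, floor_prob=floor
    )


def weight_multimapped(
    candidates, dist: SizeDistribution, max_matches: int = MAX_MATCHES
) -> pd.DataFrame:
    """Weight the candidate fragments of one multi-mapped tag pair.

    Candidate *i* receives weight ``P(len_i) / sum_j P(len_j)`` so the pair
    contributes one unit of fragment mass in total.  Pairs with more than
    ``max_matches`` candidates are discarded (empty result), mirroring the
    cap applied at alignment time.
    """
    df = _as_frame(candidates)
    if df.empty:
        return df.copy()
    if df["pair_id"].nunique() != 1:
        raise ValueError("candidates must all belong to a single tag pair")
    if len(df) > max_matches:
        logger.info(
            "discarding pair %s with %d candidate fragments (> %d)",
            df["pair_id"].iloc[0],
            len(df),
            max_matches,
        )
        return df.iloc[0:0].copy()
    p = np.asarray(dist.prob((df["end"] - df["start"]).to_numpy()), dtype=float)
    out = df.copy()
    out["weight"] = p / p.sum()
    return out


def weight_multimapped_batch(
    multi: pd.DataFrame, dist: SizeDistribution, max_matches: int = MAX_MATCHES
) -> pd.DataFrame:
    """Vectorized :func:`weight_multimapped` over many pairs at once."""
    if multi.empty:
        return multi.copy()
    df = multi.copy()
    sizes = df["pair_id"].map(df["pair_id"].value_counts())
    dropped = int((sizes > max_matches).sum())
    if dropped:
        logger.info("discarding %d candidate rows from oversized pairs", dropped)
    df = df[sizes <= max_matches].copy()
    if df.empty:
        return df
    p = np.asarray(dist.prob((df["end"] - df["start"]).to_numpy()), dtype=float)
    df["weight"] = p
    df["weight"] = df["weight"] / df.groupby("pair_id")["weight"].transform("sum")
    return df.reset_index(drop=True)


def process_sample(frags: pd.DataFrame, max_matches: int = MAX_MATCHES) -> pd.DataFrame:
    """Full per-sample fragment preprocessing.

    Unique pairs (one candidate) are deduplicated first; the size distribution
    is estimated from them; multi-mapped pairs are then weighted by size
    probability, and any multi-candidate fragment duplicating a unique
    fragment's coordinates is dropped.
    """
    df = _as_frame(frags)
    if df.empty:
        return df.copy()
    n_cand = df["pair_id"].map(df["pair_id"].value_counts())
    uniq = dedup_fragments(df[n_cand == 1])
    uniq = uniq.assign(weight=1.0)
    multi = df[n_cand > 1]
    if multi.empty:
        return uniq.reset_index(drop=True)
    dist = estimate_size_distribution(uniq)
    weighted = weight_multimapped_batch(multi, dist, max_matches=max_matches)
    if not weighted.empty:
        key = pd.MultiIndex.from_frame(weighted[["chrom", "start", "end"]])
        seen = pd.MultiIndex.from_frame(uniq[["chrom", "start", "end"]])
        weighted = weighted[~key.isin(seen)]
    out = pd.concat([uniq, weighted], ignore_index=True)
    return out.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def total_fragment_mass(frags: pd.DataFrame) -> float:
    """Total weighted fragment mass of a processed sample."""
    return float(_as_frame(frags)["weight"].sum())
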