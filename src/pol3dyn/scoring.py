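"""Occupancy scores over extended loci and empirical-null peak thresholds.

The occupancy score of a locus in one ChIP/Input sample pair is

    score = log2((norm_chip + c) / (norm_input + c)),    c = 16,

where the counts are weighted fractional fragment counts in an extended locus
window (the annotated RNA-coding region +/-150 bp for Pol III ChIP, or +/-1 kb
around the locus TSS for H3K4me3 / Pol II ChIP), normalized so every sample
has the median sequencing depth.  A locus "has a peak" when its score exceeds
a per-sample threshold derived from the empirical distribution of the same
score computed in non-overlapping genome bins, taken at the Bonferroni-
corrected quantile ``1 - alpha / n_loci``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Pseudocount added to both normalized counts before the log-ratio.
PSEUDOCOUNT = 16.0
#: Locus body extension (bp each side) for Pol III occupancy windows.
EXTEND_POL3 = 150
#: Half-width (bp) of the TSS-centered window for H3K4me3 / Pol II scores.
EXTEND_TSS = 1000
#: Null-distribution bin size (bp) per ChIP factor.
BIN_SIZE = {"RPC4": 400, "RPB2": 2000, "H3K4me3": 2000}
#: Window mode per ChIP factor.
WINDOW_MODE = {"RPC4": "pol3", "RPB2": "tss_window", "H3K4me3": "tss_window"}
#: Family-wise error rate for the Bonferroni-corrected null quantile.
ALPHA = 0.05


# ---------------------------------------------------------------------------
# normalization and the score itself
# ---------------------------------------------------------------------------

def normalization_factors(totals: dict[str, float]) -> dict[str, float]:
    """Depth-normalization factor per sample: median(totals) / total_s.

    Multiplying a sample's counts by its factor brings every sample to the
    median genome-wide fragment mass across all samples.
    """
    vals = np.array(list(totals.values()), dtype=float)
    if len(vals) == 0:
        raise ValueError("no samples")
    if np.any(vals <= 0):
        bad = [s for s, t in totals.items() if t <= 0]
        raise ValueError(f"non-positive fragment totals for samples: {bad}")
    med = float(np.median(vals))
    return {s: med / float(t) for s, t in totals.items()}


def compute_score(
    chip_count: float,
    input_count: float,
    chip_factor: float = 1.0,
    input_factor: float = 1.0,
    pseudocount: float = PSEUDOCOUNT,
):
    """Pseudocounted log2 ChIP/Input ratio (vectorized over array inputs)."""
    chip = np.asarray(chip_count, dtype=float) * chip_factor + pseudocount
    inp = np.asarray(input_count, dtype=float) * input_factor + pseudocount
    out = np.log2(chip / inp)
    return out if out.ndim else float(out)


def extend_locus(locus, mode: str, chrom_size: int | None = None) -> tuple[int, int]:
    """Extended scoring window of a locus, clipped to chromosome bounds.

    ``mode='pol3'`` pads the annotated body by 150 bp each side;
    ``mode='tss_window'`` is +/-1000 bp around the strand-aware TSS.
    """
    if mode == "pol3":
        start, end = int(locus["start"]) - EXTEND_POL3, int(locus["end"]) + EXTEND_POL3
    elif mode == "tss_window":
        tss = int(locus["tss"])
        start, end = tss - EXTEND_TSS, tss + EXTEND_TSS
    else:
        raise ValueError(f"unknown extension mode {mode!r}")
    start = max(start, 0)
    if chrom_size is not None:
        end = min(end, int(chrom_size))
    return start, end


def count_fragments(frags, interval) -> float:
    """Fractional weighted fragment count in one interval.

    Each fragment contributes ``weight * overlap / fragment_length``: a
    fragment fully inside the interval is worth its whole weight, a fragment
    half inside is worth half of it.
    """
    chrom, start, end = interval
    df = frags if isinstance(frags, pd.DataFrame) else pd.DataFrame(
        list(frags), columns=["chrom", "start", "end", "weight", "pair_id"]
    )
    sub = df[df["chrom"] == chrom]
    if sub.empty:
        return 0.0
    s = sub["start"].to_numpy(dtype=float)
    e = sub["end"].to_numpy(dtype=float)
    w = sub["weight"].to_numpy(dtype=float)
    overlap = np.clip(np.minimum(e, end) - np.maximum(s, start), 0.0, None)
    return float(np.sum(w * overlap / (e - s)))


# ---------------------------------------------------------------------------
# prefix-sum coverage index (exact fractional counting at scale)
# ---------------------------------------------------------------------------

class CoverageIndex:
    """Per-base fragment density with prefix sums for O(1) interval queries.

    With ``fractional=True`` the per-base density is ``sum(weight / length)``
    over covering fragments, so an interval sum equals the fractional count
    of :func:`count_fragments` exactly (integer coordinates).  With
    ``fractional=False`` the density is plain weighted coverage
    (``sum(weight)``), as used for tag-density profiles.
    """

    def __init__(self, frags: pd.DataFrame, chrom_sizes: dict[str, int],
                 fractional: bool = True):
        self.chrom_sizes = dict(chrom_sizes)
        self.total_mass = float(frags["weight"].sum()) if len(frags) else 0.0
        self._prefix: dict[str, np.ndarray] = {}
        groups = dict(tuple(frags.groupby("chrom", observed=True))) if len(frags) else {}
        for chrom, size in self.chrom_sizes.items():
            size = int(size)
            delta = np.zeros(size + 1)
            sub = groups.get(chrom)
            if sub is not None and len(sub):
                s = np.clip(sub["start"].to_numpy(dtype=np.int64), 0, size)
                e = np.clip(sub["end"].to_numpy(dtype=np.int64), 0, size)
                w = sub["weight"].to_numpy(dtype=float)
                if fractional:
                    w = w / (sub["end"].to_numpy(dtype=float)
                             - sub["start"].to_numpy(dtype=float))
                delta = (np.bincount(s, weights=w, minlength=size + 1)
                         - np.bincount(e, weights=w, minlength=size + 1))
            density = np.cumsum(delta)[:-1]
            self._prefix[chrom] = np.concatenate(([0.0], np.cumsum(density)))

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        p = self._prefix[chrom]
        size = self.chrom_sizes[chrom]
        start = min(max(int(start), 0), size)
        end = min(max(int(end), 0), size)
        if end <= start:
            return 0.0
        return float(p[end] - p[start])

    def density(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base density over ``[start, end)`` (zero-padded off-chromosome)."""
        p = self._prefix[chrom]
        size = self.chrom_sizes[chrom]
        out = np.zeros(int(end) - int(start))
        lo, hi = max(int(start), 0), min(int(end), size)
        if hi > lo:
            out[lo - int(start): hi - int(start)] = np.diff(p[lo: hi + 1])
        return out

    def bin_sums(self, bin_size: int) -> tuple[pd.DataFrame, np.ndarray]:
        """Sums over non-overlapping genome tiles of ``bin_size`` bp.

        Returns (bin table with chrom/start/end, per-bin sums); the last bin
        of each chromosome may be shorter.
        """
        rows, sums = [], []
        for chrom in sorted(self.chrom_sizes):
            size = int(self.chrom_sizes[chrom])
            p = self._prefix[chrom]
            edges = np.arange(0, size + bin_size, bin_size)
            edges[-1] = size
            if edges[-1] == edges[-2]:
                edges = edges[:-1]
            vals = np.diff(p[edges])
            for i in range(len(vals)):
                rows.append((chrom, int(edges[i]), int(edges[i + 1])))
            sums.append(vals)
        bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return bins, np.concatenate(sums) if sums else np.array([])


def count_fragments_indexed(cov: CoverageIndex, intervals) -> np.ndarray:
    """Fractional counts for many ``(chrom, start, end)`` intervals."""
    return np.array([cov.interval_sum(c, s, e) for c, s, e in intervals])


# ---------------------------------------------------------------------------
# empirical-null threshold
# ---------------------------------------------------------------------------

def _mask_bins(bins: pd.DataFrame, mask: pd.DataFrame) -> np.ndarray:
    """Boolean: bin overlaps any mask interval."""
    hit = np.zeros(len(bins), dtype=bool)
    for chrom, sub in mask.groupby("chrom"):
        sel = bins["chrom"] == chrom
        if not sel.any():
            continue
        bs = bins.loc[sel, "start"].to_numpy()
        be = bins.loc[sel, "end"].to_numpy()
        ms = sub["start"].to_numpy()
        me = sub["end"].to_numpy()
        ov = (bs[:, None] < me[None, :]) & (be[:, None] > ms[None, :])
        hit[np.flatnonzero(sel.to_numpy())] = ov.any(axis=1)
    return hit


def bin_scores(
    chip_cov: CoverageIndex,
    input_cov: CoverageIndex,
    bin_size: int,
    chip_factor: float = 1.0,
    input_factor: float = 1.0,
    pseudocount: float = PSEUDOCOUNT,
    mask: pd.DataFrame | None = None,
) -> np.ndarray:
    """Occupancy scores of non-overlapping genome bins (empirical null)."""
    bins, chip = chip_cov.bin_sums(bin_size)
    _, inp = input_cov.bin_sums(bin_size)
    scores = compute_score(chip, inp, chip_factor, input_factor, pseudocount)
    if mask is not None and len(mask):
        scores = scores[~_mask_bins(bins, mask)]
    return np.asarray(scores)


def empirical_threshold(scores: np.ndarray, n_loci: int,
                        alpha: float = ALPHA) -> float:
    """Bonferroni-corrected empirical quantile of a null score sample.

    Linear-interpolation quantile at level ``1 - alpha / n_loci``; a
    degenerate level <= 0 returns the minimum score; too few observations to
    resolve the level raise a ValueError.
    """
    scores = np.asarray(scores, dtype=float)
    level = 1.0 - alpha / n_loci
    if level <= 0.0:
        return float(scores.min())
    needed = int(np.ceil(n_loci / alpha))
    if len(scores) < needed:
        raise ValueError(
            f"only {len(scores)} genome bins for quantile level {level:.6g}; "
            f"need >= {needed} — use a larger genome, larger alpha, or fewer loci"
        )
    return float(np.quantile(scores, level, method="linear"))


def null_threshold(
    chip,
    input_,
    chrom_sizes: dict[str, int] | None = None,
    bin_size: int = 400,
    n_loci: int = 1,
    alpha: float = ALPHA,
    chip_factor: float = 1.0,
    input_factor: float = 1.0,
    pseudocount: float = PSEUDOCOUNT,
    mask: pd.DataFrame | None = None,
) -> float:
    """Bonferroni-corrected empirical score threshold for one ChIP/Input pair.

    The threshold is the linear-interpolation empirical quantile of the
    genome-bin score distribution at level ``1 - alpha / n_loci``; a locus
    whose score exceeds it is called peak-positive for that sample.  ``chip``
    and ``input_`` may be fragment frames (then ``chrom_sizes`` is required)
    or pre-built :class:`CoverageIndex` objects.  ``mask`` intervals remove
    bins known to carry true signal from the null (recommended whenever
    annotated loci occupy a non-negligible share of the genome).
    """
    if not isinstance(chip, CoverageIndex):
        chip = CoverageIndex(chip, chrom_sizes)
    if not isinstance(input_, CoverageIndex):
        input_ = CoverageIndex(input_, chrom_sizes)
    scores = bin_scores(
        chip, input_, bin_size, chip_factor, input_factor, pseudocount, mask
    )
    return empirical_threshold(scores, n_loci, alpha)


# ---------------------------------------------------------------------------
# the loci x samples score table
# ---------------------------------------------------------------------------

@dataclass
class ScoreTable:
    """Loci x ChIP-sample occupancy scores with per-sample null thresholds.

    ``chip_counts`` / ``input_counts`` are raw weighted fractional counts in
    the factor-specific extended windows (before depth normalization), so a
    score is reproducible as ``compute_score(chip, input, f_chip, f_input)``.
    """

    loci: pd.DataFrame
    chip_counts: pd.DataFrame
    input_counts: pd.DataFrame
    scores: pd.DataFrame
    thresholds: pd.Series
    norm_factors: pd.Series
    sample_sheet: pd.DataFrame
    pseudocount: float = PSEUDOCOUNT

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def above_cutoff(self) -> pd.DataFrame:
        """Boolean peak-presence matrix (score strictly above threshold)."""
        return self.scores.gt(self.thresholds, axis=1)

    def to_tsv(self, path) -> None:
        out = self.loci[["locus_id", "locus_type"]].copy().set_index("locus_id")
        for s in self.scores.columns:
            out[f"chip_count:{s}"] = self.chip_counts[s]
            out[f"input_count:{s}"] = self.input_counts[s]
            out[f"score:{s}"] = self.scores[s]
        with open(path, "w") as fh:
            for s, t in self.thresholds.items():
                fh.write(f"# threshold\t{s}\t{t:.6g}\n")
            for s, f in self.norm_factors.items():
                fh.write(f"# norm_factor\t{s}\t{f:.6g}\n")
            out.to_csv(fh, sep="\t", float_format="%.6g")


def build_score_table(
    frags_by_sample: dict[str, pd.DataFrame],
    sample_sheet: pd.DataFrame,
    loci: pd.DataFrame,
    chrom_sizes: dict[str, int],
    alpha: float = ALPHA,
    pseudocount: float = PSEUDOCOUNT,
    bin_sizes: dict[str, int] | None = None,
    mask_loci: bool = True,
) -> ScoreTable:
    """Score every ChIP sample of a sample sheet against its paired input.

    ``sample_sheet`` needs columns ``sample_id, factor, timepoint, replicate,
    input_id`` (``input_id`` empty/NaN for Input samples).  ``loci`` needs
    ``locus_id, chrom, start, end, strand, locus_type, tss``.
    """
    bin_sizes = dict(BIN_SIZE, **(bin_sizes or {}))
    totals = {s: float(df["weight"].sum()) for s, df in frags_by_sample.items()}
    factors = normalization_factors(totals)

    chip_rows = sample_sheet[sample_sheet["factor"] != "Input"]
    for _, row in chip_rows.iterrows():
        if row["input_id"] not in frags_by_sample:
            raise ValueError(
                f"sample {row['sample_id']}: paired input {row['input_id']!r} missing"
            )

    cov_cache: dict[str, CoverageIndex] = {}
    input_uses = chip_rows["input_id"].value_counts().to_dict()

    def cov(sample_id: str) -> CoverageIndex:
        if sample_id not in cov_cache:
            cov_cache[sample_id] = CoverageIndex(
                frags_by_sample[sample_id], chrom_sizes
            )
        return cov_cache[sample_id]

    n_loci = len(loci)
    windows_by_mode: dict[str, list[tuple[str, int, int]]] = {}
    for mode in ("pol3", "tss_window"):
        windows_by_mode[mode] = [
            (row["chrom"], *extend_locus(row, mode, chrom_sizes[row["chrom"]]))
            for _, row in loci.iterrows()
        ]

    idx = loci["locus_id"]
    chip_counts, input_counts, scores, thresholds = {}, {}, {}, {}
    for _, row in chip_rows.iterrows():
        sid, factor, iid = row["sample_id"], row["factor"], row["input_id"]
        mode = WINDOW_MODE[factor]
        wins = windows_by_mode[mode]
        c_cov, i_cov = cov(sid), cov(iid)
        chip_counts[sid] = count_fragments_indexed(c_cov, wins)
        input_counts[sid] = count_fragments_indexed(i_cov, wins)
        scores[sid] = compute_score(
            chip_counts[sid], input_counts[sid], factors[sid], factors[iid],
            pseudocount,
        )
        mask = None
        if mask_loci and n_loci:
            mask = pd.DataFrame(wins, columns=["chrom", "start", "end"])
        thresholds[sid] = null_threshold(
            c_cov,
            i_cov,
            bin_size=bin_sizes[factor],
            n_loci=max(n_loci, 1),
            alpha=alpha,
            chip_factor=factors[sid],
            input_factor=factors[iid],
            pseudocount=pseudocount,
            mask=mask,
        )
        # keep shared input indexes only while other ChIPs still need them
        cov_cache.pop(sid, None)
        input_uses[iid] -= 1
        if input_uses[iid] == 0:
            cov_cache.pop(iid, None)

    order = list(chip_rows["sample_id"])
    return ScoreTable(
        loci=loci.reset_index(drop=True),
        chip_counts=pd.DataFrame(chip_counts, index=idx.values)[order],
        input_counts=pd.DataFrame(input_counts, index=idx.values)[order],
        scores=pd.DataFrame(scores, index=idx.values)[order],
        thresholds=pd.Series(thresholds)[order],
        norm_factors=pd.Series(factors),
        sample_sheet=sample_sheet.reset_index(drop=True),
        pseudocount=pseudocount,
    )
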