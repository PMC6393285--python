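"""Synthetic miniature genome and ChIP/Input fragment simulator.

The generator emulates the statistical structure of a Pol III occupancy
time-course experiment in regenerating liver: a compact multi-chromosome
genome carrying Pol III loci of the usual types (tRNA, SINE, Rn5s, Rn4.5s,
other), a set of Pol II genes whose TSSs sit just upstream of part of the
Pol III loci, CpG islands at a subset of those TSSs, and paired-end ChIP /
Input fragment sets for four time points with two replicates each.

Loci fall into three ground-truth classes:

``stable_high``
    high Pol III occupancy, constant across time; a configurable fraction
    sits within 2.65 kb of a Pol II TSS and carries H3K4me3 and Pol II
    (RPB2) signal there.
``dynamic_low``
    low occupancy at TP0, induced by ``induction_log2fc`` log2 units at TP36
    and staying at the induced level at TP48/TP60; no nearby Pol II signal.
``silent``
    no enrichment at any time point.

Fragment counts follow a Poisson model on top of a uniform background whose
expected fractional count in any window of width ``w`` equals
``depth * w / genome``; locus-centred signal fragments are added so that the
expected ChIP/Input ratio in the scoring window is ``2**enrichment``, with
multiplicative lognormal replicate noise of the configured CV.  A fraction of
tag pairs is emitted as multi-candidate records (true origin plus uniform
decoys with a broader size distribution) to exercise size-probability
weighting.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIMEPOINTS = ("TP0", "TP36", "TP48", "TP60")

#: Locus body length range (bp) drawn per type.
LOCUS_LENGTH_RANGE = {
    "tRNA": (70, 95),
    "SINE": (120, 300),
    "Rn5s": (115, 125),
    "Rn4.5s": (95, 105),
    "other": (100, 300),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment (defaults = study conditions)."""

    genome_length: int = 1_900_000          # bp per chromosome
    n_chromosomes: int = 5
    n_loci_by_type: dict[str, int] = field(
        default_factory=lambda: {"tRNA": 110, "SINE": 55, "Rn5s": 15,
                                 "Rn4.5s": 6, "other": 14}
    )
    frac_near_pol2: float = 0.8             # of stable_high loci
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {"stable_high": 0.4, "dynamic_low": 0.3,
                                 "silent": 0.3}
    )
    base_enrichment: dict[str, float] = field(
        default_factory=lambda: {"stable_high": 4.0, "dynamic_low": 1.0,
                                 "silent": 0.0}
    )
    induction_log2fc: float = 2.0           # dynamic_low, TP36 vs TP0
    locus_effect_sd: dict[str, float] = field(
        default_factory=lambda: {"stable_high": 0.6, "dynamic_low": 0.3}
    )                                        # static per-locus spread (log2)
    depth_per_sample: int = 950_000         # expected fragments per sample
    replicate_cv: float = 0.1               # lognormal CV on locus rates
    frag_size_mean: float = 200.0
    frag_size_sd: float = 40.0
    multimap_fraction: float = 0.05         # of tag pairs
    seed: int = 0
    # --- structural knobs beyond the headline parameters ---
    min_locus_gap: int = 200                # bp between placed loci
    n_trna_clusters: int = 6                # tRNA runs of >=3 genes, <5 kb gaps
    trna_cluster_size: int = 3
    cluster_gap_range: tuple[int, int] = (500, 4000)
    pol2_offset_range: tuple[int, int] = (200, 800)   # TSS upstream of locus TSS
    pol2_gene_length_range: tuple[int, int] = (2000, 10000)
    n_background_pol2: int = 30             # unrelated Pol II genes, genome-wide
    pol2_enrichment: dict[str, float] = field(
        default_factory=lambda: {"H3K4me3": 3.0, "RPB2": 3.0}
    )
    cpg_fraction: float = 0.7               # Pol II TSSs carrying a CpG island
    cpg_width_range: tuple[int, int] = (500, 1500)
    multimap_candidates: int = 3            # candidates per multi-mapped pair
    n_replicates: int = 2
    timepoints: tuple[str, ...] = TIMEPOINTS

    def validate(self) -> None:
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if any(v < 0 for v in self.n_loci_by_type.values()):
            raise ValueError("locus counts must be non-negative")
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome dimensions must be positive")
        if self.depth_per_sample <= 0:
            raise ValueError("depth_per_sample must be positive")
        if not 0 <= self.frac_near_pol2 <= 1:
            raise ValueError("frac_near_pol2 must be in [0, 1]")
        if not 0 <= self.multimap_fraction < 1:
            raise ValueError("multimap_fraction must be in [0, 1)")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.genome_length
                for i in range(self.n_chromosomes)}

    @property
    def genome_size(self) -> int:
        return self.genome_length * self.n_chromosomes


def _sample_rng(cfg: SimConfig, sample_id: str) -> np.random.Generator:
    """Deterministic per-sample substream of the experiment seed."""
    key = zlib.crc32(sample_id.encode())
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, key]))


def _largest_remainder(n: int, fractions: dict[str, float]) -> dict[str, int]:
    keys = list(fractions)
    raw = np.array([fractions[k] * n for k in keys])
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(keys, base))


def _truncated_normal_sizes(rng, n, mean, sd, lo=1) -> np.ndarray:
    sizes = np.round(rng.normal(mean, sd, n)).astype(np.int64)
    while np.any(sizes < lo):
        bad = sizes < lo
        sizes[bad] = np.round(rng.normal(mean, sd, bad.sum())).astype(np.int64)
    return sizes


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _point_to_interval_distance(pos, start, end):
    """Distance from point(s) to a 0-based half-open interval (0 if inside)."""
    pos = np.asarray(pos)
    d = np.maximum(start - pos, pos - (end - 1))
    return np.maximum(d, 0)


def simulate_annotation(cfg: SimConfig):
    """Generate loci, Pol II features, CpG islands and per-locus ground truth.

    Returns ``(loci, pol2, cpg, truth)`` as DataFrames.  ``truth`` carries
    one row per locus with the class label, the realized near-Pol II flag,
    the true log2 enrichment per time point, and the anchor positions at
    which H3K4me3 / RPB2 signal is planted (NaN where there is none).
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA0]))
    total = int(sum(cfg.n_loci_by_type.values()))
    empty_loci = pd.DataFrame(
        columns=["locus_id", "chrom", "start", "end", "strand", "locus_type", "tss"]
    )
    if total == 0:
        pol2 = pd.DataFrame(columns=["gene_id", "chrom", "pos", "kind", "strand"])
        cpg = pd.DataFrame(columns=["chrom", "start", "end"])
        truth = pd.DataFrame(
            columns=["locus_id", "class_label", "near_pol2",
                     *cfg.timepoints, "h3k4me3_anchor", "rpb2_anchor"]
        )
        return empty_loci, pol2, cpg, truth

    # per-locus static attributes ------------------------------------------
    types = np.concatenate(
        [[t] * n for t, n in cfg.n_loci_by_type.items() if n > 0]
    )
    lengths = np.array(
        [rng.integers(*LOCUS_LENGTH_RANGE.get(t, (100, 300))) for t in types]
    )
    strands = rng.choice(["+", "-"], size=total)
    class_counts = _largest_remainder(total, cfg.class_fractions)
    labels = np.concatenate([[c] * n for c, n in class_counts.items()])
    labels = labels[rng.permutation(total)]

    stable_idx = np.flatnonzero(labels == "stable_high")
    n_near = int(round(cfg.frac_near_pol2 * len(stable_idx)))
    near_intent = np.zeros(total, dtype=bool)
    near_intent[rng.permutation(stable_idx)[:n_near]] = True

    # group tRNA loci into cluster units and singletons ---------------------
    trna_idx = np.flatnonzero(types == "tRNA")
    trna_idx = trna_idx[rng.permutation(len(trna_idx))]
    units: list[list[int]] = []
    k = cfg.trna_cluster_size
    n_clustered = min(cfg.n_trna_clusters * k, len(trna_idx)) if k >= 1 else 0
    for c in range(n_clustered // k):
        units.append(list(trna_idx[c * k: (c + 1) * k]))
    clustered = set(trna_idx[: (n_clustered // k) * k])
    units.extend([[i] for i in range(total) if i not in clustered])

    # place units on chromosomes -------------------------------------------
    pad = max(int(cfg.min_locus_gap), 1)
    chroms = sorted(cfg.chrom_sizes)
    for attempt in range(100):
        assignment = rng.integers(0, len(chroms), size=len(units))
        unit_gaps = [
            rng.integers(*cfg.cluster_gap_range, size=max(len(u) - 1, 0))
            for u in units
        ]
        unit_lengths = [
            int(lengths[u].sum() + g.sum()) for u, g in zip(units, unit_gaps)
        ]
        ok = True
        for ci in range(len(chroms)):
            sel = np.flatnonzero(assignment == ci)
            need = sum(unit_lengths[i] for i in sel) + (len(sel) + 1) * pad
            if need > cfg.genome_length:
                ok = False
                break
        if ok:
            break
    else:
        raise ValueError(
            "could not place loci: total locus span plus minimum gaps exceeds "
            "the genome — increase genome_length or reduce locus counts"
        )

    starts = np.zeros(total, dtype=np.int64)
    chrom_of = np.empty(total, dtype=object)
    for ci, chrom in enumerate(chroms):
        sel = list(np.flatnonzero(assignment == ci))
        rng.shuffle(sel)
        if not sel:
            continue
        span = sum(unit_lengths[i] for i in sel)
        free = cfg.genome_length - span - (len(sel) + 1) * pad
        offsets = np.sort(rng.random(len(sel)) * free)
        cursor_extra = 0
        for j, ui in enumerate(sel):
            ustart = int(offsets[j]) + (j + 1) * pad + cursor_extra
            pos = ustart
            for m, li in enumerate(units[ui]):
                starts[li] = pos
                chrom_of[li] = chrom
                pos += int(lengths[li])
                if m < len(units[ui]) - 1:
                    pos += int(unit_gaps[ui][m])
            cursor_extra += unit_lengths[ui]

    ends = starts + lengths
    tss = np.where(strands == "+", starts, ends)

    counters: dict[str, int] = {}
    ids = []
    for t in types:
        counters[t] = counters.get(t, 0) + 1
        ids.append(f"{t}_{counters[t]:04d}")
    loci = pd.DataFrame(
        {"locus_id": ids, "chrom": chrom_of, "start": starts, "end": ends,
         "strand": strands, "locus_type": types, "tss": tss}
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    order = {lid: i for i, lid in enumerate(ids)}

    # Pol II genes ----------------------------------------------------------
    pol2_rows = []
    h3k_anchor = np.full(total, np.nan)
    rpb2_anchor = np.full(total, np.nan)
    gene_n = 0
    for i in np.flatnonzero(near_intent):
        d = int(rng.integers(*cfg.pol2_offset_range))
        glen = int(rng.integers(*cfg.pol2_gene_length_range))
        if strands[i] == "+":
            p_tss = int(tss[i]) - d
            p_polya = max(p_tss - glen, 0)
            p_strand = "-"
        else:
            p_tss = int(tss[i]) + d
            p_polya = min(p_tss + glen, cfg.genome_length - 1)
            p_strand = "+"
        p_tss = int(np.clip(p_tss, 0, cfg.genome_length - 1))
        gene_n += 1
        gid = f"pol2g_{gene_n:04d}"
        pol2_rows.append((gid, chrom_of[i], p_tss, "tss", p_strand))
        pol2_rows.append((gid, chrom_of[i], p_polya, "polyA", p_strand))
        h3k_anchor[i] = p_tss
        rpb2_anchor[i] = p_tss

    # stable loci away from Pol II still get an H3K4me3 flank peak
    for i in stable_idx:
        if not near_intent[i]:
            d = int(rng.integers(*cfg.pol2_offset_range))
            a = tss[i] - d if strands[i] == "+" else tss[i] + d
            h3k_anchor[i] = float(np.clip(a, 0, cfg.genome_length - 1))

    # background Pol II genes, kept clear of all loci
    margin = 2650 + 500
    for b in range(cfg.n_background_pol2):
        for _ in range(200):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            p_tss = int(rng.integers(0, cfg.genome_length))
            sel = loci["chrom"] == chrom
            if sel.any():
                dmin = _point_to_interval_distance(
                    p_tss,
                    loci.loc[sel, "start"].to_numpy(),
                    loci.loc[sel, "end"].to_numpy(),
                ).min()
                if dmin <= margin:
                    continue
            glen = int(rng.integers(*cfg.pol2_gene_length_range))
            p_strand = "+" if rng.random() < 0.5 else "-"
            p_polya = p_tss + glen if p_strand == "+" else p_tss - glen
            p_polya = int(np.clip(p_polya, 0, cfg.genome_length - 1))
            gene_n += 1
            gid = f"pol2g_{gene_n:04d}"
            pol2_rows.append((gid, chrom, p_tss, "tss", p_strand))
            pol2_rows.append((gid, chrom, p_polya, "polyA", p_strand))
            break
    pol2 = pd.DataFrame(
        pol2_rows, columns=["gene_id", "chrom", "pos", "kind", "strand"]
    )

    # CpG islands at a subset of Pol II TSSs --------------------------------
    cpg_rows = []
    for _, row in pol2[pol2["kind"] == "tss"].iterrows():
        if rng.random() < cfg.cpg_fraction:
            w = int(rng.integers(*cfg.cpg_width_range))
            s = max(int(row["pos"]) - w // 2, 0)
            cpg_rows.append((row["chrom"], s, s + w))
    cpg = pd.DataFrame(cpg_rows, columns=["chrom", "start", "end"])

    # realized near-Pol II flags -------------------------------------------
    near_real = np.zeros(total, dtype=bool)
    for i in range(total):
        sel = pol2["chrom"] == chrom_of[i]
        if sel.any():
            d = _point_to_interval_distance(
                pol2.loc[sel, "pos"].to_numpy(), starts[i], ends[i]
            )
            near_real[i] = bool(d.min() <= 2650)

    # static per-locus enrichment offsets give the broad between-locus
    # occupancy spectrum seen in real data; they are constant across samples
    # and time, so contrasts are untouched
    offsets = np.array([
        rng.normal(0.0, cfg.locus_effect_sd.get(lab, 0.0))
        for lab in labels
    ])
    enr = {tp: np.zeros(total) for tp in cfg.timepoints}
    for i, lab in enumerate(labels):
        base = cfg.base_enrichment[lab] + offsets[i]
        for tp in cfg.timepoints:
            e = base
            if lab == "dynamic_low" and tp != cfg.timepoints[0]:
                e = base + cfg.induction_log2fc
            if lab == "silent":
                e = 0.0
            enr[tp][i] = e

    h3k_enr = np.where(
        np.isfinite(h3k_anchor),
        cfg.pol2_enrichment["H3K4me3"]
        + rng.normal(0.0, cfg.locus_effect_sd.get("stable_high", 0.0), total),
        np.nan,
    )
    rpb2_enr = np.where(
        np.isfinite(rpb2_anchor),
        cfg.pol2_enrichment["RPB2"]
        + rng.normal(0.0, cfg.locus_effect_sd.get("stable_high", 0.0), total),
        np.nan,
    )
    truth = pd.DataFrame(
        {"locus_id": ids, "class_label": labels, "near_pol2": near_real,
         **enr, "h3k4me3_anchor": h3k_anchor, "rpb2_anchor": rpb2_anchor,
         "h3k4me3_enr": h3k_enr, "rpb2_enr": rpb2_enr}
    )
    truth = truth.set_index("locus_id").loc[loci["locus_id"]].reset_index()
    return loci, pol2, cpg, truth


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

KNOWN_FACTORS = ("RPC4", "RPB2", "H3K4me3", "Input")


def _chrom_names(cfg) -> np.ndarray:
    return np.array([f"chr{i + 1}" for i in range(cfg.n_chromosomes)],
                    dtype=object)


def _background_fragments(cfg, rng, n):
    chrom_idx = rng.integers(0, cfg.n_chromosomes, size=n)
    sizes = _truncated_normal_sizes(rng, n, cfg.frag_size_mean, cfg.frag_size_sd)
    mids = rng.random(n) * cfg.genome_length
    starts = np.clip(
        np.round(mids - sizes / 2).astype(np.int64), 0,
        np.maximum(cfg.genome_length - sizes, 0),
    )
    return _chrom_names(cfg)[chrom_idx], starts, starts + sizes


def simulate_fragments(cfg: SimConfig, loci: pd.DataFrame, truth: pd.DataFrame,
                       sample) -> pd.DataFrame:
    """Simulate the weighted fragment set of one sample.

    ``sample`` is a mapping with keys ``sample_id, factor, timepoint``
    (replicate identity is implicit in the sample id, which seeds the
    substream).  Returns a fragment frame with columns
    ``chrom, start, end, weight, pair_id, true_origin``; multi-mapped pairs
    appear as ``multimap_candidates`` rows sharing a pair id, with uniform
    placeholder weights and ``true_origin`` marking the genuine fragment.
    """
    cfg.validate()
    factor = sample["factor"]
    if factor not in KNOWN_FACTORS:
        raise ValueError(f"unknown ChIP factor {factor!r}")
    tp = sample.get("timepoint", cfg.timepoints[0])
    rng = _sample_rng(cfg, str(sample["sample_id"]))

    n_bg = rng.poisson(cfg.depth_per_sample)
    chroms, starts, ends = _background_fragments(cfg, rng, n_bg)
    parts = [(chroms, starts, ends)]

    if factor != "Input" and len(loci):
        t = truth.set_index("locus_id").loc[loci["locus_id"]]
        sigma = float(np.sqrt(np.log1p(cfg.replicate_cv ** 2)))
        lam_bp = cfg.depth_per_sample / cfg.genome_size  # fragments per bp
        if factor == "RPC4":
            enr = t[tp].to_numpy(dtype=float)
            win = (loci["end"] - loci["start"]).to_numpy() + 300.0
            centers_lo = loci["start"].to_numpy()
            centers_hi = loci["end"].to_numpy()
            anchors = None
        else:
            pre = "h3k4me3" if factor == "H3K4me3" else "rpb2"
            anchors = t[f"{pre}_anchor"].to_numpy(dtype=float)
            enr = np.where(np.isfinite(anchors),
                           t[f"{pre}_enr"].to_numpy(dtype=float), 0.0)
            enr = np.nan_to_num(enr)
            win = np.full(len(loci), 2000.0)
        noise = rng.lognormal(-sigma ** 2 / 2.0, sigma, size=len(loci))
        expected = (2.0 ** enr - 1.0) * lam_bp * win * noise
        n_sig = rng.poisson(np.maximum(expected, 0.0))
        for i in np.flatnonzero(n_sig):
            n = int(n_sig[i])
            sizes = _truncated_normal_sizes(
                rng, n, cfg.frag_size_mean, cfg.frag_size_sd
            )
            if factor == "RPC4":
                mids = rng.uniform(centers_lo[i], centers_hi[i], size=n)
            else:
                mids = rng.normal(anchors[i], 250.0, size=n)
            s = np.clip(np.round(mids - sizes / 2).astype(np.int64), 0,
                        np.maximum(cfg.genome_length - sizes, 0))
            parts.append((
                np.repeat(loci["chrom"].iloc[i], n).astype(object),
                s, s + sizes,
            ))

    chroms = np.concatenate([p[0] for p in parts])
    starts = np.concatenate([p[1] for p in parts])
    ends = np.concatenate([p[2] for p in parts])
    n = len(starts)
    frags = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends,
         "weight": np.ones(n), "pair_id": np.arange(n),
         "true_origin": np.ones(n, dtype=bool)}
    )

    # multi-mapped pairs: true fragment plus uniform decoy candidates with a
    # broader size distribution, uniform placeholder weights
    k = max(int(cfg.multimap_candidates), 2)
    is_multi = rng.random(n) < cfg.multimap_fraction
    m = int(is_multi.sum())
    if m:
        frags.loc[is_multi, "weight"] = 1.0 / k
        d = m * (k - 1)
        d_chrom_idx = rng.integers(0, cfg.n_chromosomes, size=d)
        d_sizes = _truncated_normal_sizes(
            rng, d, cfg.frag_size_mean, 3.0 * cfg.frag_size_sd, lo=20
        )
        d_mids = rng.random(d) * cfg.genome_length
        d_start = np.clip(np.round(d_mids - d_sizes / 2).astype(np.int64), 0,
                          np.maximum(cfg.genome_length - d_sizes, 0))
        decoys = pd.DataFrame(
            {"chrom": _chrom_names(cfg)[d_chrom_idx],
             "start": d_start, "end": d_start + d_sizes,
             "weight": np.full(d, 1.0 / k),
             "pair_id": np.repeat(frags.loc[is_multi, "pair_id"].to_numpy(),
                                  k - 1),
             "true_origin": np.zeros(d, dtype=bool)}
        )
        frags = pd.concat([frags, decoys], ignore_index=True)

    return frags.sort_values(["chrom", "start", "end"],
                             kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# experiment-level helpers
# ---------------------------------------------------------------------------

def default_sample_sheet(cfg: SimConfig,
                         factors: tuple[str, ...] | None = None,
                         pol2_factor_timepoints: tuple[str, ...] = ("TP0",),
                         ) -> pd.DataFrame:
    """Sample sheet for the default design.

    Pol III ChIP (RPC4) covers every time point; H3K4me3 and RPB2 cover
    ``pol2_factor_timepoints``; each (timepoint, replicate) condition has one
    shared Input.  ``factors`` restricts the ChIP factors simulated.
    """
    factors = factors or ("RPC4", "H3K4me3", "RPB2")
    rows = []
    needed_inputs = set()
    for f in factors:
        tps = cfg.timepoints if f == "RPC4" else pol2_factor_timepoints
        for tp in tps:
            for r in range(1, cfg.n_replicates + 1):
                iid = f"Input_{tp}_r{r}"
                rows.append((f"{f}_{tp}_r{r}", f, tp, r, iid))
                needed_inputs.add((tp, r))
    for tp, r in sorted(needed_inputs):
        rows.append((f"Input_{tp}_r{r}", "Input", tp, r, None))
    return pd.DataFrame(
        rows, columns=["sample_id", "factor", "timepoint", "replicate",
                       "input_id"]
    )


@dataclass
class SimData:
    """Bundle of one simulated experiment."""

    cfg: SimConfig
    loci: pd.DataFrame
    pol2: pd.DataFrame
    cpg: pd.DataFrame
    truth: pd.DataFrame
    sample_sheet: pd.DataFrame
    frags_by_sample: dict[str, pd.DataFrame]


def simulate_experiment(cfg: SimConfig,
                        sample_sheet: pd.DataFrame | None = None,
                        factors: tuple[str, ...] | None = None) -> SimData:
    """Simulate annotation plus fragment sets for a whole sample sheet."""
    loci, pol2, cpg, truth = simulate_annotation(cfg)
    if sample_sheet is None:
        sample_sheet = default_sample_sheet(cfg, factors=factors)
    frags = {
        row["sample_id"]: simulate_fragments(cfg, loci, truth, row)
        for _, row in sample_sheet.iterrows()
    }
    return SimData(cfg, loci, pol2, cpg, truth, sample_sheet, frags)


# ---------------------------------------------------------------------------
# plain-text IO (BED / TSV, 0-based half-open)
# ---------------------------------------------------------------------------

def write_annotation_bed(loci: pd.DataFrame, path) -> None:
    out = loci[["chrom", "start", "end", "locus_id"]].copy()
    out["score"] = 0
    out["strand"] = loci["strand"]
    out["locus_type"] = loci["locus_type"]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_annotation_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "locus_id", "score", "strand",
               "locus_type"],
        dtype={"chrom": str},
    )
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
    return df[["locus_id", "chrom", "start", "end", "strand", "locus_type",
               "tss"]]


def write_sim_tables(sim: SimData, outdir) -> None:
    """Write annotation, features, truth and sample sheet as text tables."""
    from pathlib import Path
    from .fragments import write_fragment_bed

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_annotation_bed(sim.loci, out / "loci.bed")
    sim.pol2.to_csv(out / "pol2_features.tsv", sep="\t", index=False)
    sim.cpg.to_csv(out / "cpg_islands.bed", sep="\t", header=False, index=False)
    sim.truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    sim.sample_sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    for sid, frags in sim.frags_by_sample.items():
        write_fragment_bed(frags, out / f"fragments_{sid}.bed")
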