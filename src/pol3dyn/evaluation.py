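"""Benchmark runs of the pipeline under its study conditions.

These routines generate synthetic experiments with the default generator
settings, run the analysis, and measure recovery / calibration quantities
against the known ground truth: class-label recovery of induced loci,
false-positive behavior on silent data, moderated-t calibration, pi0
recovery, and the structural classification / profile directionality of the
stable near-Pol II class.  They are used by the acceptance test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from . import dynamics, fragments, profiles, scoring
from .classification import assign_groups
from .synthetic_data import (SimConfig, default_sample_sheet,
                             simulate_experiment)


def _processed_scores(sim, alpha=scoring.ALPHA):
    frags_by_sample = {}
    for sid in list(sim.frags_by_sample):
        raw = sim.frags_by_sample.pop(sid)  # release raw fragments eagerly
        frags_by_sample[sid] = fragments.process_sample(
            raw.drop(columns=["true_origin"]))
    sim.frags_by_sample = frags_by_sample
    table = scoring.build_score_table(
        frags_by_sample, sim.sample_sheet, sim.loci, sim.cfg.chrom_sizes,
        alpha=alpha,
    )
    return frags_by_sample, table


def recovery_metrics(seed: int, n_seeds: int = 5) -> dict[str, float]:
    """Class-label recovery of the default time-course design.

    Runs the Pol III arm of the default experiment for ``n_seeds`` seeds and
    averages the sensitivity on induced (dynamic_low) loci, the false-call
    rate on stable_high loci (q < 0.05, TP36 vs TP0), and the Spearman
    correlation between the true TP0 enrichment and the measured TP0 score
    across non-silent loci.
    """
    sens, false_rate, spearman = [], [], []
    for k in range(n_seeds):
        cfg = dataclasses.replace(SimConfig(), seed=(seed * 1000 + k) % 2**31)
        sim = simulate_experiment(cfg, factors=("RPC4",))
        _, table = _processed_scores(sim)
        diff = dynamics.differential_occupancy(table)
        truth = sim.truth.set_index("locus_id")
        res = diff.join(truth["class_label"])
        dyn_loci = res[res["class_label"] == "dynamic_low"]
        stable = res[res["class_label"] == "stable_high"]
        sens.append(
            float((dyn_loci["significant"] & (dyn_loci["direction"] > 0)).mean()))
        false_rate.append(float(stable["significant"].mean()))
        tp0_cols = [s for s in table.sample_ids if "TP0" in s]
        tp0_score = table.scores[tp0_cols].mean(axis=1)
        non_silent = truth.index[truth["class_label"] != "silent"]
        rho = stats.spearmanr(
            truth.loc[non_silent, "TP0"], tp0_score.loc[non_silent]
        ).statistic
        spearman.append(float(rho))
    n = len(sim.truth)
    return {
        "sensitivity": float(np.mean(sens)),
        "false_call_rate": float(np.mean(false_rate)),
        "spearman_tp0": float(np.mean(spearman)),
        "n_loci": n,
        "n_seeds": n_seeds,
    }


def silent_calibration(seed: int) -> dict[str, float]:
    """Fraction of loci above the Bonferroni-derived cutoff when nothing is
    enriched, pooled over the two TP0 Pol III replicates."""
    cfg = dataclasses.replace(
        SimConfig(),
        class_fractions={"stable_high": 0.0, "dynamic_low": 0.0, "silent": 1.0},
        seed=seed % 2**31,
    )
    sheet = default_sample_sheet(cfg, factors=("RPC4",))
    sheet = sheet[sheet["timepoint"] == "TP0"].reset_index(drop=True)
    sim = simulate_experiment(cfg, sample_sheet=sheet)
    _, table = _processed_scores(sim)
    above = table.above_cutoff()
    frac = float(above.to_numpy().mean())
    n = int(above.size)
    return {
        "fraction_above_cutoff": frac,
        "alpha": scoring.ALPHA,
        "bound_3se": scoring.ALPHA
        + 3 * float(np.sqrt(scoring.ALPHA * (1 - scoring.ALPHA) / n)),
        "n": n,
    }


def _null_matrix(rng, m, sd=0.2, n_reps=2,
                 levels=("TP0", "TP36", "TP48", "TP60")):
    samples = [f"{lv}_r{r}" for lv in levels for r in range(1, n_reps + 1)]
    lev = pd.Series([s.rsplit("_", 1)[0] for s in samples], index=samples)
    X = dynamics.design_matrix(lev, list(levels))
    Y = pd.DataFrame(rng.normal(0, sd, (m, len(samples))), columns=samples)
    return Y, X


def moderated_t_calibration(seed: int, m: int = 10_000,
                            n_fdr_seeds: int = 10) -> dict[str, float]:
    """Null p-value uniformity and empirical FDR on a 30%-effect mixture.

    The null run (no level effects) is tested for uniform p-values with a KS
    test; the mixture runs plant a TP36 shift in 30% of loci and measure the
    realized false-discovery proportion among q < 0.05 calls, averaged over
    ``n_fdr_seeds`` seeds.
    """
    rng = np.random.default_rng(seed % 2**31)
    Y, X = _null_matrix(rng, m)
    fit = dynamics.fit_linear_model(Y, X)
    prior = dynamics.ebayes_moderate(fit.s2.to_numpy(), fit.df_resid)
    res = dynamics.contrast_test(fit, prior, "TP36-TP0")
    ks_p = float(stats.kstest(res["p"], "uniform").pvalue)

    fdrs = []
    for k in range(n_fdr_seeds):
        r2 = np.random.default_rng((seed * 131 + k) % 2**31)
        Y, X = _null_matrix(r2, m)
        has_effect = np.zeros(m, dtype=bool)
        has_effect[r2.choice(m, int(0.3 * m), replace=False)] = True
        for s in Y.columns:
            if s.startswith("TP36"):
                Y.loc[has_effect, s] += 0.8
        fit = dynamics.fit_linear_model(Y, X)
        prior = dynamics.ebayes_moderate(fit.s2.to_numpy(), fit.df_resid)
        r = dynamics.contrast_test(fit, prior, "TP36-TP0")
        q, _ = dynamics.qvalues(r["p"].to_numpy())
        disc = q < 0.05
        if disc.sum():
            fdrs.append(float((disc & ~has_effect).sum() / disc.sum()))
    return {
        "ks_uniform_p": ks_p,
        "empirical_fdr": float(np.mean(fdrs)),
        "nominal_fdr": 0.05,
        "m": m,
    }


def pi0_recovery(seed: int, m: int = 10_000, n_reps: int = 8,
                 pi0_values=(0.7, 0.9, 1.0)) -> dict[float, float]:
    """Mean smoothed pi0 estimate on p-value mixtures of known composition.

    Alternative p-values come from one-sided normal tests with effect size 3;
    averaging over ``n_reps`` independent mixtures measures the estimator's
    accuracy rather than single-draw noise.
    """
    rng = np.random.default_rng(seed % 2**31)
    out = {}
    for pi0 in pi0_values:
        ests = []
        for _ in range(n_reps):
            n1 = int(round(m * (1 - pi0)))
            p = np.concatenate([
                rng.random(m - n1),
                stats.norm.sf(rng.normal(3.0, 1.0, n1)),
            ])
            ests.append(dynamics.estimate_pi0(p))
        out[pi0] = float(np.mean(ests))
    return out


def structure_metrics(seed: int) -> dict[str, float]:
    """Peak-presence classification and profile directionality at baseline.

    Simulates the TP0 slice of the default experiment (all three ChIP
    factors), classifies loci against their per-sample cutoffs, and measures
    (i) the fraction of stable_high near-Pol II loci landing in the
    RPC4+H3K4me3+RPB2 group and (ii) the upstream vs downstream integrals of
    the Pol II (RPB2) tag-density profile around the Pol III TSSs of that
    class.
    """
    cfg = dataclasses.replace(SimConfig(), seed=seed % 2**31)
    sheet = default_sample_sheet(cfg)
    sheet = sheet[sheet["timepoint"] == "TP0"].reset_index(drop=True)
    sim = simulate_experiment(cfg, sample_sheet=sheet)
    frags_by_sample, table = _processed_scores(sim)
    rep_map = {
        "rep1": {"RPC4": "RPC4_TP0_r1", "H3K4me3": "H3K4me3_TP0_r2",
                 "RPB2": "RPB2_TP0_r1"},
    }
    groups = assign_groups(table, rep_map)["rep1"]
    truth = sim.truth.set_index("locus_id")
    target = truth.index[(truth["class_label"] == "stable_high")
                         & truth["near_pol2"]]
    triple_frac = float((groups.loc[target] == "RPC4+H3K4me3+RPB2").mean())

    sub = sim.loci[sim.loci["locus_id"].isin(target)]
    prof = profiles.tag_density_profile(
        frags_by_sample["RPB2_TP0_r1"], sub, cfg.chrom_sizes)
    up, down = prof.half_integrals()

    rpc4_above = table.above_cutoff()[["RPC4_TP0_r1", "RPC4_TP0_r2"]]
    conc_r = float(np.corrcoef(
        table.scores.loc[rpc4_above.any(axis=1), "RPC4_TP0_r1"],
        table.scores.loc[rpc4_above.any(axis=1), "RPC4_TP0_r2"])[0, 1])
    return {
        "triple_peak_fraction": triple_frac,
        "n_target_loci": int(len(target)),
        "rpb2_upstream_integral": up,
        "rpb2_downstream_integral": down,
        "rpc4_replicate_r": conc_r,
    }
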