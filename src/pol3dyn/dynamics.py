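"""Differential occupancy: linear model, moderated t, and q-values.

Per locus, occupancy scores across the time course are fit with a one-way
linear model (four time-point levels, two replicates each).  Residual
variances are shrunk toward a common prior by empirical Bayes: the marginal
distribution of a scaled sample variance is ``s0^2 * F(d_g, d_0)``, and the
prior parameters ``(s0^2, d_0)`` are recovered by method of moments on
``log s^2`` using digamma/trigamma identities.  Contrast estimates are tested
with the moderated t statistic

    t = (c' mu_hat) / (s_tilde * sqrt(c' (X'X)^-1 c)),
    s_tilde^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g),

on ``d_0 + d_g`` degrees of freedom; a positive t means a score increase.
Multiplicity is handled with q-values whose null proportion pi0 is estimated
by a cubic smoothing spline (3 effective df) over the Storey lambda grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

#: Storey lambda grid for the pi0 estimate.
PI0_LAMBDAS = np.round(np.arange(0.0, 0.951, 0.05), 2)
#: Effective degrees of freedom of the pi0 smoothing spline.
PI0_SPLINE_DF = 3.0
#: Default FDR threshold for significance calls.
FDR_DEFAULT = 0.05


# ---------------------------------------------------------------------------
# linear model
# ---------------------------------------------------------------------------

def design_matrix(levels: pd.Series, level_order=None) -> pd.DataFrame:
    """One-hot samples x levels indicator matrix (cell-means coding)."""
    levels = pd.Series(levels)
    if level_order is None:
        level_order = list(dict.fromkeys(levels))
    X = pd.DataFrame(0.0, index=levels.index, columns=list(level_order))
    for s, lev in levels.items():
        X.at[s, lev] = 1.0
    return X


@dataclass
class ModelFit:
    """Per-locus OLS fit of a shared design."""

    coef: pd.DataFrame          # loci x levels
    s2: pd.Series               # residual variance per locus
    df_resid: int
    xtx_inv: np.ndarray
    levels: list[str]


def fit_linear_model(scores: pd.DataFrame, design: pd.DataFrame) -> ModelFit:
    """Ordinary least squares per locus (rows) with a common design.

    ``scores`` is loci x samples; ``design`` is samples x levels.  With a
    saturated one-way design the coefficients are the level means and the
    residual variance is the pooled within-level variance on
    ``n_samples - n_levels`` df.
    """
    X = design.loc[scores.columns].to_numpy(dtype=float)
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise ValueError("design matrix is not of full column rank")
    d = n - rank
    if d <= 0:
        raise ValueError(
            f"no residual degrees of freedom ({n} samples, rank {rank})"
        )
    Y = scores.to_numpy(dtype=float).T            # samples x loci
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)  # levels x loci
    resid = Y - X @ beta
    s2 = (resid ** 2).sum(axis=0) / d
    return ModelFit(
        coef=pd.DataFrame(beta.T, index=scores.index, columns=design.columns),
        s2=pd.Series(s2, index=scores.index),
        df_resid=d,
        xtx_inv=np.linalg.inv(X.T @ X),
        levels=list(design.columns),
    )


# ---------------------------------------------------------------------------
# empirical Bayes prior on the variances
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x = max(x + step, 1e-8)
        if abs(step) < 1e-10 * x:
            break
    return float(x)


@dataclass
class EBayesPrior:
    s2_0: float
    d_0: float  # may be inf

    def posterior_s2(self, s2, df_resid):
        """Shrunken variance s_tilde^2 per locus."""
        s2 = np.asarray(s2, dtype=float)
        if np.isinf(self.d_0):
            return np.full_like(s2, self.s2_0)
        return (self.d_0 * self.s2_0 + df_resid * s2) / (self.d_0 + df_resid)


def ebayes_moderate(s2, df_resid: int, min_loci: int = 10) -> EBayesPrior:
    """Fit the scaled inverse-chi-square variance prior across loci.

    Method of moments on ``z = log s^2``: under the hierarchical model
    ``E[z] = log s0^2 + psi(d/2) - psi(d0/2) + log(d0/d)`` and
    ``Var[z] = psi'(d/2) + psi'(d0/2)``.  When the observed spread of z does
    not exceed the pure-sampling floor ``psi'(d/2)``, the prior is degenerate
    (``d_0 = inf``, ``s0^2 = mean(s^2)``) and every shrunken variance equals
    ``s0^2``.  Loci with non-positive or non-finite s^2 are excluded, and the
    remainder floored at ``1e-5 * median`` to keep the log-moments stable.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if not ok.any():
        raise ValueError("all residual variances are zero; nothing to moderate")
    if ok.sum() < min_loci:
        raise ValueError(
            f"only {int(ok.sum())} loci with positive finite variance; "
            f"need >= {min_loci} for a stable empirical-Bayes fit"
        )
    x = np.maximum(s2[ok], 1e-5 * np.median(s2[ok]))
    z = np.log(x)
    zbar = z.mean()
    zvar = z.var(ddof=1)
    evar = zvar - polygamma(1, df_resid / 2.0)
    base = zbar - digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    if evar <= 0:
        return EBayesPrior(s2_0=float(x.mean()), d_0=np.inf)
    d0 = 2.0 * _trigamma_inverse(evar)
    s20 = np.exp(base + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return EBayesPrior(s2_0=float(s20), d_0=float(d0))


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def contrast_vector(levels: list[str], contrast: str) -> np.ndarray:
    """Parse ``"TP36-TP0"`` into a coefficient vector over ``levels``."""
    try:
        plus, minus = contrast.split("-")
    except ValueError as err:
        raise ValueError(f"cannot parse contrast {contrast!r}") from err
    c = np.zeros(len(levels))
    for name, val in ((plus.strip(), 1.0), (minus.strip(), -1.0)):
        if name not in levels:
            raise ValueError(f"contrast level {name!r} not in design {levels}")
        c[levels.index(name)] += val
    return c


def contrast_test(fit: ModelFit, prior: EBayesPrior, contrast) -> pd.DataFrame:
    """Moderated-t test of one contrast for every locus.

    Returns estimate, moderated t, two-sided p, total df and the shrunken
    variance; ``direction`` is the sign of the estimate.
    """
    c = (contrast_vector(fit.levels, contrast)
         if isinstance(contrast, str) else np.asarray(contrast, dtype=float))
    if len(c) != len(fit.levels):
        raise ValueError("contrast length must equal the number of levels")
    v_c = float(c @ fit.xtx_inv @ c)
    if v_c <= 0:
        raise ValueError("contrast is not estimable under this design")
    est = fit.coef.to_numpy() @ c
    s2_post = prior.posterior_s2(fit.s2.to_numpy(), fit.df_resid)
    # total df capped at the pooled residual df across loci (an infinite
    # prior cannot buy more information than the experiment contains)
    pooled = fit.df_resid * len(fit.coef)
    df_total = min(prior.d_0 + fit.df_resid, pooled)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / np.sqrt(s2_post * v_c)
    t = np.where(est == 0, 0.0, t)
    p = 2.0 * t_dist.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {"estimate": est, "t": t, "p": p,
         "df_total": np.full(len(est), df_total),
         "s2_post": s2_post,
         "direction": np.sign(est).astype(int)},
        index=fit.coef.index,
    )


# ---------------------------------------------------------------------------
# pi0 and q-values
# ---------------------------------------------------------------------------

def _smoothing_spline(x: np.ndarray, y: np.ndarray, df_target: float,
                      weights: np.ndarray | None = None):
    """Natural cubic smoothing spline fitted values, penalty tuned so the
    effective df (trace of the smoother matrix) matches ``df_target``."""
    n = len(x)
    h = np.diff(x)
    # second-difference operator (n-2 x n) and its Gram matrix
    D = np.zeros((n - 2, n))
    W = np.zeros((n - 2, n - 2))
    for i in range(n - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        W[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < n - 2:
            W[i, i + 1] = W[i + 1, i] = h[i + 1] / 6.0
    K = D.T @ np.linalg.solve(W, D)
    Wm = np.eye(n) if weights is None else np.diag(weights)

    def smoother(log_lam):
        return np.linalg.solve(Wm + np.exp(log_lam) * K, Wm)

    lo, hi = -25.0, 25.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.trace(smoother(mid)) > df_target:
            lo = mid
        else:
            hi = mid
    return smoother(0.5 * (lo + hi)) @ y


def estimate_pi0(p, lambdas: np.ndarray = PI0_LAMBDAS,
                 spline_df: float = PI0_SPLINE_DF) -> float:
    """Storey's smoothed estimate of the proportion of true nulls.

    ``pi0_hat(lambda) = #{p > lambda} / (m (1 - lambda))`` on the lambda
    grid, smoothed with a cubic spline of ~3 effective df and read off at
    the largest lambda, clamped into (0, 1].  Two stabilizations keep the
    estimator sane for small p-value families, where the tail counts behind
    ``pi0_hat`` at large lambda are single digits: grid points are weighted
    by their binomial precision (proportional to ``1 - lambda``), and the
    result is floored at half of the low-variance ``pi0_hat(0.5)`` point
    estimate.  Both are inert for large m.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        raise ValueError("empty p-value vector")
    lambdas = np.asarray(lambdas, dtype=float)
    pi0_raw = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    w = (1.0 - lambdas) / np.mean(1.0 - lambdas)
    smoothed = _smoothing_spline(lambdas, pi0_raw, spline_df, weights=w)
    pi0 = float(smoothed[-1])
    mid = int(np.argmin(np.abs(lambdas - 0.5)))
    pi0 = max(pi0, 0.5 * float(pi0_raw[mid]))
    if pi0 <= 0:
        warnings.warn("pi0 estimate <= 0; clamping to 1/m")
        pi0 = 1.0 / m
    return min(pi0, 1.0)


def qvalues(p, lambdas: np.ndarray = PI0_LAMBDAS,
            spline_df: float = PI0_SPLINE_DF) -> tuple[np.ndarray, float]:
    """Storey q-values: ``q_i = pi0 * min_{p_j >= p_i} (m p_j / rank_j)``."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    pi0 = estimate_pi0(p, lambdas, spline_df)
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


# ---------------------------------------------------------------------------
# top-level differential occupancy
# ---------------------------------------------------------------------------

def differential_occupancy(table, factor: str = "RPC4",
                           contrast: str = "TP36-TP0",
                           fdr: float = FDR_DEFAULT,
                           level_order=None,
                           prior_from: str = "eligible") -> pd.DataFrame:
    """Fit, moderate, test and call one contrast from a score table.

    All loci enter the per-locus model fit; loci whose scores sit below the
    empirical cutoff in every sample of both contrasted time points are
    excluded from the multiple-testing family (``eligible`` False, q = NaN).
    The empirical-Bayes variance prior is estimated from the eligible family
    by default (``prior_from='eligible'``): below-cutoff loci have
    pseudocount-compressed scores with systematically smaller replicate
    variance, and letting them into the prior deflates the shrunken standard
    errors of exactly the loci being tested.  ``prior_from='all'`` pools
    every locus instead.  Significant loci are stratified by whether their
    score was already above cutoff at the baseline time point.
    """
    sheet = table.sample_sheet
    chip = sheet[sheet["factor"] == factor]
    if chip.empty:
        raise ValueError(f"no samples for factor {factor!r}")
    sample_ids = list(chip["sample_id"])
    levels = chip.set_index("sample_id")["timepoint"]
    if level_order is None:
        level_order = [tp for tp in dict.fromkeys(levels)]
    X = design_matrix(levels, level_order)
    scores = table.scores[sample_ids]
    fit = fit_linear_model(scores, X)

    plus, minus = (s.strip() for s in contrast.split("-"))
    above = table.above_cutoff()[sample_ids]
    tp_of = levels.to_dict()
    in_contrast = [s for s in sample_ids if tp_of[s] in (plus, minus)]
    baseline = [s for s in sample_ids if tp_of[s] == minus]
    eligible = above[in_contrast].any(axis=1)
    below_at_baseline = ~above[baseline].any(axis=1)

    if prior_from == "eligible" and eligible.sum() >= 10:
        prior_s2 = fit.s2[eligible].to_numpy()
    elif prior_from in ("all", "eligible"):
        prior_s2 = fit.s2.to_numpy()
    else:
        raise ValueError(f"unknown prior_from {prior_from!r}")
    prior = ebayes_moderate(prior_s2, fit.df_resid)
    res = contrast_test(fit, prior, contrast)

    res["eligible"] = eligible
    res["q"] = np.nan
    if eligible.any():
        q, pi0 = qvalues(res.loc[eligible, "p"].to_numpy())
        res.loc[eligible, "q"] = q
        res.attrs["pi0"] = pi0
    res["significant"] = eligible & (res["q"] < fdr)
    stratum = np.where(
        ~eligible, "below_cutoff_both",
        np.where(below_at_baseline, "below_cutoff_baseline",
                 "above_cutoff_baseline"),
    )
    res["stratum"] = stratum
    res["contrast"] = contrast
    res.index.name = "locus_id"
    return res


def call_significant(results: pd.DataFrame,
                     fdr: float = FDR_DEFAULT) -> pd.DataFrame:
    """Flag loci with q < fdr (NaN q never significant)."""
    out = results.copy()
    out["significant"] = out["q"].lt(fdr).fillna(False)
    return out
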