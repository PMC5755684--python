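"""Per-variant meta-regression of allelic effects on axes of genetic variation.

For variant j with per-study effects b_kj and known variances v_kj, the model

    E[b_kj] = alpha_j + sum_t beta_tj * x_kt,

is fitted by weighted least squares with weights w_k = 1 / v_kj.  Because the
effect variances are treated as known, deviance differences reduce to weighted
residual-sum-of-squares differences and yield chi-squared tests that partition
the evidence at each variant:

* association (joint intercept + axes), T + 1 df;
* ancestry-correlated heterogeneity (axes beyond the intercept), T df;
* residual heterogeneity (lack of fit of the full model), K_j - T - 1 df;
* per-axis contribution (single axis dropped from the full model), 1 df.

An approximate Bayes' factor in favour of association is obtained from the
association statistic penalised, BIC-style, for the T + 1 fitted parameters:
ln BF = (X_assoc - (T + 1) ln K_j) / 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ancestry_axes import AxesOfVariation
from .sumstats_io import StudyPanel

logger = logging.getLogger(__name__)

_LOG10E = np.log10(np.e)


@dataclass
class VariantMetaResult:
    """Meta-regression summary for one variant."""

    alpha: float
    alpha_se: float
    beta: np.ndarray
    beta_se: np.ndarray
    n_studies: int
    n_axes: int
    x_assoc: float
    df_assoc: int
    p_assoc: float
    x_het_anc: float
    df_het_anc: int
    p_het_anc: float
    x_het_res: float | None
    df_het_res: int
    p_het_res: float | None
    x_axis: np.ndarray = field(default_factory=lambda: np.array([]))
    p_axis: np.ndarray = field(default_factory=lambda: np.array([]))
    ln_bf: float = np.nan
    log10_p_assoc: float = np.nan
    rank_deficient: bool = False


def _chisq_logp(x: np.ndarray, df: int):
    """(p, log10 p) of the chi-squared survival function, safe under underflow."""
    p = stats.chi2.sf(x, df)
    log10p = stats.chi2.logsf(x, df) * _LOG10E
    return p, log10p


def wls_stats_batch(betas: np.ndarray, variances: np.ndarray, axes: np.ndarray):
    """Vectorised weighted-least-squares fits for many variants at once.

    Parameters
    ----------
    betas, variances
        Arrays of shape (n_variants, K); every study contributes to every
        variant (use :func:`fit_variant` for variants with missing studies).
    axes
        (K, T) axes of genetic variation; T may be 0.

    Returns
    -------
    dict of arrays
        theta (n, T+1), se (n, T+1), x_assoc, x_het_anc, x_het_res (each (n,)).

    Notes
    -----
    With weights w = 1/v and design X = [1 | axes], the statistics follow from
    weighted RSS differences:  X_assoc = sum w b^2 - RSS_full,
    X_het_anc = RSS_intercept - RSS_full, X_het_res = RSS_full.
    """
    B = np.asarray(betas, dtype=float)
    V = np.asarray(variances, dtype=float)
    X = np.asarray(axes, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    K = B.shape[1]
    Xd = np.column_stack([np.ones(K), X])

    W = 1.0 / V
    A = np.einsum("nk,kp,kq->npq", W, Xd, Xd)
    c = np.einsum("nk,nk,kp->np", W, B, Xd)
    theta = np.linalg.solve(A, c[..., None])[..., 0]
    Ainv = np.linalg.inv(A)
    se = np.sqrt(np.einsum("npp->np", Ainv))

    swb2 = np.einsum("nk,nk,nk->n", W, B, B)
    explained = np.einsum("np,np->n", theta, c)
    rss_full = np.maximum(swb2 - explained, 0.0)
    sw = W.sum(axis=1)
    swb = np.einsum("nk,nk->n", W, B)
    rss_int = np.maximum(swb2 - swb**2 / sw, 0.0)

    x_assoc = np.maximum(explained, 0.0)
    x_het_anc = np.maximum(rss_int - rss_full, 0.0)
    return {
        "theta": theta,
        "se": se,
        "x_assoc": x_assoc,
        "x_het_anc": x_het_anc,
        "x_het_res": rss_full,
    }


def fit_variant(
    betas: np.ndarray,
    variances: np.ndarray,
    axes: np.ndarray,
    compute_axis_tests: bool = True,
) -> VariantMetaResult:
    """Weighted meta-regression of one variant's effects on the ancestry axes.

    ``betas`` and ``variances`` cover the K_j contributing studies only, and
    ``axes`` holds the matching rows of the genome-wide axes (shape (K_j, T)).
    The axes are global study properties and are never recomputed per variant.

    The residual-heterogeneity test needs K_j >= T + 2; with K_j = T + 1 the
    association and ancestry tests are still returned and the residual test is
    reported as unavailable.  A rank-deficient design suppresses all tests.
    """
    b = np.asarray(betas, dtype=float)
    v = np.asarray(variances, dtype=float)
    X = np.asarray(axes, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    K_j = b.size
    T = X.shape[1]
    if np.any(v <= 0) or not np.all(np.isfinite(b)):
        raise ValueError("effects must be finite and variances strictly positive")
    if K_j < T + 1:
        raise ValueError(f"need at least T+1={T + 1} studies to fit {T} axes, got {K_j}")

    Xd = np.column_stack([np.ones(K_j), X])
    if np.linalg.matrix_rank(Xd) < T + 1:
        nan_vec = np.full(T, np.nan)
        return VariantMetaResult(
            alpha=np.nan, alpha_se=np.nan, beta=nan_vec, beta_se=nan_vec,
            n_studies=K_j, n_axes=T,
            x_assoc=np.nan, df_assoc=T + 1, p_assoc=np.nan,
            x_het_anc=np.nan, df_het_anc=T, p_het_anc=np.nan,
            x_het_res=None, df_het_res=max(K_j - T - 1, 0), p_het_res=None,
            x_axis=nan_vec, p_axis=nan_vec, rank_deficient=True,
        )

    out = wls_stats_batch(b[None, :], v[None, :], X)
    theta, se = out["theta"][0], out["se"][0]
    x_assoc = float(out["x_assoc"][0])
    x_het_anc = float(out["x_het_anc"][0])
    rss_full = float(out["x_het_res"][0])

    df_res = K_j - T - 1
    if df_res >= 1:
        x_het_res = rss_full
        p_het_res = float(stats.chi2.sf(x_het_res, df_res))
    else:
        x_het_res, p_het_res = None, None

    p_assoc, log10_p = _chisq_logp(np.array(x_assoc), T + 1)
    p_het_anc = float(stats.chi2.sf(x_het_anc, T)) if T >= 1 else 1.0

    x_axis = np.full(T, np.nan)
    p_axis = np.full(T, np.nan)
    if compute_axis_tests and T >= 1:
        w = 1.0 / v
        swb2 = float(np.sum(w * b * b))
        for t in range(T):
            Xt = np.delete(Xd, t + 1, axis=1)
            At = Xt.T @ (w[:, None] * Xt)
            ct = Xt.T @ (w * b)
            rss_t = max(swb2 - float(ct @ np.linalg.solve(At, ct)), 0.0)
            x_axis[t] = max(rss_t - rss_full, 0.0)
        p_axis = stats.chi2.sf(x_axis, 1)

    ln_bf = ln_bayes_factor(x_assoc, T, K_j)
    return VariantMetaResult(
        alpha=float(theta[0]), alpha_se=float(se[0]),
        beta=theta[1:].copy(), beta_se=se[1:].copy(),
        n_studies=K_j, n_axes=T,
        x_assoc=x_assoc, df_assoc=T + 1, p_assoc=float(p_assoc),
        x_het_anc=x_het_anc, df_het_anc=T, p_het_anc=p_het_anc,
        x_het_res=x_het_res, df_het_res=max(df_res, 0), p_het_res=p_het_res,
        x_axis=x_axis, p_axis=p_axis,
        ln_bf=ln_bf, log10_p_assoc=float(log10_p),
    )


def ln_bayes_factor(x_assoc, n_axes: int, n_studies) -> float:
    """Natural-log approximate Bayes' factor in favour of association.

    ln BF = (X_assoc - (T + 1) ln K) / 2 — the association chi-squared
    penalised for the T + 1 regression parameters, in the style of a BIC
    approximation over the K contributing studies.
    """
    x = np.asarray(x_assoc, dtype=float)
    if np.any(x < 0):
        raise ValueError("association statistic must be non-negative")
    return (x - (n_axes + 1) * np.log(n_studies)) / 2.0


def lambda_gc(statistics, df: int) -> float:
    """Genomic-control inflation factor: median statistic over the null median.

    Values below 1 are reported as computed; correction routines floor at 1.
    """
    x = np.asarray(statistics, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite statistics for genomic control")
    if x.size < 100:
        logger.warning("lambda_gc: only %d statistics; estimate will be noisy", x.size)
    return float(np.median(x) / stats.chi2.ppf(0.5, df))


def genomic_control_correct(results: pd.DataFrame, lam: float, df: int) -> pd.DataFrame:
    """Deflate association statistics by ``lam`` and recompute p-values and ln BF.

    Expects a results table from :func:`run_meta_regression` (columns
    ``chisq_association``, ``ndf_association``, ``Ncohort``).  ``lam`` < 1 is a
    no-op with a warning, matching standard genomic-control practice.
    """
    if lam < 1.0:
        logger.warning("genomic_control_correct: lambda=%.4f < 1, no correction applied", lam)
        return results.copy()
    out = results.copy()
    x = out["chisq_association"].to_numpy(dtype=float) / lam
    out["chisq_association"] = x
    p, log10p = _chisq_logp(x, df)
    out["P-value_association"] = p
    out["log10P_association"] = log10p
    if "lnBF" in out.columns:
        out["lnBF"] = ln_bayes_factor(x, df - 1, out["Ncohort"].to_numpy(dtype=float))
    return out


def run_meta_regression(
    panel: StudyPanel,
    axes: AxesOfVariation,
    compute_axis_tests: bool = False,
) -> pd.DataFrame:
    """Fit every panel variant on its contributing-study subset.

    Returns one row per variant with the association, ancestry-heterogeneity
    and residual-heterogeneity statistics, p-values, and ln BF.  Variants with
    fewer than T + 1 contributing studies are skipped with a count.
    """
    T = axes.n_axes
    rows = []
    n_skipped = 0
    for i in range(panel.n_variants):
        mask = panel.present[i]
        K_j = int(mask.sum())
        if K_j < T + 1:
            n_skipped += 1
            continue
        res = fit_variant(
            panel.beta[i, mask], panel.var[i, mask], axes.coords[mask],
            compute_axis_tests=compute_axis_tests,
        )
        v = panel.variants.iloc[i]
        pooled_eaf = np.nan
        eafs = panel.eaf[i, mask]
        ok = np.isfinite(eafs)
        if ok.any():
            pooled_eaf = float(np.average(eafs[ok], weights=panel.n[i, mask][ok]))
        row = {
            "MarkerName": v["marker"],
            "Chromosome": v["chromosome"],
            "Position": int(v["position"]),
            "EA": v["ea"],
            "NEA": v["nea"],
            "EAF": pooled_eaf,
            "Nsample": float(np.nansum(panel.n[i, mask])),
            "Ncohort": K_j,
            "alpha": res.alpha,
            "alpha_se": res.alpha_se,
        }
        for t in range(T):
            row[f"beta{t + 1}"] = res.beta[t]
            row[f"se{t + 1}"] = res.beta_se[t]
        row.update(
            {
                "chisq_association": res.x_assoc,
                "ndf_association": res.df_assoc,
                "P-value_association": res.p_assoc,
                "log10P_association": res.log10_p_assoc,
                "chisq_ancestry_het": res.x_het_anc,
                "ndf_ancestry_het": res.df_het_anc,
                "P-value_ancestry_het": res.p_het_anc,
                "chisq_residual_het": res.x_het_res if res.x_het_res is not None else np.nan,
                "ndf_residual_het": res.df_het_res,
                "P-value_residual_het": res.p_het_res if res.p_het_res is not None else np.nan,
                "lnBF": res.ln_bf,
            }
        )
        if compute_axis_tests:
            for t in range(T):
                row[f"chisq_axis{t + 1}"] = res.x_axis[t]
                row[f"P-value_axis{t + 1}"] = res.p_axis[t]
        rows.append(row)
    if n_skipped:
        logger.info("run_meta_regression: skipped %d variants with K_j < T+1", n_skipped)
    return pd.DataFrame(rows)


def apply_study_genomic_control(panel: StudyPanel, lambdas: np.ndarray) -> StudyPanel:
    """Study-level genomic control: inflate each study's effect variances by max(lambda_k, 1)."""
    lam = np.maximum(np.asarray(lambdas, dtype=float), 1.0)
    if lam.size != panel.n_studies:
        raise ValueError("one lambda per study required")
    out = panel.subset(np.ones(panel.n_variants, dtype=bool))
    out.var = out.var * lam[None, :]
    return out
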