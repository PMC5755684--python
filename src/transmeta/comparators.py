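"""Fixed-effects inverse-variance-weighted meta-analysis with Cochran's Q.

The standard benchmark against which the meta-regression is compared: a
single pooled allelic effect with heterogeneity assessed by Cochran's Q on
K_j - 1 degrees of freedom, plus a Wakefield-style approximate Bayes' factor
(Gaussian N(0, 0.2^2) effect prior) for fine-mapping comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class FixedEffectsResult:
    beta: float
    se: float
    z: float
    p: float
    q: float | None
    q_df: int
    p_q: float | None
    n_studies: int


def fixed_effects_ivw(betas, variances) -> FixedEffectsResult:
    """Inverse-variance-weighted pooled effect and Cochran's Q.

    b_FE = sum(w b) / sum(w), se_FE = sum(w)^(-1/2), w = 1/v;
    Q = sum w (b - b_FE)^2 ~ chi-squared on K_j - 1 df.
    With a single study the pooled values are the study's own and Q is
    unavailable.
    """
    b = np.atleast_1d(np.asarray(betas, dtype=float))
    v = np.atleast_1d(np.asarray(variances, dtype=float))
    if b.size < 1:
        raise ValueError("at least one study required")
    if np.any(v <= 0):
        raise ValueError("variances must be strictly positive")
    w = 1.0 / v
    sw = w.sum()
    b_fe = float(np.sum(w * b) / sw)
    se_fe = float(sw**-0.5)
    z = b_fe / se_fe
    p = float(2.0 * stats.norm.sf(abs(z)))
    if b.size == 1:
        return FixedEffectsResult(b_fe, se_fe, z, p, None, 0, None, 1)
    q = float(np.sum(w * (b - b_fe) ** 2))
    q_df = b.size - 1
    p_q = float(stats.chi2.sf(q, q_df))
    return FixedEffectsResult(b_fe, se_fe, z, p, q, q_df, p_q, b.size)


def fixed_effects_batch(betas: np.ndarray, variances: np.ndarray):
    """Vectorised fixed-effects pooling over (n_variants, K) arrays.

    Returns dict with beta, se, z2, p, q, p_q arrays of shape (n_variants,).
    """
    B = np.asarray(betas, dtype=float)
    V = np.asarray(variances, dtype=float)
    W = 1.0 / V
    sw = W.sum(axis=1)
    b_fe = np.einsum("nk,nk->n", W, B) / sw
    se = sw**-0.5
    z2 = (b_fe / se) ** 2
    q = np.einsum("nk,nk->n", W, (B - b_fe[:, None]) ** 2)
    K = B.shape[1]
    return {
        "beta": b_fe,
        "se": se,
        "z2": z2,
        "p": stats.chi2.sf(z2, 1),
        "q": q,
        "p_q": stats.chi2.sf(q, K - 1),
    }


def ln_abf_wakefield(beta, se, prior_sd: float = 0.2):
    """Natural-log approximate Bayes' factor for a pooled effect estimate.

    Assumes the estimate b ~ N(theta, V) with effect prior theta ~ N(0, W),
    W = prior_sd^2, giving
    ln ABF = 0.5 ln(V / (V + W)) + 0.5 z^2 W / (V + W).
    The default prior sd of 0.2 on the log-odds scale spans odds-ratios of
    roughly 0.7-1.5 at two sigma.
    """
    b = np.asarray(beta, dtype=float)
    s = np.asarray(se, dtype=float)
    V = s**2
    W = prior_sd**2
    z2 = (b / s) ** 2
    return 0.5 * np.log(V / (V + W)) + 0.5 * z2 * W / (V + W)
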