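"""Posterior probabilities and credible sets over a fine-mapping locus.

Under the assumption of a single causal variant at the locus, each variant's
Bayes' factor is normalised over all variants to a posterior probability of
driving the association; the 99% credible set is the smallest prefix of the
Bayes'-factor-ranked variants whose cumulative posterior reaches the target
mass.  All normalisation is done in log space so loci with association
chi-squared statistics in the hundreds remain exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp


@dataclass
class FineMapResult:
    """Ranked fine-mapping summary for one locus."""

    table: pd.DataFrame  # per-variant: ln_bf, posterior, cumulative, in_set, rank
    n_in_set: int
    interval: tuple[float, float] | None  # bp span of the credible set
    mass: float

    @property
    def span_bp(self) -> float | None:
        if self.interval is None:
            return None
        return self.interval[1] - self.interval[0]


def posterior_probabilities(lnbfs) -> np.ndarray:
    """Normalise per-variant log Bayes' factors to posteriors summing to one."""
    lnl = np.asarray(lnbfs, dtype=float)
    if lnl.size == 0:
        raise ValueError("empty locus")
    if not np.all(np.isfinite(lnl)):
        raise ValueError("log Bayes' factors must be finite")
    return np.exp(lnl - logsumexp(lnl))


def credible_set(posteriors, mass: float = 0.99, positions=None) -> np.ndarray:
    """Boolean membership of the minimal credible set at the given mass.

    Variants are ranked by posterior, descending; ties break on ascending
    genomic position when ``positions`` is given (input order otherwise), and
    ranked variants are included until the cumulative posterior attains or
    exceeds ``mass``.
    """
    pi = np.asarray(posteriors, dtype=float)
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    n = pi.size
    if positions is None:
        tie = np.arange(n)
    else:
        tie = np.asarray(positions)
    order = np.lexsort((tie, -pi))
    cum = np.cumsum(pi[order])
    # smallest prefix with cumulative >= mass (all variants if mass unreached)
    reached = np.flatnonzero(cum >= mass - 1e-12)
    cutoff = reached[0] if reached.size else n - 1
    members = np.zeros(n, dtype=bool)
    members[order[: cutoff + 1]] = True
    return members


def finemap_locus(
    ln_bf,
    positions=None,
    markers=None,
    mass: float = 0.99,
) -> FineMapResult:
    """Posterior probabilities, ranking and credible set for one locus."""
    lnl = np.asarray(ln_bf, dtype=float)
    pi = posterior_probabilities(lnl)
    members = credible_set(pi, mass=mass, positions=positions)
    n = lnl.size
    tie = np.arange(n) if positions is None else np.asarray(positions)
    order = np.lexsort((tie, -pi))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    cum = np.empty(n, dtype=float)
    cum[order] = np.cumsum(pi[order])
    table = pd.DataFrame(
        {
            "marker": markers if markers is not None else [f"v{i}" for i in range(n)],
            "position": tie if positions is not None else np.full(n, np.nan),
            "ln_bf": lnl,
            "posterior": pi,
            "rank": rank,
            "cumulative": cum,
            "in_set": members,
        }
    ).sort_values("rank", kind="mergesort").reset_index(drop=True)
    interval = None
    if positions is not None and members.any():
        pos = np.asarray(positions, dtype=float)[members]
        interval = (float(pos.min()), float(pos.max()))
    return FineMapResult(table=table, n_in_set=int(members.sum()), interval=interval, mass=mass)
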