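"""Synthetic multi-population GWAS engine and experiment runners.

The generator emulates the study conditions of a 26-population, 5-ancestry-
group reference panel (African, Admixed/Native American, East Asian, European,
South Asian — population codes follow the 1000 Genomes Phase 3 naming):

* allele frequencies drift from an ancestral value under a hierarchical
  Balding–Nichols model (between-group and within-group F_ST);
* case-control genotypes are sampled retrospectively under Hardy–Weinberg
  equilibrium with a population-specific allelic odds-ratio psi, so the
  per-population additive log-odds ratio is identifiable as ln(psi);
* fine-mapping loci carry population-specific LD via Li–Stephens-style mosaic
  copying from group-bottlenecked subsamples of a shared ancestral haplotype
  panel;
* experiment runners measure false-positive rate / power of the
  meta-regression and fixed-effects tests, and calibration of 99% credible
  sets (set size, causal posterior, coverage).

All randomness flows from a single experiment seed through named
``numpy.random.SeedSequence`` substreams, so any replicate is reproducible in
isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import comparators
from .ancestry_axes import derive_axes, distance_matrix_from_frequencies
from .finemap import credible_set, posterior_probabilities
from .meta_regression import ln_bayes_factor, wls_stats_batch

logger = logging.getLogger(__name__)

#: 26 populations in five ancestry groups (1000 Genomes Phase 3 naming).
POPULATIONS: tuple[tuple[str, str], ...] = (
    ("ACB", "AFR"), ("ASW", "AFR"), ("ESN", "AFR"), ("GWD", "AFR"),
    ("LWK", "AFR"), ("MSL", "AFR"), ("YRI", "AFR"),
    ("CLM", "AMR"), ("MXL", "AMR"), ("PEL", "AMR"), ("PUR", "AMR"),
    ("CDX", "EAS"), ("CHB", "EAS"), ("CHS", "EAS"), ("JPT", "EAS"),
    ("KHV", "EAS"),
    ("CEU", "EUR"), ("FIN", "EUR"), ("GBR", "EUR"), ("IBS", "EUR"),
    ("TSI", "EUR"),
    ("BEB", "SAS"), ("GIH", "SAS"), ("ITU", "SAS"), ("PJL", "SAS"),
    ("STU", "SAS"),
)
GROUP_ORDER = ("AFR", "AMR", "EAS", "EUR", "SAS")

#: default hierarchical drift emulating the 1000G panel.  Between-group drift
#: is per-group (star approximation: pairwise group F_ST ~ sum of the two
#: branch lengths), strongly unequal as in real continental data — AFR and the
#: Native-American component of AMR are the most drifted.  Unequal drift is
#: what lets three MDS axes separate all five groups; with symmetric drift the
#: group means form a near-regular simplex and one group contrast is lost.
DEFAULT_FST_BETWEEN: dict[str, float] = {
    "AFR": 0.10,
    "AMR": 0.08,
    "EAS": 0.06,
    "EUR": 0.035,
    "SAS": 0.035,
}
DEFAULT_FST_WITHIN = 0.02

SCENARIO_NAMES = (
    "null",
    "homogeneous",
    "african_specific",
    "eurasian",
    "native_american",
    "non_ancestral",
)


def default_groups() -> np.ndarray:
    """Group label per population, in panel order."""
    return np.array([g for _, g in POPULATIONS])


def default_population_codes() -> np.ndarray:
    return np.array([c for c, _ in POPULATIONS])


@dataclass
class ScenarioSpec:
    """Population-specific odds-ratios psi defining a heterogeneity scenario."""

    name: str
    populations: np.ndarray
    groups: np.ndarray
    psi: np.ndarray

    def __post_init__(self):
        self.populations = np.asarray(self.populations)
        self.groups = np.asarray(self.groups)
        self.psi = np.asarray(self.psi, dtype=float)
        if not (len(self.populations) == len(self.groups) == len(self.psi)):
            raise ValueError("populations, groups and psi must have equal length")
        if np.any(self.psi <= 0):
            raise ValueError("odds-ratios must be strictly positive")
        self._check_constraints()

    def _check_constraints(self):
        g = self.groups
        if self.name == "null" and not np.all(self.psi == 1.0):
            raise ValueError("null scenario requires psi = 1 everywhere")
        if self.name == "homogeneous" and len(np.unique(self.psi)) != 1:
            raise ValueError("homogeneous scenario requires a single psi")
        if self.name == "african_specific" and np.any(self.psi[g != "AFR"] != 1.0):
            raise ValueError("african_specific requires psi = 1 outside AFR")
        if self.name == "eurasian" and np.any(self.psi[g == "AFR"] != 1.0):
            raise ValueError("eurasian requires no effect in AFR")
        if self.name == "native_american" and np.any(self.psi[g != "AMR"] != 1.0):
            raise ValueError("native_american requires psi = 1 outside AMR")

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    @classmethod
    def from_name(cls, name: str, psi: float | None = None, rng=None) -> "ScenarioSpec":
        """Build one of the named heterogeneity scenarios.

        ``psi`` overrides the scenario's default effect magnitude where one
        applies; ``rng`` is required for the scenarios whose psi vector is
        itself random (native_american, non_ancestral) and is drawn once, so
        the vector is fixed for the whole experiment.
        """
        pops = default_population_codes()
        groups = default_groups()
        K = len(pops)
        vec = np.ones(K)
        if name == "null":
            pass
        elif name == "homogeneous":
            vec[:] = 1.10 if psi is None else psi
        elif name == "african_specific":
            vec[groups == "AFR"] = 1.25 if psi is None else psi
        elif name == "eurasian":
            base = 1.10 if psi is None else psi
            vec[groups == "EAS"] = base
            for g in ("EUR", "SAS", "AMR"):
                vec[groups == g] = np.sqrt(base)
        elif name == "native_american":
            if rng is None:
                raise ValueError("native_american psi vector is random; pass rng")
            amr = groups == "AMR"
            vec[amr] = rng.uniform(1.15, 1.30, size=int(amr.sum()))
        elif name == "non_ancestral":
            if rng is None:
                raise ValueError("non_ancestral psi vector is random; pass rng")
            base = 1.35 if psi is None else psi
            for g in GROUP_ORDER:
                idx = np.flatnonzero(groups == g)
                vec[rng.choice(idx)] = base
        else:
            raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
        return cls(name=name, populations=pops, groups=groups, psi=vec)


@dataclass
class PopulationFrequencies:
    """Drifted per-population allele frequencies for a set of markers."""

    ancestral: np.ndarray  # (n_markers,)
    group_freq: np.ndarray  # (n_markers, n_groups)
    pop_freq: np.ndarray  # (n_markers, K)
    groups: np.ndarray
    fst_between: np.ndarray  # per-group
    fst_within: float


def _balding_nichols(rng, mean: np.ndarray, fst) -> np.ndarray:
    """Beta draw with the given mean and variance fst * mean * (1 - mean).

    ``fst`` may be a scalar or broadcast against ``mean`` (e.g. one value per
    group column); entries with fst = 0 pass the mean through undrifted.
    """
    fst = np.broadcast_to(np.asarray(fst, dtype=float), mean.shape)
    m = np.clip(mean, 1e-9, 1 - 1e-9)
    with np.errstate(divide="ignore"):
        scale = np.where(fst > 0, (1.0 - fst) / np.where(fst > 0, fst, 1.0), np.inf)
    out = np.where(fst > 0, rng.beta(np.where(fst > 0, m * scale, 1.0),
                                     np.where(fst > 0, (1.0 - m) * scale, 1.0)), m)
    return out


def _fst_between_vector(fst_between, group_labels: np.ndarray) -> np.ndarray:
    """Normalise the between-group drift spec to one value per group label."""
    if isinstance(fst_between, dict):
        try:
            return np.array([float(fst_between[g]) for g in group_labels])
        except KeyError as e:
            raise ValueError(f"fst_between mapping is missing group {e}") from None
    arr = np.asarray(fst_between, dtype=float)
    if arr.ndim == 0:
        return np.full(group_labels.size, float(arr))
    if arr.size != group_labels.size:
        raise ValueError("fst_between must be scalar, per-group array, or mapping")
    return arr


def draw_population_frequencies(
    rng,
    n_markers: int = 1,
    groups: np.ndarray | None = None,
    fst_between=None,
    fst_within: float = DEFAULT_FST_WITHIN,
    min_maf: float = 0.01,
    max_attempts: int = 10_000,
) -> PopulationFrequencies:
    """Hierarchical Balding–Nichols frequencies with MAF rejection sampling.

    For each marker the ancestral frequency is Uniform(0.05, 0.95); each
    ancestry group drifts around it with variance fst_between * p0 * (1 - p0)
    (``fst_between`` may be a scalar, a per-group array, or a group->value
    mapping; the default is the unequal 1000G-like drift), and each population
    drifts around its group value with ``fst_within``.  Markers are redrawn
    until the MAF exceeds ``min_maf`` in every population.
    """
    groups = default_groups() if groups is None else np.asarray(groups)
    group_labels, group_idx = np.unique(groups, return_inverse=True)
    G = len(group_labels)
    if fst_between is None:
        fst_between = DEFAULT_FST_BETWEEN if set(group_labels) <= set(GROUP_ORDER) else 0.08
    fst_b = _fst_between_vector(fst_between, group_labels)
    if np.any(fst_b < 0) or np.any(fst_b >= 1) or not 0 <= fst_within < 1:
        raise ValueError("fst parameters must lie in [0, 1)")

    anc, grp, pop = [], [], []
    remaining = n_markers
    attempts = 0
    while remaining > 0:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"frequency rejection sampling failed after {max_attempts} attempts"
            )
        m = max(2 * remaining, 16)
        p0 = rng.uniform(0.05, 0.95, size=m)
        pg = _balding_nichols(rng, np.repeat(p0[:, None], G, axis=1), fst_b[None, :])
        pk = _balding_nichols(rng, pg[:, group_idx], fst_within)
        maf = np.minimum(pk, 1.0 - pk)
        ok = (maf > min_maf).all(axis=1)
        take = np.flatnonzero(ok)[:remaining]
        anc.append(p0[take])
        grp.append(pg[take])
        pop.append(pk[take])
        remaining -= take.size
    return PopulationFrequencies(
        ancestral=np.concatenate(anc),
        group_freq=np.concatenate(grp),
        pop_freq=np.concatenate(pop),
        groups=groups,
        fst_between=fst_b,
        fst_within=fst_within,
    )


def hwe_probs(freq) -> np.ndarray:
    """Hardy–Weinberg genotype probabilities for the effect-allele dose 0/1/2."""
    p = np.asarray(freq, dtype=float)
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=-1)


def case_genotype_probs(freq, psi) -> np.ndarray:
    """Retrospective case genotype distribution: HWE tilted by psi^g.

    Under rare-disease retrospective sampling the probability that a case
    carries genotype g is proportional to HWE(p)[g] * psi^g, which makes the
    additive log-odds ratio equal to ln(psi) exactly.
    """
    probs = hwe_probs(freq) * np.power(np.asarray(psi, dtype=float)[..., None], np.arange(3))
    return probs / probs.sum(axis=-1, keepdims=True)


def simulate_case_control(freq, psi, n_cases: int, n_controls: int, rng):
    """Multinomial genotype counts for one or many case-control cohorts.

    Returns ``(case_counts, control_counts)`` with trailing axis over the
    genotype dose 0/1/2; leading axes broadcast over ``freq`` and ``psi``.
    """
    ctrl = rng.multinomial(n_controls, hwe_probs(freq))
    case = rng.multinomial(n_cases, case_genotype_probs(freq, psi))
    return case, ctrl


def logistic_fit_counts(case_counts, control_counts, max_iter: int = 40, tol: float = 1e-10):
    """Vectorised additive logistic regression from 2x3 genotype count tables.

    Fits P(case | g) = logit^-1(a + b g) by Newton-Raphson on the two-parameter
    likelihood, batched over any leading shape.  Returns ``(beta, se, valid)``;
    invalid fits (monomorphic genotype, complete separation, non-convergence)
    carry NaN and ``valid=False``.
    """
    C = np.asarray(case_counts, dtype=float)
    D = np.asarray(control_counts, dtype=float)
    g = np.arange(3.0)
    total = C + D
    n = total.sum(axis=-1)
    ncase = C.sum(axis=-1)

    # genotype variance must be positive and cases/controls both present
    gbar = (total * g).sum(axis=-1) / n
    gvar = (total * g**2).sum(axis=-1) / n - gbar**2
    usable = (gvar > 0) & (ncase > 0) & (n - ncase > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.log(ncase / (n - ncase))
    a = np.where(usable, a, 0.0)
    b = np.zeros_like(a)
    converged = np.zeros(a.shape, dtype=bool)

    for _ in range(max_iter):
        eta = a[..., None] + b[..., None] * g
        mu = 1.0 / (1.0 + np.exp(-eta))
        resid = C - total * mu
        ga = resid.sum(axis=-1)
        gb = (resid * g).sum(axis=-1)
        w = total * mu * (1.0 - mu)
        iaa = w.sum(axis=-1)
        iab = (w * g).sum(axis=-1)
        ibb = (w * g**2).sum(axis=-1)
        det = iaa * ibb - iab**2
        ok = usable & (det > 1e-12) & ~converged
        da = np.where(ok, (ibb * ga - iab * gb) / np.where(det > 0, det, 1.0), 0.0)
        db = np.where(ok, (iaa * gb - iab * ga) / np.where(det > 0, det, 1.0), 0.0)
        a = a + da
        b = b + db
        converged = converged | (ok & (np.abs(da) < tol) & (np.abs(db) < tol))
        if converged[usable].all() if usable.any() else True:
            break

    eta = a[..., None] + b[..., None] * g
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = total * mu * (1.0 - mu)
    iaa = w.sum(axis=-1)
    iab = (w * g).sum(axis=-1)
    ibb = (w * g**2).sum(axis=-1)
    det = iaa * ibb - iab**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b = iaa / det
    valid = usable & converged & (det > 1e-12) & np.isfinite(b) & (np.abs(b) < 10) & (var_b > 0)
    beta = np.where(valid, b, np.nan)
    se = np.where(valid, np.sqrt(np.where(valid, var_b, 1.0)), np.nan)
    return beta, se, valid


def logistic_association(case_counts, control_counts):
    """Additive logistic fit for a single cohort's 2x3 genotype table.

    Returns ``(beta, se)``; both NaN when the fit is unavailable (constant
    genotype or separation), in which case the replicate should be flagged.
    """
    beta, se, valid = logistic_fit_counts(np.asarray(case_counts), np.asarray(control_counts))
    if not np.all(valid):
        return np.nan, np.nan
    return float(beta), float(se)


# ---------------------------------------------------------------------------
# locus haplotype generator


@dataclass
class LocusPools:
    """Per-population haplotype pools over a fine-mapping locus."""

    positions: np.ndarray  # (n_variants,) bp
    haplotypes: np.ndarray  # (K, pool_size, n_variants) 0/1
    causal_index: int
    populations: np.ndarray
    groups: np.ndarray

    @property
    def n_variants(self) -> int:
        return self.positions.size

    def frequencies(self) -> np.ndarray:
        """(K, n_variants) effect-allele frequencies of the pools."""
        return self.haplotypes.mean(axis=1)


def _ancestral_panel(rng, freqs, positions, panel_size, ld_scale):
    """Threshold a per-haplotype AR(1) Gaussian to Bernoulli(f_j) with
    distance-decaying correlation — a first-order Markov chain over sites."""
    m = freqs.size
    z = np.empty((panel_size, m))
    z[:, 0] = rng.standard_normal(panel_size)
    gaps = np.diff(positions)
    rho = np.exp(-gaps / ld_scale)
    eps = rng.standard_normal((panel_size, m - 1))
    for j in range(1, m):
        r = rho[j - 1]
        z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * eps[:, j - 1]
    thresh = stats.norm.ppf(freqs)
    return (z < thresh).astype(np.uint8)


def _mosaic_copy(rng, templates, n_haps, positions, switch_rate):
    """Li–Stephens-style mosaic: copy from a random template, switching to a
    fresh template between adjacent sites with probability 1 - exp(-rate*gap)."""
    B, m = templates.shape
    t = rng.integers(0, B, size=(n_haps, m))
    if m > 1:
        p_switch = 1.0 - np.exp(-switch_rate * np.diff(positions))
        keep = rng.random((n_haps, m - 1)) >= p_switch
        for j in range(1, m):
            t[:, j] = np.where(keep[:, j - 1], t[:, j - 1], t[:, j])
    return templates[t, np.arange(m)]


def simulate_locus(
    rng,
    n_variants: int = 64,
    locus_length: float = 1_000_000.0,
    panel_size: int = 200,
    bottleneck: int = 12,
    pool_size: int = 240,
    switch_rate: float = 1e-5,
    ld_scale: float = 100_000.0,
    groups: np.ndarray | None = None,
    min_maf: float = 0.01,
    max_attempts: int = 200,
) -> LocusPools:
    """Generate per-population haplotype pools with group-differentiated LD.

    An ancestral haplotype panel is built site-by-site with distance-decaying
    allelic correlation; each ancestry group takes a bottlenecked subsample of
    ``bottleneck`` panel haplotypes, and each population draws ``pool_size``
    haplotypes by mosaic copying over its group's subsample.  The causal
    variant sits mid-locus and the whole locus is redrawn until its MAF
    exceeds ``min_maf`` in every population.  ``bottleneck`` controls the
    realised between-group drift (F_ST ~ 1 / bottleneck); ``switch_rate`` = 0
    with ``bottleneck`` = ``panel_size`` reduces populations to copies of the
    ancestral panel with identical LD.
    """
    if n_variants < 2:
        raise ValueError("a locus needs at least 2 variants")
    groups = default_groups() if groups is None else np.asarray(groups)
    group_labels = np.unique(groups)
    causal_index = n_variants // 2

    for _ in range(max_attempts):
        positions = np.sort(rng.uniform(0.0, locus_length, size=n_variants))
        freqs = rng.uniform(0.05, 0.95, size=n_variants)
        panel = _ancestral_panel(rng, freqs, positions, panel_size, ld_scale)
        K = groups.size
        haps = np.empty((K, pool_size, n_variants), dtype=np.uint8)
        for glab in group_labels:
            if bottleneck >= panel_size:
                sub = panel
            else:
                sub = panel[rng.choice(panel_size, size=bottleneck, replace=False)]
            for k in np.flatnonzero(groups == glab):
                haps[k] = _mosaic_copy(rng, sub, pool_size, positions, switch_rate)
        causal_freq = haps[:, :, causal_index].mean(axis=1)
        if np.all(np.minimum(causal_freq, 1 - causal_freq) > min_maf):
            return LocusPools(
                positions=positions,
                haplotypes=haps,
                causal_index=causal_index,
                populations=default_population_codes() if K == len(POPULATIONS) else np.arange(K),
                groups=groups,
            )
    raise RuntimeError(f"could not draw a locus with causal MAF > {min_maf} everywhere")


def sample_locus_cohorts(pools: LocusPools, psi, n_cases: int, n_controls: int, rng):
    """Retrospective case-control sampling from the haplotype pools.

    Individuals are random haplotype pairs; cases are drawn with probability
    proportional to psi^g at the causal variant.  Returns per-population
    genotype count tables of shape (K, n_variants, 3) for cases and controls.
    """
    K, H, m = pools.haplotypes.shape
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (K,))
    case_counts = np.empty((K, m, 3), dtype=np.int64)
    ctrl_counts = np.empty((K, m, 3), dtype=np.int64)
    g_range = np.arange(3)
    n_candidates = 4 * n_cases
    for k in range(K):
        hap = pools.haplotypes[k]
        ctrl_g = (
            hap[rng.integers(0, H, size=n_controls)] + hap[rng.integers(0, H, size=n_controls)]
        )
        cand = rng.integers(0, H, size=(n_candidates, 2))
        g_causal = (
            hap[cand[:, 0], pools.causal_index] + hap[cand[:, 1], pools.causal_index]
        ).astype(float)
        wts = np.power(psi[k], g_causal)
        pick = rng.choice(n_candidates, size=n_cases, replace=True, p=wts / wts.sum())
        case_g = hap[cand[pick, 0]] + hap[cand[pick, 1]]
        case_counts[k] = (case_g[:, :, None] == g_range).sum(axis=0)
        ctrl_counts[k] = (ctrl_g[:, :, None] == g_range).sum(axis=0)
    return case_counts, ctrl_counts


# ---------------------------------------------------------------------------
# experiment runners


def _experiment_axes(rng, groups, T, n_distance_markers, fst_between, fst_within):
    """Genome-wide axes of variation for an experiment: distance matrix over a
    thinned marker panel (MAF >= 5% in all populations), then classical MDS."""
    freqs = draw_population_frequencies(
        rng,
        n_markers=n_distance_markers,
        groups=groups,
        fst_between=fst_between,
        fst_within=fst_within,
        min_maf=0.05,
    )
    D = distance_matrix_from_frequencies(freqs.pop_freq, list(default_population_codes()))
    return derive_axes(D, T)


def _rate_row(test, threshold, hits, n):
    rate = hits / n if n else np.nan
    se = np.sqrt(rate * (1 - rate) / n) if n else np.nan
    return {
        "test": test,
        "threshold": threshold,
        "n": n,
        "n_reject": int(hits),
        "rate": rate,
        "mc_se": se,
    }


@dataclass
class PowerExperimentResult:
    scenario: ScenarioSpec
    n_replicates: int
    n_used: int
    n_dropped: int
    rates: pd.DataFrame
    pvalues: dict = field(repr=False, default_factory=dict)

    def rate(self, test: str, threshold: float) -> float:
        tab = self.rates
        row = tab[(tab["test"] == test) & (tab["threshold"] == threshold)]
        return float(row["rate"].iloc[0])


def run_power_experiment(
    scenario: ScenarioSpec | str,
    n_replicates: int,
    rng_seed: int,
    T: int = 3,
    n_cases: int = 1000,
    n_controls: int = 1000,
    alpha: float = 0.05,
    gw_alpha: float = 5e-8,
    n_distance_markers: int = 2000,
    fst_between=None,
    fst_within: float = DEFAULT_FST_WITHIN,
) -> PowerExperimentResult:
    """Single-variant rejection-rate experiment.

    Per replicate: drifted causal allele frequencies (MAF > 1% everywhere),
    HWE case-control genotype counts under the scenario's odds-ratios, a
    per-population additive logistic fit, then the meta-regression (T axes)
    and fixed-effects aggregations.  Axes are derived once per experiment from
    an independent genome-wide marker panel, mirroring their role as global
    study properties.  Rejection proportions are reported at the nominal
    (``alpha``) and genome-wide (``gw_alpha``) thresholds with binomial
    Monte-Carlo standard errors; replicates with any failed logistic fit are
    dropped and counted.
    """
    ss = np.random.SeedSequence(rng_seed)
    s_scen, s_axes, s_freq, s_geno = ss.spawn(4)
    if isinstance(scenario, str):
        scenario = ScenarioSpec.from_name(scenario, rng=np.random.default_rng(s_scen))
    groups = scenario.groups
    K = scenario.n_pops

    axes = _experiment_axes(
        np.random.default_rng(s_axes), groups, T, n_distance_markers, fst_between, fst_within
    )

    freq_rng = np.random.default_rng(s_freq)
    freqs = draw_population_frequencies(
        freq_rng,
        n_markers=n_replicates,
        groups=groups,
        fst_between=fst_between,
        fst_within=fst_within,
        min_maf=0.01,
    )
    geno_rng = np.random.default_rng(s_geno)
    case, ctrl = simulate_case_control(
        freqs.pop_freq, scenario.psi[None, :], n_cases, n_controls, geno_rng
    )
    beta, se, valid = logistic_fit_counts(case, ctrl)
    used = valid.all(axis=1)
    n_used = int(used.sum())
    n_dropped = n_replicates - n_used
    if n_dropped:
        logger.info("run_power_experiment: dropped %d replicates with failed fits", n_dropped)
    B, V = beta[used], se[used] ** 2

    mr = wls_stats_batch(B, V, axes.coords)
    p_assoc = stats.chi2.sf(mr["x_assoc"], T + 1)
    p_het_anc = stats.chi2.sf(mr["x_het_anc"], T)
    p_het_res = stats.chi2.sf(mr["x_het_res"], K - T - 1)
    fe = comparators.fixed_effects_batch(B, V)

    rows = [
        _rate_row("mr_association", alpha, (p_assoc < alpha).sum(), n_used),
        _rate_row("mr_association", gw_alpha, (p_assoc < gw_alpha).sum(), n_used),
        _rate_row("fe_association", alpha, (fe["p"] < alpha).sum(), n_used),
        _rate_row("fe_association", gw_alpha, (fe["p"] < gw_alpha).sum(), n_used),
        _rate_row("mr_ancestry_het", alpha, (p_het_anc < alpha).sum(), n_used),
        _rate_row("mr_residual_het", alpha, (p_het_res < alpha).sum(), n_used),
        _rate_row("cochran_q", alpha, (fe["p_q"] < alpha).sum(), n_used),
    ]
    return PowerExperimentResult(
        scenario=scenario,
        n_replicates=n_replicates,
        n_used=n_used,
        n_dropped=n_dropped,
        rates=pd.DataFrame(rows),
        pvalues={
            "mr_association": p_assoc,
            "fe_association": fe["p"],
            "mr_ancestry_het": p_het_anc,
            "mr_residual_het": p_het_res,
            "cochran_q": fe["p_q"],
        },
    )


@dataclass
class FinemapExperimentResult:
    scenario: ScenarioSpec
    n_replicates: int
    n_used: int
    n_dropped: int
    metrics: pd.DataFrame
    per_replicate: dict = field(repr=False, default_factory=dict)

    def metric(self, method: str, name: str) -> float:
        tab = self.metrics
        return float(tab.loc[tab["method"] == method, name].iloc[0])


def run_finemap_experiment(
    scenario: ScenarioSpec | str,
    n_replicates: int,
    rng_seed: int,
    T: int = 3,
    n_variants: int = 64,
    n_cases: int = 1000,
    n_controls: int = 1000,
    mass: float = 0.99,
    locus_length: float = 1_000_000.0,
    n_distance_markers: int = 2000,
    fst_between=None,
    fst_within: float = DEFAULT_FST_WITHIN,
    **locus_kwargs,
) -> FinemapExperimentResult:
    """Fine-mapping calibration experiment on single-causal-variant loci.

    Per replicate: a locus of ``n_variants`` with population-specific LD from
    the mosaic haplotype generator, retrospective phenotype sampling on the
    causal genotype, per-population per-variant logistic fits, then for each
    method (meta-regression with T axes; fixed-effects with Wakefield
    approximate Bayes' factors) posterior probabilities and the 99% credible
    set.  Reports the median credible-set size, mean posterior on the causal
    variant, and coverage (fraction of replicates whose set holds the causal
    variant).  Variants with failed fits in some populations are retained on
    the fitting subset; replicates where the causal variant itself cannot be
    aggregated are dropped and counted.
    """
    ss = np.random.SeedSequence(rng_seed)
    s_scen, s_axes, *rep_seeds = ss.spawn(2 + n_replicates)
    if isinstance(scenario, str):
        scenario = ScenarioSpec.from_name(scenario, rng=np.random.default_rng(s_scen))
    groups = scenario.groups
    K = scenario.n_pops

    axes = _experiment_axes(
        np.random.default_rng(s_axes), groups, T, n_distance_markers, fst_between, fst_within
    )

    methods = ("meta_regression", "fixed_effects")
    sizes = {m: [] for m in methods}
    causal_post = {m: [] for m in methods}
    covered = {m: [] for m in methods}
    n_dropped = 0

    for rs in rep_seeds:
        rng = np.random.default_rng(rs)
        pools = simulate_locus(
            rng,
            n_variants=n_variants,
            locus_length=locus_length,
            groups=groups,
            **locus_kwargs,
        )
        case, ctrl = sample_locus_cohorts(pools, scenario.psi, n_cases, n_controls, rng)
        beta, se, valid = logistic_fit_counts(case, ctrl)  # (K, m)
        B = beta.T.copy()  # (m, K)
        V = (se**2).T.copy()
        ok = valid.T
        k_j = ok.sum(axis=1)
        keep = k_j >= T + 2
        if not keep[pools.causal_index]:
            n_dropped += 1
            continue
        # absent fits enter with zero weight; K_j tracks the true subset size
        B = np.where(ok, B, 0.0)
        V = np.where(ok, V, np.inf)
        B, V, k_j = B[keep], V[keep], k_j[keep]
        positions = pools.positions[keep]
        causal = int(np.flatnonzero(np.flatnonzero(keep) == pools.causal_index)[0])

        mr = wls_stats_batch(B, V, axes.coords)
        lnbf = {
            "meta_regression": ln_bayes_factor(mr["x_assoc"], T, k_j),
        }
        fe = comparators.fixed_effects_batch(B, V)
        lnbf["fixed_effects"] = comparators.ln_abf_wakefield(fe["beta"], fe["se"])

        for m in methods:
            pi = posterior_probabilities(lnbf[m])
            members = credible_set(pi, mass=mass, positions=positions)
            sizes[m].append(int(members.sum()))
            causal_post[m].append(float(pi[causal]))
            covered[m].append(bool(members[causal]))

    n_used = n_replicates - n_dropped
    rows = []
    for m in methods:
        cov = np.mean(covered[m]) if n_used else np.nan
        rows.append(
            {
                "method": m,
                "n": n_used,
                "median_set_size": float(np.median(sizes[m])) if n_used else np.nan,
                "mean_causal_posterior": float(np.mean(causal_post[m])) if n_used else np.nan,
                "coverage": float(cov),
                "coverage_mc_se": float(np.sqrt(cov * (1 - cov) / n_used)) if n_used else np.nan,
            }
        )
    return FinemapExperimentResult(
        scenario=scenario,
        n_replicates=n_replicates,
        n_used=n_used,
        n_dropped=n_dropped,
        metrics=pd.DataFrame(rows),
        per_replicate={
            "set_size": {m: np.array(sizes[m]) for m in methods},
            "causal_posterior": {m: np.array(causal_post[m]) for m in methods},
            "covered": {m: np.array(covered[m]) for m in methods},
        },
    )
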