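"""Axes of genetic variation from between-study allele-frequency distances.

The distance between two studies is the root mean squared difference of their
effect-allele frequencies over a thinned set of common markers (one marker
with MAF >= 5% in every study per 1 Mb bin, to blunt the effect of LD).
Classical (Torgerson) multi-dimensional scaling of the distance matrix yields
up to K-2 axes that place each study in a low-dimensional ancestry space;
these axes are the covariates of the meta-regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .sumstats_io import StudyPanel

logger = logging.getLogger(__name__)


class AxesError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """K x K symmetric matrix of between-study allele-frequency distances."""

    matrix: np.ndarray
    studies: list[str]
    n_markers: int
    #: True when entries are root mean squared differences (Euclidean scale);
    #: False when the raw mean squared difference variant was requested.
    root_scale: bool = True

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise AxesError("distance matrix must be square")
        if not np.allclose(m, m.T):
            raise AxesError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise AxesError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise AxesError("distances must be finite and non-negative")
        self.matrix = m

    @property
    def n_studies(self) -> int:
        return self.matrix.shape[0]

    def squared(self) -> np.ndarray:
        """Mean squared frequency differences, whichever scale is stored."""
        return self.matrix**2 if self.root_scale else self.matrix


@dataclass
class AxesOfVariation:
    """K x T study coordinates from classical scaling, plus the eigenvalue spectrum.

    Columns are ordered by decreasing eigenvalue, mean-centred by construction
    of the double-centring, and sign-fixed so the entry of largest magnitude
    in each column is positive.
    """

    coords: np.ndarray
    eigenvalues: np.ndarray
    studies: list[str]

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]

    def rows(self, indices) -> np.ndarray:
        return self.coords[np.asarray(indices)]


def select_distance_markers(
    panel: StudyPanel, bin_size: int = 1_000_000, min_maf: float = 0.05
) -> np.ndarray:
    """Pick at most one marker per genomic bin for the distance calculation.

    A marker qualifies when it is present, with a known frequency, in every
    study and has MAF >= ``min_maf`` in every study.  Within a bin the
    qualifying marker nearest the bin midpoint is taken (ties to the lower
    position), which keeps the selection deterministic while spacing markers
    roughly ``bin_size`` apart.

    Returns a boolean indicator array over the panel's variants.
    """
    eaf = panel.eaf
    known = panel.present & np.isfinite(eaf)
    all_present = known.all(axis=1)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(eaf, 1.0 - eaf)
        maf_ok = np.where(known, maf >= min_maf, False).all(axis=1)
    qualifying = all_present & maf_ok

    indicator = np.zeros(panel.n_variants, dtype=bool)
    pos = panel.variants["position"].to_numpy()
    chrom = panel.variants["chromosome"].to_numpy()
    bins = pos // bin_size
    midpoint = (bins + 0.5) * bin_size
    dist_to_mid = np.abs(pos - midpoint)

    import pandas as pd

    qual_idx = np.flatnonzero(qualifying)
    if qual_idx.size == 0:
        raise AxesError(
            "no qualifying distance markers: relax --min-maf or check that "
            "frequencies are present in all studies"
        )
    order = pd.DataFrame(
        {
            "chrom": chrom[qual_idx],
            "bin": bins[qual_idx],
            "d": dist_to_mid[qual_idx],
            "pos": pos[qual_idx],
            "idx": qual_idx,
        }
    ).sort_values(["chrom", "bin", "d", "pos"], kind="mergesort")
    chosen = order.groupby(["chrom", "bin"], sort=False)["idx"].first().to_numpy()
    indicator[chosen] = True
    logger.info(
        "select_distance_markers: %d markers from %d qualifying variants",
        indicator.sum(),
        qualifying.sum(),
    )
    return indicator


def distance_matrix_from_frequencies(
    freqs: np.ndarray, studies: list[str] | None = None, root: bool = True
) -> DistanceMatrix:
    """Distance matrix from an (n_markers, K) frequency array.

    d_kk' = sqrt( mean_j (p_kj - p_k'j)^2 ) when ``root`` (the default,
    Euclidean scale); the raw mean squared difference otherwise.
    """
    P = np.asarray(freqs, dtype=float)
    if P.ndim != 2:
        raise AxesError("frequency array must be 2-D (markers x studies)")
    if not np.all(np.isfinite(P)):
        raise AxesError("missing frequency among selected markers")
    K = P.shape[1]
    diff = P[:, :, None] - P[:, None, :]
    msd = np.mean(diff**2, axis=0)
    np.fill_diagonal(msd, 0.0)
    msd = 0.5 * (msd + msd.T)
    mat = np.sqrt(msd) if root else msd
    return DistanceMatrix(
        matrix=mat,
        studies=list(studies) if studies is not None else [f"S{k}" for k in range(K)],
        n_markers=P.shape[0],
        root_scale=root,
    )


def compute_distance_matrix(
    panel: StudyPanel, markers: np.ndarray, root: bool = True
) -> DistanceMatrix:
    """Distance matrix over the panel's studies using the selected markers."""
    markers = np.asarray(markers, dtype=bool)
    if markers.sum() == 0:
        raise AxesError("no markers selected")
    return distance_matrix_from_frequencies(panel.eaf[markers], panel.studies, root=root)


def derive_axes(D: DistanceMatrix, T: int) -> AxesOfVariation:
    """Classical multi-dimensional scaling of the distance matrix to T axes.

    Double-centres -0.5 * D^2, eigendecomposes, and scales the leading
    eigenvectors by the square roots of their eigenvalues.  T is limited to
    K-2 so that the residual-heterogeneity test keeps at least one degree of
    freedom.
    """
    K = D.n_studies
    if not 1 <= T <= K - 2:
        raise AxesError(f"T must satisfy 1 <= T <= K-2 = {K - 2}, got {T}")
    B = -0.5 * D.squared()
    J = np.eye(K) - np.ones((K, K)) / K
    B = J @ B @ J
    eigval, eigvec = linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(K, 1) * np.finfo(float).eps * max(abs(eigval[0]), 1.0)
    n_pos = int(np.sum(eigval > tol))
    if n_pos < T:
        raise AxesError(
            f"only {n_pos} positive eigenvalues in the scaling solution; reduce T below {T}"
        )
    coords = eigvec[:, :T] * np.sqrt(eigval[:T])
    # deterministic sign: entry of largest magnitude in each column positive
    for t in range(T):
        j = np.argmax(np.abs(coords[:, t]))
        if coords[j, t] < 0:
            coords[:, t] = -coords[:, t]
    return AxesOfVariation(coords=coords, eigenvalues=eigval, studies=list(D.studies))
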