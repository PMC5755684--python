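"""Reading, validation and cross-study harmonisation of GWAS summary statistics.

Each contributing study supplies a whitespace- or tab-delimited flat file with
one row per variant and columns for marker name, chromosome, position, effect
and other allele, effect-allele frequency, sample size, allelic effect and its
standard error.  Studies are merged on (chromosome, position, allele pair) and
aligned to a common effect allele; rows whose alleles cannot be reconciled are
dropped with a reason recorded in a per-file QC report.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order expected after renaming
REQUIRED_COLUMNS = (
    "MARKERNAME",
    "CHROMOSOME",
    "POSITION",
    "EA",
    "NEA",
    "EAF",
    "N",
    "BETA",
    "SE",
)

_CANONICAL = {
    "MARKERNAME": "marker",
    "CHROMOSOME": "chromosome",
    "POSITION": "position",
    "EA": "ea",
    "NEA": "nea",
    "EAF": "eaf",
    "N": "n",
    "BETA": "beta",
    "SE": "se",
}

_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


class SummaryStatsError(ValueError):
    """Fatal configuration or validation problem in a summary-statistics file."""


@dataclass
class QCReport:
    """Per-file accounting of rows read and rows dropped, by reason."""

    rows_read: int = 0
    rows_kept: int = 0
    dropped: Counter = field(default_factory=Counter)

    @property
    def rows_dropped(self) -> int:
        return sum(self.dropped.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("rows_read", self.rows_read), ("rows_kept", self.rows_kept)]
        rows += [(f"dropped_{reason}", n) for reason, n in sorted(self.dropped.items())]
        return pd.DataFrame(rows, columns=["item", "count"])


@dataclass
class StudyTable:
    """Validated per-study summary statistics.

    ``data`` holds canonical columns: marker, chromosome, position, ea, nea,
    eaf, n, beta, se, plus a boolean ``strand_ambiguous`` flag for A/T and C/G
    allele pairs (which are harmonised literally, never strand-flipped).
    """

    study_id: str
    data: pd.DataFrame
    qc: QCReport = field(default_factory=QCReport)

    def __len__(self) -> int:
        return len(self.data)


def _is_valid_allele(a) -> bool:
    if not isinstance(a, str) or not a:
        return False
    return all(c in "ACGTDRI" for c in a.upper())


def read_study_file(path, column_map: dict | None = None, study_id: str | None = None) -> StudyTable:
    """Read one study's flat summary-statistics file.

    Parameters
    ----------
    path
        Whitespace- or tab-delimited text file with a header row; gzip is
        handled transparently.
    column_map
        Optional mapping from the canonical names (MARKERNAME, CHROMOSOME,
        POSITION, EA, NEA, EAF, N, BETA, SE) to the names actually present in
        the file header.
    study_id
        Label for the study; defaults to the file stem.

    Returns
    -------
    StudyTable
        Validated rows; invalid rows are dropped and counted in ``qc``.

    Raises
    ------
    SummaryStatsError
        If a required column cannot be resolved in the header.
    """
    raw = pd.read_csv(path, sep=r"\s+", dtype=str, compression="infer")
    colmap = {k: k for k in REQUIRED_COLUMNS}
    if column_map:
        colmap.update({k.upper(): v for k, v in column_map.items()})

    header = {c.upper(): c for c in raw.columns}
    resolved = {}
    for canon in REQUIRED_COLUMNS:
        want = colmap[canon].upper()
        if want not in header:
            raise SummaryStatsError(
                f"{path}: required column {canon!r} (looked for {colmap[canon]!r}) "
                f"not found in header {list(raw.columns)}"
            )
        resolved[header[want]] = _CANONICAL[canon]

    df = raw[list(resolved)].rename(columns=resolved)
    qc = QCReport(rows_read=len(df))

    for col in ("position", "eaf", "n", "beta", "se"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    def drop(mask: pd.Series, reason: str) -> pd.DataFrame:
        n = int(mask.sum())
        if n:
            qc.dropped[reason] += n
        return df[~mask]

    df = drop(df[["position", "eaf", "n", "beta", "se"]].isna().any(axis=1), "unparseable_numeric")
    for a in ("ea", "nea"):
        df[a] = df[a].astype(str).str.upper()
    df = drop(~df["ea"].map(_is_valid_allele) | ~df["nea"].map(_is_valid_allele), "invalid_allele")
    df = drop(df["ea"] == df["nea"], "identical_alleles")
    df = drop((df["eaf"] < 0) | (df["eaf"] > 1), "eaf_out_of_range")
    df = drop(df["se"] <= 0, "nonpositive_se")
    df = drop(df["n"] <= 0, "nonpositive_n")
    # duplicate marker rows within one file: first occurrence wins
    dup = df["marker"].duplicated(keep="first")
    if dup.any():
        logger.warning("%s: %d duplicate marker rows; keeping first occurrence", path, int(dup.sum()))
    df = drop(dup, "duplicate_marker")

    df = df.copy()
    df["position"] = df["position"].astype(np.int64)
    df["chromosome"] = df["chromosome"].astype(str)
    df["strand_ambiguous"] = [
        frozenset((ea, nea)) in _AMBIGUOUS_PAIRS for ea, nea in zip(df["ea"], df["nea"])
    ]
    if df["strand_ambiguous"].any():
        logger.warning(
            "%s: %d strand-ambiguous (A/T or C/G) variants; harmonised literally",
            path,
            int(df["strand_ambiguous"].sum()),
        )
    qc.rows_kept = len(df)
    sid = study_id if study_id is not None else _stem(path)
    return StudyTable(study_id=sid, data=df.reset_index(drop=True), qc=qc)


def _stem(path) -> str:
    import os

    name = os.path.basename(str(path))
    for suffix in (".gz", ".txt", ".tsv", ".csv"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


def harmonize_alleles(ea: str, nea: str, beta: float, eaf: float, reference_ea: str, reference_nea: str):
    """Align one study record to a reference effect/other allele pair.

    Returns ``(beta, eaf, flipped)`` with the allelic effect negated and the
    frequency complemented when the record carries the alleles in the opposite
    orientation, or ``None`` when the allele sets do not match at all.
    """
    ea, nea = ea.upper(), nea.upper()
    reference_ea, reference_nea = reference_ea.upper(), reference_nea.upper()
    if (ea, nea) == (reference_ea, reference_nea):
        return beta, eaf, False
    if (ea, nea) == (reference_nea, reference_ea):
        return -beta, 1.0 - eaf, True
    return None


@dataclass
class StudyPanel:
    """Cross-study aligned variant panel.

    Variants are keyed by (chromosome, position, unordered allele pair); the
    reference effect allele of each variant is taken from the first study that
    carries it.  Matrices are variants x studies, with ``present`` marking
    which studies contribute; absent cells hold NaN.
    """

    studies: list[str]
    variants: pd.DataFrame  # chromosome, position, ea, nea, marker, strand_ambiguous, n_studies
    beta: np.ndarray
    var: np.ndarray
    eaf: np.ndarray
    n: np.ndarray
    present: np.ndarray

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def study_sizes(self) -> np.ndarray:
        """Per-study sample size N_k, taken as the largest reported n."""
        with np.errstate(all="ignore"):
            return np.nanmax(np.where(self.present, self.n, np.nan), axis=0)

    def subset(self, mask: np.ndarray) -> "StudyPanel":
        mask = np.asarray(mask, dtype=bool)
        return StudyPanel(
            studies=list(self.studies),
            variants=self.variants.loc[mask].reset_index(drop=True),
            beta=self.beta[mask],
            var=self.var[mask],
            eaf=self.eaf[mask],
            n=self.n[mask],
            present=self.present[mask],
        )


def assemble_panel(tables: list[StudyTable]) -> StudyPanel:
    """Merge validated study tables into an allele-aligned variant panel.

    Requires at least three studies (one ancestry axis needs T <= K-2, hence
    K >= 3).  The reference effect allele for a variant is the EA of the first
    study, in input order, that carries it; later studies are flipped or
    rejected by :func:`harmonize_alleles`.
    """
    if len(tables) < 3:
        raise SummaryStatsError(f"need at least 3 studies, got {len(tables)}")

    K = len(tables)
    key_index: dict[tuple, int] = {}
    ref_rows = []
    for table in tables:
        for row in table.data.itertuples(index=False):
            key = (row.chromosome, row.position, frozenset((row.ea, row.nea)))
            if key not in key_index:
                key_index[key] = len(ref_rows)
                ref_rows.append(
                    {
                        "chromosome": row.chromosome,
                        "position": row.position,
                        "ea": row.ea,
                        "nea": row.nea,
                        "marker": row.marker,
                        "strand_ambiguous": bool(row.strand_ambiguous),
                    }
                )
    M = len(ref_rows)
    variants = pd.DataFrame(ref_rows)
    beta = np.full((M, K), np.nan)
    var = np.full((M, K), np.nan)
    eaf = np.full((M, K), np.nan)
    n = np.full((M, K), np.nan)
    present = np.zeros((M, K), dtype=bool)

    n_rejected = 0
    for k, table in enumerate(tables):
        for row in table.data.itertuples(index=False):
            key = (row.chromosome, row.position, frozenset((row.ea, row.nea)))
            i = key_index[key]
            ref = ref_rows[i]
            aligned = harmonize_alleles(row.ea, row.nea, row.beta, row.eaf, ref["ea"], ref["nea"])
            if aligned is None:  # unreachable for 2-allele keys, kept as a guard
                n_rejected += 1
                continue
            b, f, _ = aligned
            beta[i, k] = b
            eaf[i, k] = f
            var[i, k] = row.se**2
            n[i, k] = row.n
            present[i, k] = True
    if n_rejected:
        logger.warning("assemble_panel: %d records rejected (allele_mismatch)", n_rejected)

    variants["n_studies"] = present.sum(axis=1)
    return StudyPanel(
        studies=[t.study_id for t in tables],
        variants=variants,
        beta=beta,
        var=var,
        eaf=eaf,
        n=n,
        present=present,
    )


def presence_filter(panel: StudyPanel, min_fraction: float) -> StudyPanel:
    """Keep variants observed in studies covering at least ``min_fraction`` of the total sample size."""
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    sizes = panel.study_sizes()
    total = np.nansum(sizes)
    covered = np.nansum(np.where(panel.present, panel.n, 0.0), axis=1)
    keep = covered >= min_fraction * total
    logger.info(
        "presence_filter: kept %d / %d variants at fraction %.2f",
        int(keep.sum()),
        panel.n_variants,
        min_fraction,
    )
    return panel.subset(keep)
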