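import numpy as np
import pandas as pd
import pytest

COLUMNS = ["MARKERNAME", "CHROMOSOME", "POSITION", "EA", "NEA", "EAF", "N", "BETA", "SE"]


def make_study_frames(n_variants=30, n_studies=3, seed=202):
    """Synthetic summary-statistics tables sharing a variant panel.

    Study 1 defines the reference alleles; study 2 carries every variant with
    swapped alleles (beta negated, eaf complemented — the same underlying
    signal); study 3 misses the last two variants.
    """
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, 5_000_001), size=n_variants, replace=False))
    chrom = np.where(np.arange(n_variants) < n_variants // 2, "1", "2")
    alleles = np.array([["A", "G"], ["C", "A"], ["T", "C"], ["G", "T"]])
    pair = alleles[rng.integers(0, len(alleles), size=n_variants)]
    eaf = rng.uniform(0.1, 0.9, size=n_variants)
    beta0 = rng.normal(0, 0.05, size=n_variants)

    frames = []
    for k in range(n_studies):
        se = rng.uniform(0.02, 0.08, size=n_variants)
        df = pd.DataFrame(
            {
                "MARKERNAME": [f"rs{i + 1}" for i in range(n_variants)],
                "CHROMOSOME": chrom,
                "POSITION": pos,
                "EA": pair[:, 0],
                "NEA": pair[:, 1],
                "EAF": np.clip(eaf + rng.normal(0, 0.03, size=n_variants), 0.01, 0.99),
                "N": np.full(n_variants, 4000 + 500 * k),
                "BETA": beta0 + rng.normal(0, se),
                "SE": se,
            }
        )
        if k == 1:  # swapped allele orientation, same signal
            df["EA"], df["NEA"] = pair[:, 1], pair[:, 0]
            df["BETA"] = -df["BETA"]
            df["EAF"] = 1.0 - df["EAF"]
        if k == 2:
            df = df.iloc[:-2]
        frames.append(df)
    return frames


@pytest.fixture(scope="session")
def study_files(tmp_path_factory):
    """Three summary-statistics files on disk, sharing 28-30 variants."""
    d = tmp_path_factory.mktemp("studies")
    paths = []
    for k, df in enumerate(make_study_frames()):
        p = d / f"study{k + 1}.txt"
        df.to_csv(p, sep="\t", index=False)
        paths.append(str(p))
    return paths


@pytest.fixture(scope="session")
def panel(study_files):
    from transmeta import assemble_panel, read_study_file

    return assemble_panel([read_study_file(p) for p in study_files])
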