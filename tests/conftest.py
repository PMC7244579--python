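import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def diff_table():
    """Small well-formed differential table."""
    return pd.DataFrame(
        {
            "feature_id": ["g1", "g2", "g3", "g4"],
            "log2fc": [2.0, -1.0, 0.5, 0.0],
            "p_value": [0.001, 0.01, 0.2, 0.9],
            "fdr": [0.004, 0.02, 0.3, 0.9],
            "status": ["up", "down", "stable", "stable"],
        }
    )


@pytest.fixture
def annotation():
    """Three genes, two chromosomes, both strands."""
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "chrom": ["chr1", "chr1", "chr2"],
            "tss": [50_000, 200_000, 50_000],
            "strand": ["+", "-", "+"],
        }
    )


def make_peaks(rows):
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    peaks.insert(0, "peak_id", [f"peak_{i}" for i in range(len(peaks))])
    return peaks


@pytest.fixture
def block_matrix():
    """Two planted 10-feature blocks plus metadata; 24 samples."""
    rng = np.random.default_rng(7)
    n_samples = 24
    rows = []
    for b in range(2):
        latent = rng.standard_normal(n_samples)
        for _ in range(10):
            rows.append(np.sqrt(0.8) * latent
                        + np.sqrt(0.2) * rng.standard_normal(n_samples))
    values = pd.DataFrame(
        rows,
        index=[f"f{i:02d}" for i in range(20)],
        columns=[f"s{i:02d}" for i in range(n_samples)],
    )
    meta = pd.DataFrame(
        {
            "sample": values.columns,
            "condition": ["control", "treated"] * (n_samples // 2),
            "time_h": [8.0] * (n_samples // 2) + [24.0] * (n_samples // 2),
            "replicate": list(range(n_samples // 2)) * 2,
        }
    )
    return values, meta
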