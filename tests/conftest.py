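import numpy as np
import pandas as pd
import pytest

from meripdiff.model import CountExperiment, PeakInterval, SampleInfo


def build_samples(n_reps: int, conditions=("control", "treated")) -> list[SampleInfo]:
    samples = []
    for cond in conditions:
        for rep in range(1, n_reps + 1):
            for frac in ("input", "IP"):
                samples.append(SampleInfo(f"{cond}_{rep}_{frac}", frac, cond, rep))
    return samples


def build_experiment(peak_counts: np.ndarray, n_reps: int,
                     gene_counts: np.ndarray | None = None) -> CountExperiment:
    """Tiny experiment: rows of ``peak_counts`` are peaks, columns follow
    build_samples order; one gene per peak unless gene_counts given."""
    samples = build_samples(n_reps)
    sample_ids = [s.sample_id for s in samples]
    peak_counts = np.atleast_2d(np.asarray(peak_counts))
    n_peaks = peak_counts.shape[0]
    peak_ids = [f"p{i}" for i in range(n_peaks)]
    if gene_counts is None:
        gene_counts = peak_counts.copy()
        gene_ids = [f"g{i}" for i in range(n_peaks)]
    else:
        gene_counts = np.atleast_2d(np.asarray(gene_counts))
        gene_ids = [f"g{i}" for i in range(gene_counts.shape[0])]
    peaks = [
        PeakInterval("chr1", 1000 * i, 1000 * i + 100, strand="+",
                     peak_id=peak_ids[i], gene_id=gene_ids[i % len(gene_ids)])
        for i in range(n_peaks)
    ]
    return CountExperiment(
        peak_counts=pd.DataFrame(peak_counts, index=peak_ids, columns=sample_ids),
        gene_counts=pd.DataFrame(gene_counts, index=gene_ids, columns=sample_ids),
        peaks=peaks,
        samples=samples,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
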