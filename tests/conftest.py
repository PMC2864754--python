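import numpy as np
import pandas as pd
import pytest

from delnet.data import DAYS, ExpressionDataset, SampleMeta


def build_dataset(gene_fns, n_reps=4, drop=None, noise_sd=0.0, seed=0):
    """Construct a 2-condition x 5-day dataset from per-gene mean functions.

    ``gene_fns`` maps gene id -> f(day, treated: bool, replicate) giving the
    cell mean; Gaussian noise is added on top.  ``drop`` removes one
    (day, treatment, replicate) sample, mimicking a degraded array.
    """
    rng = np.random.default_rng(seed)
    samples = []
    for day in DAYS:
        for treatment in ("control", "treated"):
            for rep in range(1, n_reps + 1):
                if drop == (day, treatment, rep):
                    continue
                samples.append(SampleMeta(f"d{day}_{treatment}_r{rep}", day, treatment, rep))
    data = {}
    for gene, fn in gene_fns.items():
        data[gene] = [
            fn(s.day, s.treatment == "treated", s.replicate) + rng.normal(0, noise_sd)
            for s in samples
        ]
    frame = pd.DataFrame(data, index=[s.sample_id for s in samples]).T
    frame.index.name = "gene"
    return ExpressionDataset(frame, samples)


@pytest.fixture
def full_design_dataset():
    """2 x 5 x 4 design with the treated day-2 replicate dropped: 39 arrays."""
    return build_dataset(
        {"gA": lambda d, t, r: 0.1 * d, "gB": lambda d, t, r: 0.5 * t},
        drop=(2, "treated", 4), noise_sd=0.05, seed=1,
    )
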