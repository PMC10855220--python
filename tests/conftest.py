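import numpy as np
import pandas as pd
import pytest

from evpmircomp import (
    CohortSpec,
    RawCounts,
    normalize_positive_controls,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-sample, 100-probe simulated cohort with no injected effects."""
    spec = CohortSpec(n_samples=20, n_endogenous=100, seed=11)
    ann, raw = simulate_cohort(spec)
    return spec, ann, raw


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    _, _, raw = small_cohort
    return normalize_positive_controls(raw)


def make_raw(counts: dict, probe_class: dict) -> RawCounts:
    """Hand-built RawCounts from {probe: [per-sample counts]} dicts."""
    df = pd.DataFrame(counts).T
    df.columns = [f"S{i+1}" for i in range(df.shape[1])]
    return RawCounts(counts=df, probe_class=pd.Series(probe_class))


@pytest.fixture
def tiny_raw():
    """2 endogenous + 2 positive + 2 negative probes, 2 samples."""
    return make_raw(
        {
            "miR-1": [40, 40],
            "miR-2": [10, 20],
            "POS_A": [50, 100],
            "POS_B": [200, 400],
            "NEG_A": [4, 6],
            "NEG_B": [6, 4],
        },
        {
            "miR-1": "endogenous",
            "miR-2": "endogenous",
            "POS_A": "positive",
            "POS_B": "positive",
            "NEG_A": "negative",
            "NEG_B": "negative",
        },
    )
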