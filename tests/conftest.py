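import numpy as np
import pandas as pd
import pytest

from scmlab.io_formats import ActivityTable


def make_activity_table(
    rng: np.random.Generator,
    n_animals: int = 2,
    n_days: int = 1,
    bin_width_min: int = 15,
    genotypes=("control",),
    start: str = "2023-01-01 00:00",
    zero_fraction: float = 0.3,
) -> ActivityTable:
    """Random, structurally valid activity table for property tests."""
    bins_per_day = 24 * 60 // bin_width_min
    n_bins = n_days * bins_per_day
    times = pd.Timestamp(start) + pd.to_timedelta(
        np.arange(n_bins) * bin_width_min, unit="m"
    )
    rows = []
    for a in range(n_animals):
        genotype = genotypes[a % len(genotypes)]
        values = rng.exponential(50.0, n_bins)
        values[rng.uniform(size=n_bins) < zero_fraction] = 0.0
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": f"{genotype}_{a:02d}",
                    "genotype": genotype,
                    "bin_start": times,
                    "bin_width_min": bin_width_min,
                    "value": values,
                }
            )
        )
    return ActivityTable(pd.concat(rows, ignore_index=True))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
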