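import numpy as np
import pytest

from microtrace import (
    CountTable,
    GeneratorConfig,
    MicrobiotaSeries,
    filter_low_abundance,
    generate_dataset,
    to_relative_abundance,
)


@pytest.fixture
def tiny_counts() -> CountTable:
    """3 samples x 4 families with family totals {12, 9, 10, 30}."""
    counts = np.array(
        [
            [5, 3, 2, 10],
            [4, 3, 3, 10],
            [3, 3, 5, 10],
        ]
    )
    return CountTable(("s1", "s2", "s3"), ("fA", "fB", "fC", "fD"), counts)


def make_series(profiles, days=None, series_id="s", family_ids=None, **meta):
    profiles = np.asarray(profiles, dtype=float)
    if family_ids is None:
        family_ids = tuple(f"f{j}" for j in range(profiles.shape[1]))
    if days is None:
        days = tuple(range(1, profiles.shape[0] + 1))
    return MicrobiotaSeries(
        series_id=series_id,
        individual_id=meta.get("individual_id", "ind"),
        species_label=meta.get("species_label", "sp"),
        site_id=meta.get("site_id", "zoo1"),
        day_indices=tuple(days),
        family_ids=family_ids,
        profiles=profiles,
    )


def scalar_series(values, **kw):
    """1-D 'series' for DTW arithmetic checks, embedded as 2-family
    compositions (v, 1-v) so only the first family varies."""
    values = np.asarray(values, dtype=float)
    profiles = np.stack([values, 1.0 - values], axis=1)
    return make_series(profiles, **kw)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared by read-only tests."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_abundances(default_dataset):
    table, records, truth = default_dataset
    return to_relative_abundance(filter_low_abundance(table)), records, truth
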