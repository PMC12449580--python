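import numpy as np
import pandas as pd
import pytest

from biofilmnet.tables_io import CountTable, FeatureTaxonomy, SampleMetadata


@pytest.fixture
def small_table() -> CountTable:
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 50, size=(8, 12))
    counts[0, :] += 1  # guarantee positive totals
    return CountTable(
        [f"s{i}" for i in range(8)],
        [f"f{j}" for j in range(12)],
        counts,
    )


def make_metadata(labels, substrate="seaweed", timepoint="exp1", prefix="s"):
    """Two-column design helper: one sample per label entry."""
    n = len(labels)
    return SampleMetadata(
        pd.DataFrame(
            {
                "treatment": labels,
                "substrate": [substrate] * n,
                "timepoint": [timepoint] * n,
                "panel": [f"P{i % 4}" for i in range(n)],
                "bottle": [f"b{i}" for i in range(n)],
            },
            index=[f"{prefix}{i}" for i in range(n)],
        )
    )


@pytest.fixture
def taxonomy_factory():
    def _make(feature_ids, domain="prokaryote", copy_numbers=None):
        n = len(feature_ids)
        cn = copy_numbers if copy_numbers is not None else [np.nan] * n
        return FeatureTaxonomy(
            pd.DataFrame(
                {
                    "domain_class": [domain] * n,
                    "lineage": ["Bacteria;TestPhylum"] * n,
                    "copy_number": cn,
                },
                index=list(feature_ids),
            )
        )

    return _make
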