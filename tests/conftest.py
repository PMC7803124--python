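import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rumenakp.community_data import (
    CommunityTable,
    SampleMetadata,
    TaxonomyMap,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_table() -> CommunityTable:
    """Three samples, four OTUs, hand-written counts."""
    return CommunityTable(
        ["s1", "s2", "s3"],
        ["Otu01", "Otu02", "Otu03", "Otu04"],
        np.array([[5, 0, 3, 2],
                  [1, 4, 0, 5],
                  [2, 2, 2, 2]]),
    )


@pytest.fixture
def tiny_taxonomy() -> TaxonomyMap:
    lineage = {
        "Otu01": ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
                  "Prevotellaceae", "Prevotella"),
        "Otu02": ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
                  "Prevotellaceae", "Paraprevotella"),
        "Otu03": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                  "Ruminococcaceae", "Ruminococcus"),
        "Otu04": ("Archaea", "Euryarchaeota", "Methanobacteria",
                  "Methanobacteriales", "Methanobacteriaceae",
                  "Methanobrevibacter"),
    }
    from rumenakp.community_data import CANONICAL_RANKS

    return TaxonomyMap({o: tuple(zip(CANONICAL_RANKS, names))
                        for o, names in lineage.items()})


@pytest.fixture
def small_metadata() -> SampleMetadata:
    rows = []
    for vessel, cond in (("C1", "control"), ("C2", "control"),
                         ("T1", "treatment"), ("T2", "treatment")):
        for day, hpf in ((1, 4), (1, 12), (2, 4)):
            t = 24 * (day - 1) + hpf
            rows.append(dict(sample_id=f"{vessel}_d{day}h{hpf:02d}",
                             vessel=vessel, condition=cond, day=day,
                             hours_post_feeding=hpf, time_h=float(t)))
    return SampleMetadata(pd.DataFrame(rows))


def random_table(rng: np.random.Generator, n_samples: int = 5,
                 n_otus: int = 8, max_count: int = 30) -> CommunityTable:
    counts = rng.integers(0, max_count, size=(n_samples, n_otus))
    counts[:, 0] += 1  # guarantee positive library sizes
    return CommunityTable([f"s{i}" for i in range(n_samples)],
                          [f"Otu{j:02d}" for j in range(n_otus)], counts)
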