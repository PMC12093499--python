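import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import parcelfp as p

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_atlas():
    atlas, truth = p.make_paper_atlas()
    return atlas, truth


@pytest.fixture(scope="session")
def small_cohort(paper_atlas):
    """50-subject cohort from the study-structured generator (multiplier 3)."""
    atlas, truth = paper_atlas
    conns = p.simulate_cohort(atlas, truth, 50, rng_seed=42)
    cohort = p.assemble_cohort(conns, atlas, cohort_id="small")
    return atlas, truth, conns, cohort


@pytest.fixture
def toy_atlas():
    """6 merged parcels, 2 insular seeds."""
    rows = [
        ("Ig1", "Ig1", "merged", "insular", True, "granular"),
        ("Id7", "Id7", "merged", "insular", True, "dysgranular"),
        ("44", "44", "merged", "frontal", False, ""),
        ("45", "45", "merged", "frontal", False, ""),
        ("TE1.0", "TE1.0", "merged", "temporal", False, ""),
        ("hOc1", "hOc1", "merged", "occipital", False, ""),
    ]
    return p.AtlasTable(pd.DataFrame(rows, columns=[
        "parcel_id", "parcel_name", "hemisphere", "macro_region",
        "is_insular_seed", "granularity"]))


def symmetric_connectome(ids, rng_or_values, subject_id="s0"):
    """Build a SubjectConnectome from an rng (random entries) or a full array."""
    n = len(ids)
    if isinstance(rng_or_values, np.random.Generator):
        m = rng_or_values.random((n, n)) * 10
        m = (m + m.T) / 2
    else:
        m = np.asarray(rng_or_values, dtype=float)
    np.fill_diagonal(m, 0.0)
    return p.SubjectConnectome(subject_id, pd.DataFrame(m, index=ids, columns=ids))
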