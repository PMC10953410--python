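import numpy as np
import pandas as pd
import pytest

from achburden import achb, prescriptions, synthetic


@pytest.fixture(scope="session")
def catalogue():
    return synthetic.make_catalogue(n_drugs=50, n_combinations=5, seed=1)


@pytest.fixture(scope="session")
def scales(catalogue):
    made = synthetic.make_scales(catalogue, n_scales=5, coverage_range=(0.1, 0.5), seed=2)
    return [achb.apply_improbable_rule(s) for s in made]


@pytest.fixture(scope="session")
def truth():
    return synthetic.SimulationTruth(seed=0)


@pytest.fixture(scope="session")
def participants():
    return synthetic.simulate_participants(600, seed=3)


@pytest.fixture(scope="session")
def sim_bundle(participants, catalogue, truth):
    """Prescription stream with planted violations, plus its normalization."""
    records, audit = synthetic.simulate_prescriptions(
        participants, catalogue, truth, years=(2000, 2015), seed=4, rate_multiplier=0.25
    )
    normalized = prescriptions.normalize_names(records, catalogue.brand_map, catalogue.formulary)
    return {"records": records, "normalized": normalized, "audit": audit}


@pytest.fixture(scope="session")
def small_records(scales):
    """Hand-sized random record table (10 participants x 50 records) for oracle checks."""
    rng = np.random.default_rng(42)
    pool = sorted({d for s in scales for d in s.potencies}) + ["unlisted_a", "unlisted_b"]
    n = 50
    years = rng.integers(2001, 2015, size=n)
    return pd.DataFrame(
        {
            "participant_id": rng.choice([f"p{i}" for i in range(10)], size=n),
            "drug_generic": rng.choice(pool, size=n),
            "route": rng.choice(
                ["oral", "oral", "oral", "topical", "ophthalmic", "nasal", "otic", "parenteral"], size=n
            ),
            "year": years,
            "issue_date": pd.to_datetime([f"{y}-06-15" for y in years]),
        }
    )
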