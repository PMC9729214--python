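import numpy as np
import pandas as pd
import pytest

import traitcurate as tc


@pytest.fixture(scope="session")
def small_taxonomy() -> pd.DataFrame:
    """Hand-written reference taxonomy covering every higher-rank group."""
    return pd.DataFrame([
        ("Quercus robur", "Quercus", "Fagaceae", "angiosperm_other",
         "Quercus pedunculata"),
        ("Quercus ilex", "Quercus", "Fagaceae", "angiosperm_other", ""),
        ("Poa annua", "Poa", "Poaceae", "angiosperm_monocot", ""),
        ("Poa trivialis", "Poa", "Poaceae", "angiosperm_monocot", ""),
        ("Trifolium repens", "Trifolium", "Fabaceae",
         "angiosperm_eudicot_fabaceae", ""),
        ("Pinus sylvestris", "Pinus", "Pinaceae", "gymnosperm", ""),
        ("Pteridium aquilinum", "Pteridium", "Dennstaedtiaceae",
         "pteridophyte", ""),
    ], columns=["accepted_name", "genus", "family", "group", "synonyms"])


def make_record(record_id="R1", dataset_id="DS01", species="Poa annua",
                term="plant height", value=1.0, unit="m", maturity="mature",
                health="healthy", growth_condition="natural", exposure="sun",
                location_id="", date=""):
    return {
        "record_id": record_id, "dataset_id": dataset_id,
        "species_name": species, "trait_term": term, "value": value,
        "unit": unit, "maturity": maturity, "health": health,
        "growth_condition": growth_condition, "exposure": exposure,
        "location_id": location_id, "date": date,
    }


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def default_tables():
    """One default synthetic benchmark, shared read-only across tests."""
    config = tc.GeneratorConfig(
        seed=11,
        errors=tc.ErrorInjectionSpec(unit_shift=0.005, decimal_shift=0.005,
                                     species_swap=0.005,
                                     nonrepresentative=0.01, duplicate=0.02),
    )
    return tc.generate_dataset(config)


@pytest.fixture(scope="session")
def clean_tables():
    """A default-size synthetic benchmark with no injected errors."""
    return tc.generate_dataset(tc.GeneratorConfig(seed=5))


def resolved_records(n_per_species: int, log10_means: dict, sd: float,
                     seed: int = 0, trait: str = "H") -> pd.DataFrame:
    """Small already-resolved record table for outlier/aggregate tests.

    ``log10_means`` maps species name -> log10 mean; genus is the first word,
    family derived from the genus.
    """
    rng = np.random.default_rng(seed)
    rows = []
    rid = 0
    for species, mu in log10_means.items():
        genus = species.split()[0]
        for _ in range(n_per_species):
            rid += 1
            rows.append({
                "record_id": f"R{rid:05d}",
                "accepted_name": species,
                "genus": genus,
                "family": f"{genus}aceae",
                "group": "angiosperm_other",
                "trait_code": trait,
                "value": 10.0 ** (mu + rng.normal(0.0, sd)),
                "flags": "",
                "location_id": "",
                "date": "",
                "maturity": "mature", "health": "healthy",
                "growth_condition": "natural", "exposure": "sun",
            })
    return pd.DataFrame(rows)


@pytest.fixture
def resolved_record_factory():
    return resolved_records
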