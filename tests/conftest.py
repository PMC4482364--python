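import numpy as np
import pandas as pd
import pytest

from phylobeta.traits import TraitTable


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(20260921))


def make_trait_frame(rows):
    """Build a trait DataFrame from (taxon, species, genus, region, y) plus
    reasonable filler trait values, overridable per-row via dict entries."""
    records = []
    for i, row in enumerate(rows):
        base = {
            "range_km2": 10.0 ** (3 + i),
            "rainfall_mm": 300.0 + 150.0 * i,
            "female_mass_g": 20.0 * (i + 1),
            "habitat_openness": i % 5,
            "litter_size": 2.0 + 0.5 * i,
        }
        if isinstance(row, dict):
            base.update(row)
        else:
            taxon, species, genus, region, y = row
            base.update(taxon_id=taxon, species=species, genus=genus,
                        region=region, decline=y)
        records.append(base)
    return pd.DataFrame(records)


@pytest.fixture
def toy_table():
    """Four analysis taxa: three northern (incl. one stable), one southern."""
    df = make_trait_frame([
        ("n1_north", "n1", "Pseudomys", "north", 0.0),
        ("n2_north", "n2", "Pseudomys", "north", 0.1),
        ("n3_north", "n3", "Notomys", "north", 0.6),
        ("s1_south", "s1", "Notomys", "south", 0.3),
    ])
    return TraitTable(data=df, provenance="toy")


@pytest.fixture(scope="session")
def small_fit():
    """A small but complete synthetic fit, shared across tests (read-only)."""
    from phylobeta.mcmc import SamplerSettings
    from phylobeta.model import ModelSpec
    from phylobeta.synthetic_data import (SyntheticConfig, fit_synthetic,
                                          simulate_dataset)

    config = SyntheticConfig(n_species=25, seed=7)
    tree, table, cov = simulate_dataset(config)
    settings = SamplerSettings(n_chains=2, n_adapt=300, n_keep=800, seed=5)
    chains = fit_synthetic(table, cov, ModelSpec(), settings)
    return {"config": config, "tree": tree, "table": table, "cov": cov,
            "chains": chains}
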