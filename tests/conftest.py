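import datetime as dt

import pandas as pd
import pytest

from florivis import simulate as sim


@pytest.fixture
def species_df() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species_id": ["erigeron", "trifolium", "lamium", "taraxacum"],
            "origin": ["alien", "alien", "native", "native"],
            "has_nectaries": [True, True, True, True],
            "floral_unit_type": ["head", "head", "flower", "head"],
        }
    )


@pytest.fixture
def counts_df(species_df) -> pd.DataFrame:
    d1, d2 = dt.date(2018, 5, 5), dt.date(2018, 10, 13)
    return pd.DataFrame(
        [
            ("site1", d1, "plot1", "erigeron", 10),
            ("site1", d1, "plot1", "lamium", 4),
            ("site1", d1, "plot2", "erigeron", 6),
            ("site1", d2, "plot1", "trifolium", 3),
            ("site2", d1, "plot1", "taraxacum", 7),
        ],
        columns=["site", "date", "plot_id", "species_id", "floral_units"],
    )


@pytest.fixture
def visits_df(species_df) -> pd.DataFrame:
    d1 = dt.date(2018, 5, 5)
    return pd.DataFrame(
        [
            ("site1", d1, "plot1", "erigeron", "bee_wasp", 5),
            ("site1", d1, "plot1", "erigeron", "honeybee", 3),
            ("site1", d1, "plot1", "lamium", "hoverfly", 2),
            ("site1", d1, "plot2", "erigeron", "coleoptera", 1),
            ("site1", d1, "plot2", "erigeron", "hemiptera", 2),
            ("site1", d1, "plot2", "lamium", "butterfly", 1),
            ("site2", d1, "plot1", "taraxacum", "bee_wasp", 4),
        ],
        columns=["site", "date", "plot_id", "species_id", "insect_group", "count"],
    )


@pytest.fixture
def profiles_df() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species_id": ["erigeron", "trifolium", "lamium", "taraxacum"],
            "mean_sugar_ug": [5.0, 40.0, float("nan"), 12.0],
            "mean_pollen_ul": [0.5, float("nan"), 0.02, 0.1],
            "n_nectar": [10, 8, 0, 5],
            "n_pollen": [6, 0, 7, 4],
        }
    )


@pytest.fixture(scope="session")
def default_dataset() -> sim.SyntheticDataset:
    """One default-condition synthetic dataset shared across tests."""
    return sim.generate(sim.SimulationConfig(seed=42))


def true_profiles(ds: sim.SyntheticDataset) -> pd.DataFrame:
    """Species profiles straight from the generator's ground truth."""
    gt = ds.ground_truth["species"]
    return pd.DataFrame(
        {
            "species_id": list(gt),
            "mean_sugar_ug": [gt[s]["sugar_mean_ug"] for s in gt],
            "mean_pollen_ul": [gt[s]["pollen_mean_ul"] for s in gt],
        }
    )
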