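import numpy as np
import pandas as pd
import pytest

from npcomics.datatypes import OmicsDataset, StudyDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_balanced_design():
    """Six individuals (two per group, one of each sex), fully paired.

    Sex and age are balanced within groups so the design matrix stays full
    rank under every label permutation.
    """
    rows = []
    ages = {"HC": (30.0, 44.0), "RR": (35.0, 41.0), "SP": (50.0, 57.0)}
    for g in ("HC", "RR", "SP"):
        for j, sex in enumerate(("F", "M")):
            ind = f"{g}{j}"
            for ds in ("CD4", "CD8"):
                rows.append(dict(sample_id=f"{ind}_{ds}", individual_id=ind,
                                 dataset_id=ds, group=g, age=ages[g][j], sex=sex))
    return StudyDesign(pd.DataFrame(rows))


def gaussian_datasets(design, n_features, seed, modality="expression"):
    """Independent standard-normal matrices aligned to a design (null data)."""
    rng = np.random.default_rng(seed)
    feats = [f"g{i}" for i in range(n_features)]
    out = {}
    for ds in design.dataset_ids:
        cols = list(design.subset(ds)["sample_id"])
        out[ds] = OmicsDataset(ds, modality, pd.DataFrame(
            rng.normal(size=(n_features, len(cols))), index=feats, columns=cols))
    return out


@pytest.fixture
def tiny_null_data(tiny_balanced_design):
    return gaussian_datasets(tiny_balanced_design, 40, seed=7)
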