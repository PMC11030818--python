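import numpy as np
import pandas as pd
import pytest

from omicdiff.io import SITE_INDEX, MetaboliteTable, SampleSheet


@pytest.fixture
def sheet_2x2() -> SampleSheet:
    """Two groups x two paired replicates (the minimal CV design)."""
    return SampleSheet(pd.DataFrame({
        "sample_id": ["ctrl_1", "ctrl_2", "CS_1", "CS_2"],
        "group": ["control", "control", "CS", "CS"],
        "replicate_index": [1, 2, 1, 2],
    }))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20221124)


def make_site_table(values, sample_ids=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    n_sites, n_samples = values.shape
    if sample_ids is None:
        sample_ids = [f"S{j + 1}" for j in range(n_samples)]
    index = pd.MultiIndex.from_tuples(
        [(f"P{i:03d}", "K", 10 * (i + 1), "crotonyl") for i in range(n_sites)],
        names=SITE_INDEX,
    )
    return pd.DataFrame(values, index=index, columns=sample_ids)


def make_metabolite_table(values, ids, names=None, classes=None,
                          sample_ids=None) -> MetaboliteTable:
    values = np.asarray(values, dtype=float)
    if sample_ids is None:
        sample_ids = [f"S{j + 1}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=pd.Index(ids, name="metabolite_id"),
                         columns=sample_ids)
    names_s = pd.Series(names, index=ids, name="name") if names is not None else None
    classes_s = pd.Series(classes, index=ids, name="lipid_class") if classes is not None else None
    return MetaboliteTable(values=frame, names=names_s, classes=classes_s)
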