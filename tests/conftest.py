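import numpy as np
import pandas as pd
import pytest

from gdmetab.matrix import AbundanceMatrix
from gdmetab.preprocess import merge_datasets, preprocess_dataset
from gdmetab.synthetic import SyntheticConfig, generate_cohort


def make_matrix(values, batches=None, is_qc=None, labels=None, columns=None):
    """Small AbundanceMatrix builder for unit tests (negatives allowed)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    idx = [f"S{i}" for i in range(n)]
    cols = columns or [f"M{j}" for j in range(p)]
    df = pd.DataFrame(values, index=idx, columns=cols)
    meta = pd.DataFrame(
        {
            "batch_id": batches if batches is not None else ["B1"] * n,
            "is_qc": is_qc if is_qc is not None else [False] * n,
            "label": labels if labels is not None else [np.nan] * n,
        },
        index=idx,
    )
    out = AbundanceMatrix.__new__(AbundanceMatrix)
    out.values = df
    out.sample_meta = meta
    out.metabolite_meta = pd.DataFrame(
        {"dataset": "polar", "lipid_class": "unknown", "kegg_id": np.nan}, index=cols
    )
    out.allow_negative = True
    return out


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_metabolites_per_dataset=(30, 4, 4),
        effect_set_size=10,
        strong_subset_size=6,
        strong_shift=1.2,
        negative_effect_fraction=0.0,
        kegg_annotation_fraction=1.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def merged_cohort(small_cohort):
    matrices, clinical, truth = small_cohort
    processed = {tag: preprocess_dataset(m)[0] for tag, m in matrices.items()}
    merged = merge_datasets(*processed.values())
    labels = clinical.loc[merged.values.index, "gdm"].astype(int)
    return merged, clinical, labels, truth
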