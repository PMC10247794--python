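import numpy as np
import pandas as pd
import pytest

from epiliver import cohortsim
from epiliver.datatypes import BetaMatrix


def make_beta_matrix(rows: dict[str, list[float]], samples: list[str] | None = None) -> BetaMatrix:
    """Small literal beta matrix: probe -> list of betas."""
    data = pd.DataFrame.from_dict(rows, orient="index")
    if samples is not None:
        data.columns = samples
    else:
        data.columns = [f"s{i}" for i in range(data.shape[1])]
    return BetaMatrix(data)


@pytest.fixture(scope="session")
def tissue_cohort():
    """Default synthetic tissue cohort, seed 1."""
    return cohortsim.simulate_tissue_betas(seed=1)


@pytest.fixture(scope="session")
def plasma_cohort():
    """Default synthetic plasma cohort, seed 1."""
    return cohortsim.simulate_plasma_reads(seed=1)


def discovery_chain(matrix, sheet):
    """Run the full detect/spec discovery chain and return its pieces."""
    from epiliver import discovery

    groups = sheet.set_index("sample_id")["group"]
    normal = sheet.loc[sheet["group"].isin(["blood", "tissue:other"]), "sample_id"].tolist()
    hcc = sheet.loc[sheet["group"] == "HCC", "sample_id"].tolist()
    liver = sheet.loc[sheet["group"] == "tissue:liver", "sample_id"].tolist()
    resistant = discovery.resistant_sites(matrix.subset_samples(normal))
    case = matrix.subset_samples(hcc)
    ctrl = matrix.subset_samples(liver)
    categorical = discovery.categorical_filter(case, ctrl, resistant)
    ranked = discovery.differential_shortlist(case, ctrl, categorical)
    chain = matrix.subset_samples(hcc + liver)
    labels = np.array([1] * len(hcc) + [0] * len(liver))
    panel = discovery.reduce_panel(chain, labels, ranked)
    spec_samples = sheet.loc[sheet["group"] != "tissue:liver", "sample_id"].tolist()
    spec_labels = (groups.loc[spec_samples] == "HCC").astype(int).to_numpy()
    _, spec_probe = discovery.spec_site(matrix.subset_samples(spec_samples), spec_labels)
    return panel, spec_probe
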