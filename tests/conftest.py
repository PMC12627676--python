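import numpy as np
import pandas as pd
import pytest

import splicemut as sm


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort: full signal structure at reduced gene count."""
    cfg = sm.SimConfig(n_genes=300, n_de_genes=30, n_signature_genes=15,
                       cells_per_donor=150, seed=11)
    return cfg, sm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_usage(small_cohort):
    _, res = small_cohort
    um = sm.compute_usage(res.junctions)
    return um, sm.impute_mean(um)


@pytest.fixture(scope="session")
def fitted_classifier(small_cohort, small_usage):
    _, res = small_cohort
    _, imputed = small_usage
    weak = res.expression.obs["donor"].map(res.donors["sf3b1_status"]).to_numpy()
    clf = sm.CloneClassifier(random_state=5).fit(imputed.usage, weak)
    return clf


def make_junction_anndata(canonical, cryptic):
    """Build a junction AnnData from two dense integer arrays."""
    import anndata as ad
    from scipy import sparse

    canonical = np.asarray(canonical)
    cryptic = np.asarray(cryptic)
    n, m = canonical.shape
    obs = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"))
    var = pd.DataFrame(index=pd.Index([f"e{j}" for j in range(m)], name="event_id"))
    return ad.AnnData(
        X=sparse.csr_matrix(canonical + cryptic),
        obs=obs, var=var,
        layers={"canonical": sparse.csr_matrix(canonical),
                "cryptic": sparse.csr_matrix(cryptic)},
    )
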