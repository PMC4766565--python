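import numpy as np
import pandas as pd
import pytest

from bpmr.phenotypes import derive_participant_table
from bpmr.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_bundle():
    """A modest cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(n_per_stratum=150, seed=11))


@pytest.fixture(scope="session")
def small_derived(small_bundle):
    return derive_participant_table(small_bundle.participants)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def analysis_frame(small_bundle, small_derived):
    """Derived phenotypes + PCs + in-sample GRS columns, ready for model fits."""
    from bpmr.genetics import apply_qc, compute_grs, genotype_pca, select_locus_snps

    g, _ = apply_qc(small_bundle.genotypes)
    data = small_derived.copy()
    pca = genotype_pca(g, 5)
    data = pd.concat([data, pca.scores.reset_index(drop=True)], axis=1)
    dummies = pd.get_dummies(data["stratum"], prefix="stratum", drop_first=True, dtype=float)
    panel = [s for s in g.snps if s.locus == s.snp_id]
    for expo in ("sbp", "dbp", "map"):
        w = select_locus_snps(
            g, data[expo].to_numpy(), panel, phenotype=expo, covariates=dummies
        )
        data[f"grs_{expo}"] = compute_grs(g, w).to_numpy()
    return data
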