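import numpy as np
import pandas as pd
import pytest

from vtcombine import SimConfig, filter_genes, run_all_schemes, simulate_dataset


@pytest.fixture(scope="session")
def null_vt_results():
    """Unweighted VT results on 500 genes with phenotype independent of genotype.

    Shared by the type-I-error and p-value-uniformity checks; n_perm = 2000.
    """
    import warnings

    config = SimConfig(n_genes=500, causal_gene_fraction=0.0, seed=11)
    bundle = simulate_dataset(config)
    index = filter_genes(bundle.annotation, 2, variant_ids=bundle.genotypes.variant_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fully monomorphic genes warn as degenerate
        results = run_all_schemes(
            bundle.genotypes,
            bundle.phenotype,
            bundle.annotation,
            index,
            schemes="unweighted",
            n_perm=2000,
            seed=7,
        )
    return results


@pytest.fixture(scope="session")
def null_vt_pvalues(null_vt_results):
    p = np.array([r.p_value for r in null_vt_results])
    return p[np.isfinite(p)]


@pytest.fixture()
def tiny_annotation():
    """Six variants in two genes with a mix of flags and missing scores."""
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(6)],
            "gene": ["A", "A", "A", "B", "B", "B"],
            "is_nonsynonymous": [True, False, True, True, True, False],
            "sift_score": [0.04, np.nan, np.nan, 0.5, 0.01, np.nan],
            "polyphen_score": [0.9, np.nan, 0.3, np.nan, 0.99, np.nan],
        }
    )


@pytest.fixture()
def small_bundle():
    return simulate_dataset(SimConfig(n_genes=25, seed=5))
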