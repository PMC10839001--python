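import numpy as np
import pandas as pd
import pytest

from omictwas.expression import CountMatrix
from omictwas.relationship import build_orm
from omictwas.synthetic import (
    SyntheticConfig,
    simulate_counts,
    simulate_phenotypes,
    standardized_expression,
)
from omictwas.varcomp import design_from_phenotypes


def make_counts(mat, biotypes=None, individual_ids=None) -> CountMatrix:
    """CountMatrix from a plain array with minimal synthetic annotation."""
    mat = np.asarray(mat)
    m, n = mat.shape
    meta = pd.DataFrame(
        {
            "chromosome": (np.arange(m) % 21) + 1,
            "start": np.arange(m) * 1000 + 1,
            "end": np.arange(m) * 1000 + 500,
            "biotype": biotypes if biotypes is not None else "protein_coding",
            "novel": False,
            "level": "gene",
        },
        index=pd.Index([f"g{i:03d}" for i in range(m)], name="feature_id"),
    )
    ids = individual_ids or [f"s{j:03d}" for j in range(n)]
    return CountMatrix(counts=mat, feature_meta=meta, individual_ids=ids)


@pytest.fixture(scope="session")
def null_sim():
    """A null-model dataset (no causal fixed effects): n=500 individuals,
    m=1,000 features, polygenic + noise only.  Shared by the calibration
    tests because it is the most expensive fixture."""
    cfg = SyntheticConfig(
        n_individuals=500,
        n_genes=1000,
        frac_wide=1.0,
        frac_restricted=0.0,
        rho2_true=0.3,
        n_causal=0,
        seed=20240915,
    )
    counts = simulate_counts(cfg)
    pheno = simulate_phenotypes(counts, cfg)
    std = standardized_expression(counts)
    orm = build_orm(std)
    X = design_from_phenotypes(pheno)
    y = pheno["bw84"].to_numpy(float)
    return {"y": y, "X": X, "std": std, "orm": orm, "pheno": pheno, "cfg": cfg}


@pytest.fixture(scope="session")
def pure_noise_sim():
    """A strict-null dataset: expression has no effect on the trait at all
    (rho2_true = 0), n=500 individuals, m=1,000 features.  The right
    reference for calibration of the leave-target-out test, which under an
    infinitesimal polygenic background legitimately detects each feature's
    own share of signal."""
    cfg = SyntheticConfig(
        n_individuals=500,
        n_genes=1000,
        frac_wide=1.0,
        frac_restricted=0.0,
        rho2_true=0.0,
        n_causal=0,
        seed=77011,
    )
    counts = simulate_counts(cfg)
    pheno = simulate_phenotypes(counts, cfg)
    std = standardized_expression(counts)
    orm = build_orm(std)
    X = design_from_phenotypes(pheno)
    y = pheno["bw84"].to_numpy(float)
    return {"y": y, "X": X, "std": std, "orm": orm, "pheno": pheno, "cfg": cfg}
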