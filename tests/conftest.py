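import numpy as np
import pandas as pd
import pytest

from snactiv import (
    CountMatrix,
    ExpressionMatrix,
    SampleMetadata,
    SimulationConfig,
    Stain,
    generate_cohort,
    run_de,
)


@pytest.fixture(scope="session")
def default_cohort():
    """Synthetic cohort at the study-design defaults (seed = config default)."""
    cfg = SimulationConfig()
    counts, tpm, meta, truth = generate_cohort(cfg)
    return cfg, counts, tpm, meta, truth


@pytest.fixture(scope="session")
def default_de(default_cohort):
    """DE table on the default cohort with pseudo-positive nuclei excluded,
    mirroring the analysis design."""
    _, counts, _, meta, truth = default_cohort
    exclude = list(truth.pseudo_positive.index[truth.pseudo_positive])
    return run_de(counts, meta, group_field="stain", exclude=exclude)


@pytest.fixture(scope="session")
def recovery_rhos():
    """|Spearman rho| between inferred pseudotime and the latent activation
    time over ten independently seeded synthetic cohorts at defaults."""
    from scipy import stats as sps

    from snactiv import order_nuclei

    rhos = []
    for seed in range(10):
        cfg = SimulationConfig(seed=seed)
        counts, tpm, meta, truth = generate_cohort(cfg)
        exclude = list(truth.pseudo_positive.index[truth.pseudo_positive])
        de = run_de(counts, meta, group_field="stain", exclude=exclude)
        res = order_nuclei(tpm, de, meta, seed=0)
        rho = sps.spearmanr(
            res.samples["pseudotime"], truth.pseudotime.loc[res.samples.index]
        )[0]
        rhos.append(abs(float(rho)))
    return rhos


@pytest.fixture
def small_expression():
    """3-gene x 4-sample TPM matrix with hand-checkable values."""
    df = pd.DataFrame(
        {
            "s1": [0.0, 1.0, 7.0],
            "s2": [2.0, 0.5, 100.0],
            "s3": [0.0, 0.0, 0.0],
            "s4": [1.0, 1.01, 3.0],
        },
        index=["gA", "gB", "gC"],
    )
    return ExpressionMatrix(df)


def make_counts(values, genes=None, samples=None) -> CountMatrix:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def make_meta(sample_ids, stains) -> list[SampleMetadata]:
    return [
        SampleMetadata(sample_id=s, stain=Stain(st))
        for s, st in zip(sample_ids, stains)
    ]
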