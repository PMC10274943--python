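import numpy as np
import pandas as pd
import pytest

from metaboqtl.containers import GenotypeMatrix, MetaboliteMatrix, NON_XENOBIOTIC
from metaboqtl import syndata


@pytest.fixture(scope="session")
def small_geno() -> GenotypeMatrix:
    """500 samples x 60 variants in 6 LD blocks."""
    return syndata.simulate_genotypes(500, 60, ld_block_size=10, seed=11)


@pytest.fixture(scope="session")
def large_geno() -> GenotypeMatrix:
    """2,000 samples x 60 variants for power-hungry checks."""
    return syndata.simulate_genotypes(2000, 60, ld_block_size=10, seed=13)


def planted_violation_fixture():
    """A metabolome with exactly one violation per metabolomics-QC stage.

    Values are uniform on the log10 scale (no tails), so the 1.5*IQR
    fences mask only the single planted outlier and the masking fixpoint
    is reached after one round. Returns (matrix, disease_status,
    expectations) where expectations maps stage name -> expected removal
    or mask count.
    """
    rng = np.random.default_rng(77)
    n = 60
    samples = [f"S{i:04d}" for i in range(n)]
    u = lambda: 10 ** rng.uniform(1, 2, size=n)  # log10 ~ Uniform[1, 2]

    cols = {
        "ok": u(),          # clean
        "missy": u(),       # > 80% missing, not disease-driven
        "imp": u(),         # exactly one missing value to impute
        "zero": u(),        # one non-positive value masked at the log step
        "const": np.full(n, 5.0),   # IQR = 0
        "out": u(),         # one gross outlier masked by the IQR fences
        "sparse": u(),      # xenobiotic with 49 observed values
    }
    df = pd.DataFrame(cols, index=samples)

    # stage 1: one sample missing in > 50% of metabolites
    bad_sample = samples[0]
    df.loc[bad_sample, ["ok", "missy", "imp", "zero", "out", "sparse"]] = np.nan
    keep = [s for s in samples if s != bad_sample]
    # stage 2: 'missy' missing in ~85% of the remaining samples, at random
    missing_rows = rng.choice(keep, size=50, replace=False)
    df.loc[missing_rows, "missy"] = np.nan
    # stage 3: one value to impute
    df.loc[keep[3], "imp"] = np.nan
    # stage 4: one non-positive abundance
    df.loc[keep[5], "zero"] = 0.0
    # stage 6: one gross outlier (log10 = 5 vs fences around [0.5, 2.5])
    df.loc[keep[7], "out"] = 1e5
    # stage 7: xenobiotic with only 49 observed values (never imputed)
    drop_rows = [s for s in keep if s != bad_sample][:10]
    df.loc[drop_rows, "sparse"] = np.nan

    meta = pd.DataFrame(
        {
            "klass": [NON_XENOBIOTIC] * 6 + ["xenobiotic"],
            "super_pathway": "test",
        },
        index=pd.Index(df.columns, name="metabolite_id"),
    )
    status = pd.Series(
        rng.choice(["control", "case"], size=n, p=[0.5, 0.5]), index=samples
    )
    expectations = {
        "sample_missingness": [bad_sample],
        "metabolite_missingness": ["missy"],
        "half_min_imputation": 1,
        "log10_transform": 1,
        "low_variation": ["const"],
        "outlier_masking": 1,
        "min_observations": ["sparse"],
    }
    return MetaboliteMatrix(df, meta), status, expectations


def make_metabolite_matrix(values: np.ndarray, samples=None, klass=NON_XENOBIOTIC,
                           log_scale=False) -> MetaboliteMatrix:
    """Wrap a plain array (samples x metabolites) as a MetaboliteMatrix."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, m = values.shape
    if samples is None:
        samples = [f"S{i:04d}" for i in range(n)]
    cols = [f"M{j:03d}" for j in range(m)]
    df = pd.DataFrame(values, index=samples, columns=cols)
    meta = pd.DataFrame(
        {"klass": klass, "super_pathway": "test"},
        index=pd.Index(cols, name="metabolite_id"),
    )
    return MetaboliteMatrix(df, meta, log_scale=log_scale)
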