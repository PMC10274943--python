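"""Shared in-memory containers for the pipeline.

Conventions used throughout:

* Genotypes are additive dosages of the ALT allele in [0, 2], samples in
  rows, variants in columns. ALT is always the effect allele (A1) when
  summary statistics are produced from a :class:`GenotypeMatrix`.
* Metabolite abundances are samples x metabolites with NaN for missing;
  ``log_scale`` records whether values are raw or log10.
* Summary statistics are long-format DataFrames with the standard columns
  ``phenotype, SNP, CHR, BP, A1, A2, FREQ, BETA, SE, P, N`` (FREQ is the
  A1 frequency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUMSTAT_COLUMNS = [
    "phenotype",
    "SNP",
    "CHR",
    "BP",
    "A1",
    "A2",
    "FREQ",
    "BETA",
    "SE",
    "P",
    "N",
]

#: metabolite class labels
NON_XENOBIOTIC = "non-xenobiotic"
XENOBIOTIC = "xenobiotic"
MINIMALLY_CHARACTERIZED = "minimally characterized"


@dataclass
class GenotypeMatrix:
    """Samples x variants additive ALT-dosage matrix plus variant metadata.

    ``variants`` has one row per column of ``dosages`` with columns
    ``variant_id, chrom, pos, ref, alt, freq`` (``pos`` 1-based; ``freq``
    the designed/estimated ALT frequency).
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                "dosage shape %s does not match %d samples x %d variants"
                % (self.dosages.shape, len(self.samples), len(self.variants))
            )
        self._index = {v: i for i, v in enumerate(self.variants["variant_id"])}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self._index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    def column(self, variant_id: str) -> np.ndarray:
        try:
            return self.dosages[:, self._index[variant_id]]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in genotype matrix") from None

    def columns(self, variant_ids) -> np.ndarray:
        idx = [self._index[v] for v in variant_ids]
        return self.dosages[:, idx]

    def empirical_freqs(self) -> np.ndarray:
        """Observed ALT allele frequency per variant (mean dosage / 2)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def ld_corr(self, variant_ids) -> np.ndarray:
        """Pearson dosage-correlation (LD r) matrix for the given variants."""
        X = self.columns(variant_ids)
        X = X - X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = np.nan
        R = (X.T @ X) / len(X)
        R = R / np.outer(sd, sd)
        np.fill_diagonal(R, 1.0)
        return R

    def subset_variants(self, keep_mask_or_ids) -> "GenotypeMatrix":
        if isinstance(keep_mask_or_ids, (list, tuple, pd.Index)):
            idx = [self._index[v] for v in keep_mask_or_ids]
        else:
            idx = np.flatnonzero(np.asarray(keep_mask_or_ids))
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(
            dosages=self.dosages[idx, :],
            samples=list(sample_ids),
            variants=self.variants.copy(),
        )


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites abundance matrix with metabolite metadata.

    ``values``: DataFrame indexed by sample id, one column per metabolite,
    NaN = missing. ``meta``: DataFrame indexed by metabolite id with columns
    ``klass`` (one of non-xenobiotic / xenobiotic / minimally characterized)
    and ``super_pathway``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        missing_meta = set(self.values.columns) - set(self.meta.index)
        if missing_meta:
            raise ValueError(f"metabolites without metadata: {sorted(missing_meta)[:5]}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    def klass(self, metabolite_id: str) -> str:
        return str(self.meta.loc[metabolite_id, "klass"])

    def missing_fraction(self, axis: str = "metabolite") -> pd.Series:
        if axis == "metabolite":
            return self.values.isna().mean(axis=0)
        if axis == "sample":
            return self.values.isna().mean(axis=1)
        raise ValueError("axis must be 'metabolite' or 'sample'")

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(self.values.copy(), self.meta.copy(), self.log_scale)


def empty_sumstats() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in SUMSTAT_COLUMNS})


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns {missing}")
    return df
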