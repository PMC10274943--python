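"""Per-metabolite additive-model GWAS, IVW meta-analysis and replication.

The association model is ordinary least squares of log10 metabolite level
on ALT-allele dosage plus covariates (age, sex, genetic PCs,
cohort/platform indicators as supplied); p-values come from the t
distribution at the per-test residual degrees of freedom. Studies are
combined by fixed-effect inverse-variance weighting (the STDERR scheme):

    beta_meta = sum(beta_i / se_i^2) / sum(1 / se_i^2)
    se_meta   = sqrt(1 / sum(1 / se_i^2))

A (metabolite, variant) pair is called significant when it is nominally
significant (p < 0.05) with a consistent effect direction in both the
discovery and replication stages and its meta-analysis p-value passes the
study-wide threshold 5e-8 / n_independent_metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, MetaboliteMatrix, SUMSTAT_COLUMNS

GENOME_WIDE_ALPHA = 5e-8
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SignificanceCriteria:
    stagewise_alpha: float = 0.05
    direction_consistent: bool = True
    studywide_p: float = 2.79e-10
    min_cohort_fraction: float | None = None  # brain mode: > 0.5

    def __post_init__(self) -> None:
        if self.studywide_p >= self.stagewise_alpha:
            raise ValueError("studywide_p must be below stagewise_alpha")


def derive_studywide_threshold(n_independent_phenotypes: int) -> float:
    """Bonferroni-style study-wide threshold 5e-8 / n independent phenotypes."""
    if n_independent_phenotypes < 1:
        raise ValueError("n_independent_phenotypes must be >= 1")
    return GENOME_WIDE_ALPHA / n_independent_phenotypes


def fit_additive_model(
    y: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | None = None,
) -> dict:
    """OLS of y on dosage (+ intercept + covariates), case-wise deletion.

    Returns ``{"beta", "se", "t", "p", "n", "testable"}`` where ``beta``
    is the dosage coefficient and ``p`` is two-sided from the t
    distribution with residual degrees of freedom. A dosage that is
    constant after filtering is flagged non-testable.
    """
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    ok = np.isfinite(y) & np.isfinite(dosage)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != len(y):
            covariates = covariates.T
        ok &= np.isfinite(covariates).all(axis=1)
    yv, dv = y[ok], dosage[ok]
    n = int(ok.sum())
    if n < 3 or np.ptp(dv) == 0:
        return {"beta": np.nan, "se": np.nan, "t": np.nan, "p": np.nan, "n": n,
                "testable": False}
    X = np.column_stack([np.ones(n), dv] if covariates is None
                        else [np.ones(n), dv, covariates[ok]])
    df = n - X.shape[1]
    if df < 1 or np.linalg.matrix_rank(X) < X.shape[1]:
        return {"beta": np.nan, "se": np.nan, "t": np.nan, "p": np.nan, "n": n,
                "testable": False}
    coef, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ coef
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    if se == 0:
        return {"beta": beta, "se": 0.0, "t": np.inf, "p": 0.0, "n": n,
                "testable": True}
    t = beta / se
    p = float(2 * stats.t.sf(abs(t), df))
    return {"beta": beta, "se": se, "t": float(t), "p": max(p, 5e-324), "n": n,
            "testable": True}


def _residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Project columns of M off the orthonormal basis Q."""
    return M - Q @ (Q.T @ M)


def run_mgwas(
    metabolome: MetaboliteMatrix,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Association scan of every metabolite against every variant.

    Vectorized per metabolite via Frisch-Waugh-Lovell: y and all dosages
    are residualized on the covariates (plus intercept) for the samples
    where the metabolite is observed, and the per-variant slope, SE and t
    p-value then follow from one matrix product. Residualized genotype
    blocks are cached per missingness pattern, so fully observed
    metabolites share one projection. Non-testable (constant-dosage)
    variants are omitted.
    """
    common = [s for s in metabolome.samples if s in set(genotypes.samples)]
    if not common:
        raise ValueError("no overlapping samples between metabolome and genotypes")
    G_all = genotypes.subset_samples(common).dosages
    Y = metabolome.values.loc[common]
    if not metabolome.log_scale:
        Y = np.log10(Y.mask(Y <= 0))
    if covariates is not None:
        C_all = covariates.loc[common].to_numpy(dtype=float)
    else:
        C_all = np.empty((len(common), 0))

    v = genotypes.variants
    cache: dict[bytes, tuple] = {}
    frames = []
    for m in metabolome.metabolites:
        y = Y[m].to_numpy(dtype=float)
        ok = np.isfinite(y)
        key = np.packbits(ok).tobytes()
        if key not in cache:
            X = np.column_stack([np.ones(int(ok.sum())), C_all[ok]])
            Q, _ = np.linalg.qr(X)
            Gr = _residualize(G_all[ok], Q)
            sxx = (Gr**2).sum(axis=0)
            freq = G_all[ok].mean(axis=0) / 2.0
            cache[key] = (Q, Gr, sxx, freq, X.shape[1])
        Q, Gr, sxx, freq, ncov = cache[key]
        n = int(ok.sum())
        df = n - ncov - 1
        if df < 1:
            continue
        yr = y[ok] - Q @ (Q.T @ y[ok])
        sxy = Gr.T @ yr
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = sxy / sxx
            rss = yr @ yr - beta * sxy
            sigma2 = np.maximum(rss, 0.0) / df
            se = np.sqrt(sigma2 / sxx)
            t = beta / se
        p = 2 * stats.t.sf(np.abs(t), df)
        testable = sxx > 1e-12
        frames.append(
            pd.DataFrame(
                {
                    "phenotype": m,
                    "SNP": v["variant_id"].to_numpy(),
                    "CHR": v["chrom"].to_numpy(),
                    "BP": v["pos"].to_numpy(),
                    "A1": v["alt"].to_numpy(),
                    "A2": v["ref"].to_numpy(),
                    "FREQ": freq,
                    "BETA": beta,
                    "SE": se,
                    "P": np.clip(p, 5e-324, 1.0),
                    "N": n,
                }
            )[testable]
        )
    return pd.concat(frames, ignore_index=True)[SUMSTAT_COLUMNS]


def harmonize_to_reference(stats_df: pd.DataFrame, ref: pd.DataFrame,
                           ambiguous_eaf_margin: float = 0.08) -> pd.DataFrame:
    """Align effect alleles of ``stats_df`` to a reference allele table.

    ``ref`` must carry SNP, A1, A2. Direct match -> kept; swapped alleles
    -> beta sign flipped and frequency complemented; strand flips are
    resolved by base complement when unambiguous; palindromic (A/T, C/G)
    variants are aligned by allele frequency when |eaf - 0.5| exceeds the
    margin and dropped otherwise. Unresolvable variants are dropped.
    """
    m = stats_df.merge(ref[["SNP", "A1", "A2"]].rename(
        columns={"A1": "refA1", "A2": "refA2"}), on="SNP", how="inner")
    if m.empty:
        return stats_df.iloc[0:0]
    up = lambda s: m[s].astype(str).str.upper()
    a1, a2, r1, r2 = up("A1"), up("A2"), up("refA1"), up("refA2")
    comp = lambda s: s.map(_COMPLEMENT)
    c1, c2 = comp(a1), comp(a2)

    palindromic = c1 == a2
    ambiguous = palindromic & ((m["FREQ"] - 0.5).abs() <= ambiguous_eaf_margin)
    direct = (a1 == r1) & (a2 == r2)
    swapped = (a1 == r2) & (a2 == r1)
    strand = (c1 == r1) & (c2 == r2) & ~palindromic
    strand_swapped = (c1 == r2) & (c2 == r1) & ~palindromic

    keep = (direct | swapped | strand | strand_swapped) & ~ambiguous
    flip = (swapped | strand_swapped) & keep
    out = m[keep].copy()
    flip = flip[keep]
    out.loc[flip, "BETA"] = -out.loc[flip, "BETA"]
    out.loc[flip, "FREQ"] = 1 - out.loc[flip, "FREQ"]
    out["A1"] = out["refA1"]
    out["A2"] = out["refA2"]
    return out.drop(columns=["refA1", "refA2"]).reset_index(drop=True)


def ivw_meta(stats_per_study: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance-weighted meta-analysis.

    Studies are aligned on (phenotype, SNP) with effect alleles
    harmonized to the first study; variants with unresolvable alleles are
    dropped. The meta p-value is two-sided normal. A single study is
    returned unchanged (identity).
    """
    if len(stats_per_study) == 0:
        raise ValueError("need at least one study")
    ref = stats_per_study[0]
    aligned = [ref] + [
        harmonize_to_reference(s, ref.drop_duplicates("SNP")) for s in stats_per_study[1:]
    ]
    stacked = pd.concat(aligned, ignore_index=True).copy()
    stacked["w"] = 1.0 / stacked["SE"] ** 2
    stacked["wb"] = stacked["w"] * stacked["BETA"]
    stacked["fn"] = stacked["FREQ"] * stacked["N"]
    g = stacked.groupby(["phenotype", "SNP"], sort=False)
    sums = g[["w", "wb", "fn", "N"]].sum()
    first = g[["CHR", "BP", "A1", "A2"]].first()
    beta = sums["wb"] / sums["w"]
    se = np.sqrt(1.0 / sums["w"])
    z = (beta / se).to_numpy()
    out = first.assign(
        FREQ=sums["fn"] / sums["N"],
        BETA=beta,
        SE=se,
        P=np.clip(2 * stats.norm.sf(np.abs(z)), 5e-324, 1.0),
        N=sums["N"].astype(int),
    ).reset_index()
    return out[SUMSTAT_COLUMNS]


def apply_replication_criteria(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    meta: pd.DataFrame,
    criteria: SignificanceCriteria,
) -> pd.DataFrame:
    """Keep (metabolite, variant) pairs passing the two-stage criteria.

    A pair passes iff discovery and replication are both nominally
    significant, effect directions agree, and the meta p-value passes the
    study-wide threshold. A variant absent from a required stage fails.
    """
    key = ["phenotype", "SNP"]
    d = discovery[key + ["BETA", "P"]].rename(columns={"BETA": "b_d", "P": "p_d"})
    r = replication[key + ["BETA", "P"]].rename(columns={"BETA": "b_r", "P": "p_r"})
    m = meta.merge(d, on=key, how="left").merge(r, on=key, how="left")
    passes = (
        (m["p_d"] < criteria.stagewise_alpha)
        & (m["p_r"] < criteria.stagewise_alpha)
        & (m["P"] < criteria.studywide_p)
    )
    if criteria.direction_consistent:
        passes &= np.sign(m["b_d"]) == np.sign(m["b_r"])
    passes &= m["p_d"].notna() & m["p_r"].notna()
    return m.loc[passes.fillna(False), SUMSTAT_COLUMNS].reset_index(drop=True)


def apply_brain_criteria(
    per_cohort: list[pd.DataFrame],
    meta: pd.DataFrame,
    studywide_p: float,
    min_cohort_fraction: float = 0.5,
) -> pd.DataFrame:
    """Brain-style criteria: direction consistency across > min fraction of
    the cohorts that captured the variant, plus a study-wide meta p."""
    key = ["phenotype", "SNP"]
    stacked = pd.concat(
        [c[key + ["BETA"]].assign(study=i) for i, c in enumerate(per_cohort)],
        ignore_index=True,
    )
    def _consistent(g: pd.DataFrame) -> pd.Series:
        captured = len(g)
        signs = np.sign(g["BETA"])
        agree = max((signs > 0).sum(), (signs < 0).sum())
        return pd.Series(
            {
                "captured_fraction": captured / len(per_cohort),
                "direction_agree": agree == captured,
            }
        )
    flags = stacked.groupby(key).apply(_consistent, include_groups=False).reset_index()
    m = meta.merge(flags, on=key, how="left")
    passes = (
        (m["captured_fraction"] > min_cohort_fraction)
        & m["direction_agree"].fillna(False)
        & (m["P"] < studywide_p)
    )
    return m.loc[passes.fillna(False), SUMSTAT_COLUMNS].reset_index(drop=True)


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic-control lambda: median observed 1-df chi-square over the
    null median 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        raise ValueError("need at least 100 p-values")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
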