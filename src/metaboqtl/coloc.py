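"""Single-causal-variant Bayesian colocalization from summary statistics.

For each variant an approximate Bayes factor against the null follows
Wakefield's normal approximation: with shrinkage ratio
``r = prior_sd^2 / (prior_sd^2 + varbeta)`` and ``z = beta / sqrt(varbeta)``,

    log ABF = 0.5 * (log(1 - r) + r * z^2).

Under a single causal variant per trait the five hypotheses are H0 (no
association), H1/H2 (one trait only), H3 (two distinct causal variants)
and H4 (one shared causal variant). Hypothesis sums run over
configurations in log space (log-sum-exp): single variants for H1/H2/H4,
ordered distinct pairs for H3; posteriors are the prior-weighted sums
(priors p1 = p2 = 1e-4 per variant, p12 = 1e-5 per shared variant)
normalized over H0..H4. PP.H4 is the probability the two phenotypes share
one causal variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_CASE_CONTROL = 0.2


@dataclass
class ColocDataset:
    """Aligned per-variant effects for one trait over a region."""

    beta: np.ndarray
    varbeta: np.ndarray
    snps: list[str] | None = None
    maf: np.ndarray | None = None
    n: int | None = None
    trait_type: str = "quantitative"  # or "case-control"
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.varbeta = np.asarray(self.varbeta, dtype=float)
        if self.beta.shape != self.varbeta.shape:
            raise ValueError("beta and varbeta must be aligned")
        if np.any(self.varbeta <= 0):
            raise ValueError("varbeta must be positive")

    @property
    def prior_sd(self) -> float:
        return (
            PRIOR_SD_CASE_CONTROL
            if self.trait_type == "case-control"
            else PRIOR_SD_QUANTITATIVE
        )


@dataclass
class ColocResult:
    pp: dict[str, float]
    n_snps: int
    priors: tuple[float, float, float]
    h4_contributions: np.ndarray = field(repr=False, default=None)

    def __getitem__(self, key: str) -> float:
        return self.pp[key]


def wakefield_abf(beta, varbeta, prior_sd: float) -> np.ndarray:
    """Log approximate Bayes factor (association vs null) per variant."""
    beta = np.asarray(beta, dtype=float)
    varbeta = np.asarray(varbeta, dtype=float)
    if np.any(varbeta <= 0) or prior_sd <= 0:
        raise ValueError("varbeta and prior_sd must be positive")
    r = prior_sd**2 / (prior_sd**2 + varbeta)
    z2 = beta**2 / varbeta
    return 0.5 * (np.log1p(-r) + r * z2)


def coloc_abf(
    d1: ColocDataset,
    d2: ColocDataset,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> ColocResult:
    """Posterior probabilities of colocalization hypotheses H0..H4.

    The two datasets must already be intersected on shared variants with
    harmonized effect alleles. With a single shared variant the H3 mass
    is exactly zero (no distinct pair exists).
    """
    l1 = wakefield_abf(d1.beta, d1.varbeta, d1.prior_sd)
    l2 = wakefield_abf(d2.beta, d2.varbeta, d2.prior_sd)
    ok = np.isfinite(l1) & np.isfinite(l2)
    l1, l2 = l1[ok], l2[ok]
    k = len(l1)
    if k == 0:
        raise ValueError("no shared variants with finite Bayes factors")

    lse1 = logsumexp(l1)
    lse2 = logsumexp(l2)
    lse12 = logsumexp(l1 + l2)

    lh0 = 0.0
    lh1 = np.log(p1) + lse1
    lh2 = np.log(p2) + lse2
    # ordered distinct pairs: sum_i sum_{j != i} exp(l1_i + l2_j)
    if k > 1:
        all_pairs = lse1 + lse2
        gap = lse12 - all_pairs  # <= 0 up to rounding
        if gap >= -1e-15:
            lh3 = -np.inf  # the diagonal carries all the mass
        else:
            lh3 = np.log(p1) + np.log(p2) + all_pairs + np.log1p(-np.exp(gap))
    else:
        lh3 = -np.inf
    lh4 = np.log(p12) + lse12

    lall = np.array([lh0, lh1, lh2, lh3, lh4])
    norm = logsumexp(lall)
    pp = np.exp(lall - norm)
    contrib = np.exp(l1 + l2 - lse12)
    return ColocResult(
        pp={f"PP.H{i}": float(pp[i]) for i in range(5)},
        n_snps=k,
        priors=(p1, p2, p12),
        h4_contributions=contrib,
    )


def varbeta_from_p(
    p: np.ndarray,
    maf: np.ndarray,
    n: int,
    trait_type: str = "quantitative",
    case_fraction: float | None = None,
    sign: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct (beta, varbeta) from p-values and allele frequencies.

    On the unit-variance phenotype scale ``varbeta ~= 1 / (2 n f (1-f))``
    for a quantitative trait; for case-control the effective sample size
    shrinks by ``case_fraction * (1 - case_fraction)``. The signed z is
    recovered from the two-sided p and the supplied effect direction
    (magnitude-only when no direction is given).
    """
    p = np.asarray(p, dtype=float)
    maf = np.asarray(maf, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(~np.isfinite(maf)):
        raise ValueError("p and maf must be finite")
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    varbeta = 1.0 / (2.0 * n * maf * (1.0 - maf))
    if trait_type == "case-control":
        if case_fraction is None or not 0 < case_fraction < 1:
            raise ValueError("case-control traits need case_fraction in (0,1)")
        varbeta = varbeta / (case_fraction * (1.0 - case_fraction))
    z = stats.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)
    if sign is not None:
        z = z * np.sign(np.asarray(sign, dtype=float))
    beta = z * np.sqrt(varbeta)
    return beta, varbeta


def dataset_from_sumstats(
    stats_df,
    trait_type: str = "quantitative",
    case_fraction: float | None = None,
    use_p: bool = False,
) -> ColocDataset:
    """Build a :class:`ColocDataset` from a standard summary-stats table."""
    maf = np.minimum(stats_df["FREQ"].to_numpy(float), 1 - stats_df["FREQ"].to_numpy(float))
    n = int(stats_df["N"].max())
    if use_p:
        beta, varbeta = varbeta_from_p(
            stats_df["P"].to_numpy(float),
            np.clip(maf, 1e-4, 0.5),
            n,
            trait_type,
            case_fraction,
            sign=stats_df["BETA"].to_numpy(float),
        )
    else:
        beta = stats_df["BETA"].to_numpy(float)
        varbeta = stats_df["SE"].to_numpy(float) ** 2
    return ColocDataset(
        beta=beta,
        varbeta=varbeta,
        snps=list(stats_df["SNP"]),
        maf=maf,
        n=n,
        trait_type=trait_type,
        case_fraction=case_fraction,
    )


def intersect_datasets(stats1, stats2) -> tuple:
    """Inner-join two summary-stats tables on SNP, aligning alleles of the
    second to the first (sign flip on swapped alleles)."""
    m = stats1.merge(stats2, on="SNP", suffixes=("_1", "_2"))
    if m.empty:
        raise ValueError("no shared variants between the two datasets")
    flip = (m["A1_1"] == m["A2_2"]) & (m["A2_1"] == m["A1_2"])
    keep = flip | ((m["A1_1"] == m["A1_2"]) & (m["A2_1"] == m["A2_2"]))
    m = m[keep].copy()
    m.loc[flip[keep], "BETA_2"] = -m.loc[flip[keep], "BETA_2"]
    m.loc[flip[keep], "FREQ_2"] = 1 - m.loc[flip[keep], "FREQ_2"]
    s1 = m[[c for c in m.columns if c.endswith("_1")] + ["SNP"]].rename(
        columns=lambda c: c[:-2] if c.endswith("_1") else c
    )
    s2 = m[[c for c in m.columns if c.endswith("_2")] + ["SNP"]].rename(
        columns=lambda c: c[:-2] if c.endswith("_2") else c
    )
    return s1, s2
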