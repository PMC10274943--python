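"""Metabolomics and genotype quality control.

The metabolomics rule set (applied in a fixed stage order):

1. drop samples with > 50% missing metabolites;
2. drop non-xenobiotic metabolites with > 80% missingness, unless a
   disease-linked recovery check rescues them;
3. per-cohort half-minimum imputation of non-xenobiotics (xenobiotics are
   never imputed);
4. log10 transform (non-positive values are masked, not fatal);
5. drop near-constant metabolites (IQR = 0 or variance < 0.001);
6. per-cohort masking of values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR];
7. drop metabolites with fewer than 50 observed values (per analysis stage
   when a stage split is declared).

Stage 6 re-applies the per-cohort fences until no further value is masked,
which makes the whole pipeline idempotent: running it on its own output is
a no-op. Each stage emits a :class:`QcReport` so removals are auditable
and replayable.

Genotype QC removes variants failing call rate (>= 95%), minor allele
count (>= 5) and Hardy-Weinberg equilibrium (exact-test p >= 1e-6), in
that order, on hard calls rounded from dosages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .containers import GenotypeMatrix, MetaboliteMatrix, NON_XENOBIOTIC


@dataclass
class QcReport:
    stage: str
    removed_samples: list[str] = field(default_factory=list)
    removed_metabolites: list[str] = field(default_factory=list)
    recovered_metabolites: list[str] = field(default_factory=list)
    masked_values: int = 0
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "removed_samples": list(self.removed_samples),
            "removed_metabolites": list(self.removed_metabolites),
            "recovered_metabolites": list(self.recovered_metabolites),
            "masked_values": int(self.masked_values),
            "parameters": dict(self.parameters),
        }


def merge_replicates(
    raw: MetaboliteMatrix,
    replicate_map: list[tuple[str, str]],
    lod_quantile: float = 0.10,
) -> MetaboliteMatrix:
    """Merge technical-replicate sample pairs.

    Both present -> mean. One present -> kept only when the lone value is
    at or below the metabolite's ``lod_quantile`` quantile across all
    values (close to the limit of detection), else missing. Neither ->
    missing. The merged sample keeps the first id of each pair.
    """
    seen: set[str] = set()
    for a, b in replicate_map:
        for s in (a, b):
            if s in seen:
                raise ValueError(f"sample {s!r} appears in more than one replicate pair")
            seen.add(s)
            if s not in raw.values.index:
                raise ValueError(f"replicate sample {s!r} not present in the matrix")

    values = raw.values.copy()
    lod = values.quantile(lod_quantile, axis=0)
    for a, b in replicate_map:
        va, vb = values.loc[a], values.loc[b]
        both = va.notna() & vb.notna()
        only_a = va.notna() & vb.isna()
        only_b = vb.notna() & va.isna()
        merged = pd.Series(np.nan, index=values.columns)
        merged[both] = (va[both] + vb[both]) / 2.0
        merged[only_a & (va <= lod)] = va[only_a & (va <= lod)]
        merged[only_b & (vb <= lod)] = vb[only_b & (vb <= lod)]
        values.loc[a] = merged
        values = values.drop(index=b)
    return MetaboliteMatrix(values, raw.meta.copy(), raw.log_scale)


def recover_disease_associated(
    values: pd.Series,
    disease_status: pd.Series,
    alpha: float = 0.05,
    control_label: str = "control",
) -> str:
    """Decide whether a high-missingness metabolite is disease-driven.

    Recover iff, for some non-control status group, (a) Fisher's exact
    test of missingness vs control is significant, (b) linear regression
    of observed abundance on group membership is significant, and (c) the
    directions jointly explain the missingness (e.g. more missing and
    lower abundance in the group). Returns ``"recover"`` or ``"exclude"``.
    """
    status = pd.Series(np.asarray(disease_status), index=values.index)
    groups = [g for g in status.unique() if g != control_label]
    if control_label not in set(status):
        raise ValueError("disease_status must include a control group")
    miss = values.isna()
    for g in groups:
        in_g = status == g
        in_c = status == control_label
        table = [
            [int((miss & in_g).sum()), int((~miss & in_g).sum())],
            [int((miss & in_c).sum()), int((~miss & in_c).sum())],
        ]
        _, p_fisher = stats.fisher_exact(table)
        rate_g = miss[in_g].mean()
        rate_c = miss[in_c].mean()

        obs = values[(in_g | in_c) & ~miss]
        grp = (status[(in_g | in_c) & ~miss] == g).astype(float)
        if obs.empty or grp.nunique() < 2:
            continue  # regression not possible for this group
        slope, _, _, p_reg, _ = stats.linregress(grp.to_numpy(), obs.to_numpy())
        direction_ok = (rate_g - rate_c) * slope < 0
        if p_fisher < alpha and p_reg < alpha and direction_ok:
            return "recover"
    return "exclude"


def _half_min_impute(values: pd.DataFrame, cohorts: pd.Series, non_xeno: list[str]):
    """Per-cohort half-minimum imputation of non-xenobiotic metabolites."""
    out = values.copy()
    n_imputed = 0
    for cohort in pd.unique(cohorts):
        rows = cohorts[cohorts == cohort].index
        block = out.loc[rows, non_xeno]
        halfmin = block.min(axis=0) / 2.0
        mask = block.isna() & halfmin.notna()
        n_imputed += int(mask.to_numpy().sum())
        out.loc[rows, non_xeno] = block.fillna(halfmin)
    return out, n_imputed


def _iqr_fences(col: pd.Series) -> tuple[float, float]:
    q1, q3 = col.quantile([0.25, 0.75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def run_metabolite_qc(
    merged: MetaboliteMatrix,
    disease_status: pd.Series | None = None,
    cohorts: pd.Series | None = None,
    sample_missing_max: float = 0.50,
    metabolite_missing_max: float = 0.80,
    min_values: int = 50,
    variance_min: float = 1e-3,
    recovery_alpha: float = 0.05,
    stage_split: pd.Series | None = None,
) -> tuple[MetaboliteMatrix, list[QcReport]]:
    """Apply the full metabolomics QC rule set; see the module docstring.

    ``cohorts`` / ``disease_status`` / ``stage_split`` are Series indexed
    by sample id (defaulting to a single cohort, no recovery testing and
    no stage split). Returns the cleaned log10-scale matrix and the
    per-stage audit reports.
    """
    values = merged.values.copy()
    meta = merged.meta
    if cohorts is None:
        cohorts = pd.Series("all", index=values.index)
    else:
        cohorts = pd.Series(np.asarray(cohorts), index=values.index)
    reports: list[QcReport] = []

    # stage 1: samples with > 50% missingness
    frac = values.isna().mean(axis=1)
    bad_samples = list(values.index[frac > sample_missing_max])
    values = values.drop(index=bad_samples)
    cohorts = cohorts.drop(index=bad_samples)
    reports.append(
        QcReport(
            "sample_missingness",
            removed_samples=bad_samples,
            parameters={"max_missing": sample_missing_max},
        )
    )

    # stage 2: non-xenobiotics with > 80% missingness, with recovery check
    non_xeno = [m for m in values.columns if meta.loc[m, "klass"] == NON_XENOBIOTIC]
    frac_m = values[non_xeno].isna().mean(axis=0)
    candidates = list(frac_m.index[frac_m > metabolite_missing_max])
    recovered: list[str] = []
    if disease_status is not None:
        status = pd.Series(np.asarray(disease_status), index=merged.values.index)
        status = status.loc[values.index]
        for m in list(candidates):
            if recover_disease_associated(values[m], status, recovery_alpha) == "recover":
                recovered.append(m)
                candidates.remove(m)
    values = values.drop(columns=candidates)
    reports.append(
        QcReport(
            "metabolite_missingness",
            removed_metabolites=candidates,
            recovered_metabolites=recovered,
            parameters={"max_missing": metabolite_missing_max},
        )
    )

    # stage 3: per-cohort half-minimum imputation (non-xenobiotics only)
    non_xeno = [m for m in values.columns if meta.loc[m, "klass"] == NON_XENOBIOTIC]
    values, n_imputed = _half_min_impute(values, cohorts, non_xeno)
    reports.append(
        QcReport("half_min_imputation", masked_values=0, parameters={"imputed": n_imputed})
    )

    # stage 4: log10 transform; non-positive values masked, not fatal
    if not merged.log_scale:
        nonpos = (values <= 0).to_numpy().sum()
        values = values.mask(values <= 0)
        values = np.log10(values)
        reports.append(
            QcReport("log10_transform", masked_values=int(nonpos), parameters={})
        )
    else:
        reports.append(QcReport("log10_transform", parameters={"already_log": True}))

    # stage 5: near-constant metabolites (IQR = 0 or variance < 0.001)
    q1 = values.quantile(0.25)
    q3 = values.quantile(0.75)
    var = values.var()
    flat = list(values.columns[((q3 - q1) == 0) | (var < variance_min)])
    values = values.drop(columns=flat)
    reports.append(
        QcReport(
            "low_variation",
            removed_metabolites=flat,
            parameters={"variance_min": variance_min},
        )
    )

    # stage 6: per-cohort 1.5*IQR outlier masking, iterated to a fixpoint
    total_masked = 0
    for _ in range(50):
        masked_this_round = 0
        for cohort in pd.unique(cohorts):
            rows = cohorts[cohorts == cohort].index
            block = values.loc[rows]
            q1 = block.quantile(0.25)
            q3 = block.quantile(0.75)
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            outside = block.lt(lo, axis=1) | block.gt(hi, axis=1)
            masked_this_round += int(outside.to_numpy().sum())
            values.loc[rows] = block.mask(outside)
        total_masked += masked_this_round
        if masked_this_round == 0:
            break
    reports.append(
        QcReport("outlier_masking", masked_values=total_masked, parameters={"k": 1.5})
    )

    # stage 7: metabolites with too few observed values (overall and per stage)
    counts = values.notna().sum(axis=0)
    sparse = set(counts.index[counts < min_values])
    if stage_split is not None:
        split = pd.Series(np.asarray(stage_split), index=merged.values.index)
        split = split.loc[values.index]
        for part in pd.unique(split):
            c = values.loc[split == part].notna().sum(axis=0)
            sparse |= set(c.index[c < min_values])
    sparse_list = sorted(sparse)
    values = values.drop(columns=sparse_list)
    reports.append(
        QcReport(
            "min_observations",
            removed_metabolites=sparse_list,
            parameters={"min_values": min_values},
        )
    )

    out = MetaboliteMatrix(values, meta.loc[list(values.columns)].copy(), log_scale=True)
    return out, reports


def sample_outliers_pca(qc_matrix: MetaboliteMatrix, sd_limit: float = 5.0) -> list[str]:
    """Samples beyond ``sd_limit`` SD on principal component 1 or 2.

    PCA is computed on z-scored complete metabolite columns (columns that
    still contain missing values - e.g. xenobiotics - are excluded, since
    PCA is undefined with missing cells).
    """
    complete = qc_matrix.values.dropna(axis=1)
    if len(complete) < 3 or complete.shape[1] < 2:
        return []
    X = complete.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    # scores via SVD; only the top two components are needed
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :2] * S[:2]
    z = (scores - scores.mean(axis=0)) / scores.std(axis=0)
    bad = np.abs(z).max(axis=1) > sd_limit
    return list(complete.index[bad])


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test by enumeration of heterozygote
    counts conditional on the allele counts.

    The p-value sums the conditional probabilities of all heterozygote
    configurations no more probable than the observed one. Monomorphic or
    empty samples return 1 by convention.
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_minor == 0:
        return 1.0

    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(n_het | allele counts) up to a shared constant
    homr = (n_minor - hets) // 2
    homc = n - hets - homr
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
    )
    logp = logp - logp.max()
    prob = np.exp(logp)
    prob = prob / prob.sum()
    p_obs = prob[hets == n_Aa][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def genotype_qc(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.95,
    mac_min: int = 5,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, QcReport]:
    """Post-imputation variant QC: call rate, minor allele count, HWE.

    Filters are applied in that order so the report attributes each
    removal to the first failing filter. HWE uses hard calls obtained by
    rounding dosages to the nearest integer.
    """
    D = genotypes.dosages
    n_variants = D.shape[1]
    keep = np.ones(n_variants, dtype=bool)
    counts = {"call_rate": 0, "mac": 0, "hwe": 0}

    called = np.isfinite(D)
    call_rate = called.mean(axis=0)
    fail_cr = call_rate < call_rate_min
    counts["call_rate"] = int(fail_cr.sum())
    keep &= ~fail_cr

    hard = np.round(np.clip(D, 0, 2))
    for j in np.flatnonzero(keep):
        calls = hard[called[:, j], j]
        alt = int(calls.sum())
        mac = min(alt, 2 * len(calls) - alt)
        if mac < mac_min:
            counts["mac"] += 1
            keep[j] = False
            continue
        n_aa = int((calls == 2).sum())
        n_Aa = int((calls == 1).sum())
        n_AA = int((calls == 0).sum())
        if hwe_exact_test(n_AA, n_Aa, n_aa) < hwe_p_min:
            counts["hwe"] += 1
            keep[j] = False

    removed = [v for v, k in zip(genotypes.variant_ids, keep) if not k]
    report = QcReport(
        "genotype_qc",
        removed_metabolites=[],
        parameters={
            "call_rate_min": call_rate_min,
            "mac_min": mac_min,
            "hwe_p_min": hwe_p_min,
            "removed_per_filter": counts,
            "removed_variants": removed,
        },
    )
    return genotypes.subset_variants(keep), report
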