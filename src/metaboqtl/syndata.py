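"""Synthetic multi-cohort genotypes, metabolomes and mediated traits.

Every downstream stage of the pipeline (QC, mGWAS, meta-analysis, region
building, conditional analysis, colocalization, MWAS, MR, triangulation)
is exercised against data produced here, with a machine-readable truth
table recording the planted cis/trans QTLs, the pleiotropic locus, the
polygenic metabolite, and the metabolite that mediates a quantitative
trait.

Model
-----
* Genotypes: hard additive dosages in {0, 1, 2} drawn under Hardy-Weinberg
  equilibrium. Linkage disequilibrium follows a Gaussian copula: within a
  block of consecutive variants the two latent haplotype normals share one
  exchangeable correlation; variants in different blocks are independent.
* Metabolites: natural-scale abundance ``10 ** (base + sum(beta * dosage)
  + cohort shift + N(0, noise_sd))``; genetic effects are additive per
  ALT-allele dose on the log10 scale.
* Missingness is applied in order: below-detection-limit (lower-tail
  quantile) censoring, then completely-at-random dropout, then
  disease-linked dropout at a configured odds ratio for designated
  metabolites.
* Traits: ``mediated`` (trait = causal_effect x standardized metabolite +
  noise, so the metabolite's QTL is the trait's causal variant),
  ``independent-signal`` (trait driven by a different variant in the same
  region) or ``null`` (pure noise).

All generators are pure functions of (parameters, seed); per-stage child
seeds are derived from one master seed by fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    GenotypeMatrix,
    MetaboliteMatrix,
    NON_XENOBIOTIC,
    SUMSTAT_COLUMNS,
)

# fixed offsets for deriving per-stage child seeds from a master seed
SEED_OFFSETS = {
    "genotypes": 11,
    "metabolome": 23,
    "trait": 37,
    "labels": 53,
}
_SEED_MOD = 2**31 - 1


def child_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed by a fixed offset."""
    return (int(master_seed) * 1000003 + SEED_OFFSETS[stage]) % _SEED_MOD


@dataclass
class QtlSpec:
    """A planted additive QTL: per-allele effect on log10 abundance."""

    metabolite_id: str
    variant_id: str
    beta: float
    region_role: str = "primary"  # or "secondary-independent"
    pleiotropy_group: str | None = None


@dataclass
class MissingSpec:
    """Missingness configuration (all probabilities in [0, 1])."""

    random_rate: float = 0.0
    lod_quantile: float = 0.0
    disease_or: float = 1.0
    disease_metabolites: tuple[str, ...] = ()
    disease_base_rate: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.random_rate <= 1:
            raise ValueError("random_rate must lie in [0, 1]")
        if not 0 <= self.lod_quantile <= 0.5:
            raise ValueError("lod_quantile must lie in [0, 0.5]")
        if self.disease_or <= 0:
            raise ValueError("disease_or must be positive")


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset."""

    qtls: list[QtlSpec] = field(default_factory=list)
    causal_metabolite: str | None = None
    causal_effect: float = 0.0
    h2_cis: dict[str, float] = field(default_factory=dict)

    def qtls_for(self, metabolite_id: str) -> list[QtlSpec]:
        return [q for q in self.qtls if q.metabolite_id == metabolite_id]

    def to_frame(self) -> pd.DataFrame:
        rows = [asdict(q) for q in self.qtls]
        return pd.DataFrame(rows)


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_size: int = 10,
    seed: int = 0,
    block_rho: float = 0.8,
    spacing_bp: int = 20_000,
    chrom: str = "1",
    mafs: np.ndarray | None = None,
) -> GenotypeMatrix:
    """HWE dosages with exchangeable-correlation LD blocks.

    Each haplotype's allele indicator derives from a latent normal; latents
    of variants in the same block share correlation ``block_rho``, latents
    in different blocks are independent, so genotypes are Hardy-Weinberg
    within each variant and block-correlated across variants.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    rng = np.random.default_rng(seed)
    if mafs is None:
        mafs = rng.uniform(lo, hi, size=n_variants)
    else:
        mafs = np.broadcast_to(np.asarray(mafs, float), (n_variants,)).copy()
    thresholds = stats.norm.ppf(mafs)

    dosage = np.zeros((n_samples, n_variants))
    for start in range(0, n_variants, ld_block_size):
        stop = min(start + ld_block_size, n_variants)
        width = stop - start
        for _hap in range(2):
            shared = rng.standard_normal((n_samples, 1))
            indep = rng.standard_normal((n_samples, width))
            z = np.sqrt(block_rho) * shared + np.sqrt(1 - block_rho) * indep
            dosage[:, start:stop] += (z < thresholds[start:stop]).astype(float)

    pos = spacing_bp * (1 + np.arange(n_variants))
    variants = pd.DataFrame(
        {
            "variant_id": [f"{chrom}:{p}:A:G" for p in pos],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "freq": mafs,
        }
    )
    samples = [f"S{i:05d}" for i in range(n_samples)]
    return GenotypeMatrix(dosage, samples, variants)


def _apply_qtl_effects(
    genotypes: GenotypeMatrix,
    qtls: list[QtlSpec],
    metabolite_ids: list[str],
) -> np.ndarray:
    """Genetic value per (sample, metabolite) on the log10 scale."""
    g = np.zeros((genotypes.n_samples, len(metabolite_ids)))
    col = {m: j for j, m in enumerate(metabolite_ids)}
    for q in qtls:
        if q.metabolite_id not in col:
            raise KeyError(f"QTL references unknown metabolite {q.metabolite_id!r}")
        try:
            dose = genotypes.column(q.variant_id)
        except KeyError:
            raise KeyError(
                f"QTL variant {q.variant_id!r} absent from the genotype matrix"
            ) from None
        g[:, col[q.metabolite_id]] += q.beta * dose
    return g


def simulate_metabolome(
    genotypes: GenotypeMatrix,
    qtls: list[QtlSpec],
    n_metabolites: int,
    cohorts: pd.Series | np.ndarray | None = None,
    batch_shifts: dict[str, float] | None = None,
    missing: MissingSpec | None = None,
    noise_sd: float = 0.25,
    seed: int = 0,
    disease_status: np.ndarray | None = None,
    disease_abundance_shift: dict[str, float] | None = None,
    baseline: float = 1.0,
    metabolite_classes: dict[str, str] | None = None,
) -> tuple[MetaboliteMatrix, TruthTable]:
    """Natural-scale metabolite abundances with planted QTLs and missingness.

    Returns the (raw-scale) :class:`MetaboliteMatrix` and a
    :class:`TruthTable` whose ``h2_cis`` records the realized proportion of
    log10-scale variance explained by each metabolite's planted QTLs.
    """
    rng = np.random.default_rng(seed)
    metabolite_ids = [f"M{j:03d}" for j in range(n_metabolites)]
    missing = missing or MissingSpec()
    batch_shifts = batch_shifts or {}
    if cohorts is None:
        cohorts = np.array(["cohortA"] * genotypes.n_samples)
    cohorts = np.asarray(cohorts)

    genetic = _apply_qtl_effects(genotypes, qtls, metabolite_ids)
    shift = np.array([batch_shifts.get(c, 0.0) for c in cohorts])[:, None]
    noise = rng.standard_normal(genetic.shape) * noise_sd
    log10_abund = baseline + genetic + shift + noise

    if disease_abundance_shift and disease_status is not None:
        case = np.asarray(disease_status).astype(bool)
        for m, delta in disease_abundance_shift.items():
            j = metabolite_ids.index(m)
            log10_abund[case, j] += delta

    values = pd.DataFrame(
        10.0**log10_abund,
        index=[s for s in genotypes.samples],
        columns=metabolite_ids,
    )

    # missingness order: below-LOD censoring, then random, then disease-linked
    if missing.lod_quantile > 0:
        lod = values.quantile(missing.lod_quantile, axis=0)
        values = values.mask(values.le(lod, axis=1))
    if missing.random_rate > 0:
        drop = rng.random(values.shape) < missing.random_rate
        values = values.mask(drop)
    if missing.disease_metabolites and disease_status is not None:
        case = np.asarray(disease_status).astype(bool)
        p0 = missing.disease_base_rate
        odds0 = p0 / (1 - p0)
        p1 = (missing.disease_or * odds0) / (1 + missing.disease_or * odds0)
        for m in missing.disease_metabolites:
            prob = np.where(case, p1, p0)
            drop = rng.random(len(values)) < prob
            values.loc[drop, m] = np.nan

    # realized cis h2 on the log10 scale
    h2 = {}
    total_var = genetic.var(axis=0) + noise_sd**2 + np.var(shift.ravel())
    for j, m in enumerate(metabolite_ids):
        gv = genetic[:, j].var()
        h2[m] = float(gv / total_var[j]) if total_var[j] > 0 else 0.0

    meta = pd.DataFrame(
        {
            "klass": [
                (metabolite_classes or {}).get(m, NON_XENOBIOTIC)
                for m in metabolite_ids
            ],
            "super_pathway": "simulated",
        },
        index=pd.Index(metabolite_ids, name="metabolite_id"),
    )
    truth = TruthTable(qtls=list(qtls), h2_cis=h2)
    return MetaboliteMatrix(values, meta, log_scale=False), truth


def simulate_disease_labels(n_samples: int, case_fraction: float = 0.4, seed: int = 0):
    """Bernoulli case/control labels independent of genotype."""
    rng = np.random.default_rng(seed)
    return rng.random(n_samples) < case_fraction


def gwas_scan(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    phenotype_id: str = "trait",
) -> pd.DataFrame:
    """Per-variant simple regression summary statistics for a trait vector."""
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    yv = y[ok] - y[ok].mean()
    X = genotypes.dosages[ok]
    Xc = X - X.mean(axis=0)
    n = ok.sum()
    sxx = (Xc**2).sum(axis=0)
    sxy = Xc.T @ yv
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = (yv**2).sum() - beta * sxy
        df = n - 2
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
    p = 2 * stats.t.sf(np.abs(tstat), df)
    v = genotypes.variants
    out = pd.DataFrame(
        {
            "phenotype": phenotype_id,
            "SNP": v["variant_id"].to_numpy(),
            "CHR": v["chrom"].to_numpy(),
            "BP": v["pos"].to_numpy(),
            "A1": v["alt"].to_numpy(),
            "A2": v["ref"].to_numpy(),
            "FREQ": X.mean(axis=0) / 2.0,
            "BETA": beta,
            "SE": se,
            "P": np.clip(p, np.nextafter(0, 1), 1.0),
            "N": n,
        }
    )
    return out[np.isfinite(out["SE"])].reset_index(drop=True)


def simulate_trait(
    genotypes: GenotypeMatrix,
    metabolome: MetaboliteMatrix,
    truth: TruthTable,
    mode: str = "mediated",
    seed: int = 0,
    noise_sd: float = 1.0,
    independent_variant: str | None = None,
    independent_beta: float = 0.5,
    trait_id: str = "trait",
) -> tuple[np.ndarray, pd.DataFrame]:
    """A quantitative trait plus its per-variant GWAS summary statistics.

    ``mediated``: the trait is ``causal_effect`` trait-units per SD of the
    causal metabolite's log10 level (missing metabolite values are
    mean-imputed before mediation), so the metabolite's QTLs drive the
    trait. ``independent-signal``: the trait is driven directly by
    ``independent_variant``. ``null``: pure noise.
    """
    rng = np.random.default_rng(seed)
    n = len(metabolome.values)
    noise = rng.standard_normal(n) * noise_sd

    if mode == "null":
        trait = noise
    elif mode == "mediated":
        if truth.causal_metabolite is None:
            raise ValueError("mediated mode requires truth.causal_metabolite")
        raw = metabolome.values[truth.causal_metabolite].to_numpy(dtype=float)
        x = raw if metabolome.log_scale else np.log10(raw)
        if np.isnan(x).any():
            x = np.where(np.isnan(x), np.nanmean(x), x)
        z = (x - x.mean()) / x.std()
        trait = truth.causal_effect * z + noise
    elif mode == "independent-signal":
        if independent_variant is None:
            raise ValueError("independent-signal mode requires independent_variant")
        dose = genotypes.column(independent_variant)
        trait = independent_beta * dose + noise
    else:
        raise ValueError(f"unknown trait mode {mode!r}")

    stats_df = gwas_scan(trait, genotypes, phenotype_id=trait_id)
    return trait, stats_df


# ---------------------------------------------------------------------------
# external interfaces: plain-text writers
# ---------------------------------------------------------------------------


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        genotypes.dosages,
        index=pd.Index(genotypes.samples, name="sample_id"),
        columns=genotypes.variant_ids,
    )
    df.to_csv(path, sep="\t")


def read_dosage_tsv(path, variants: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if variants is None:
        ids = list(df.columns)
        parts = [v.split(":") for v in ids]
        variants = pd.DataFrame(
            {
                "variant_id": ids,
                "chrom": [p[0] for p in parts],
                "pos": [int(p[1]) for p in parts],
                "ref": [p[2] for p in parts],
                "alt": [p[3] for p in parts],
                "freq": df.to_numpy().mean(axis=0) / 2.0,
            }
        )
    return GenotypeMatrix(df.to_numpy(), list(df.index), variants)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Uncompressed VCF with GT (hard call) and DS (dosage) fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in genotypes.variants.iterrows():
            dose = genotypes.dosages[:, j]
            calls = [
                f"{gt_codes[int(round(min(max(d, 0), 2)))]}:{d:g}" for d in dose
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT:DS\t" + "\t".join(calls) + "\n"
            )


def write_metabolome_tsv(metabolome: MetaboliteMatrix, values_path, meta_path) -> None:
    metabolome.values.rename_axis("sample_id").to_csv(values_path, sep="\t")
    metabolome.meta.to_csv(meta_path, sep="\t")


def write_truth_table(truth: TruthTable, path) -> None:
    df = truth.to_frame()
    df["causal_metabolite"] = truth.causal_metabolite
    df["causal_effect"] = truth.causal_effect
    df["h2_cis"] = df["metabolite_id"].map(truth.h2_cis)
    df.to_csv(path, sep="\t", index=False)


def write_sumstats(stats_df: pd.DataFrame, path) -> None:
    stats_df[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False)
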