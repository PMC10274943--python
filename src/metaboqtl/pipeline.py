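"""End-to-end orchestration over a synthetic two-cohort study.

``simulate_study`` generates the reference study conditions: two cohorts
of 1,000 samples, 5,000 variants in LD blocks, 40 metabolites with nine
planted QTL associations at eight distinct loci (one pleiotropic locus
shared by three metabolites, one polygenic metabolite with two distant
loci, one metabolite that mediates a quantitative trait), batch shifts,
below-detection-limit plus random missingness, and Bernoulli disease
labels. ``run_pipeline`` then carries the data through metabolomics and
genotype QC, per-cohort mGWAS (discovery/replication), IVW meta-analysis
with the two-stage significance criteria, region and locus construction,
conditional signal dissection, and - for the simulated trait - MWAS,
colocalization and MR, triangulated into causal-metabolite tiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import gwas as gwas_mod
from . import integrate as integrate_mod
from . import loci as loci_mod
from . import mr as mr_mod
from . import mwas as mwas_mod
from . import qc as qc_mod
from . import syndata
from .containers import GenotypeMatrix, MetaboliteMatrix
from .syndata import MissingSpec, QtlSpec, TruthTable, child_seed


@dataclass
class StudyData:
    genotypes: GenotypeMatrix
    metabolome: MetaboliteMatrix
    truth: TruthTable
    cohorts: pd.Series
    disease: np.ndarray
    trait: np.ndarray
    trait_stats: pd.DataFrame


@dataclass
class PipelineResult:
    sumstats_meta: pd.DataFrame
    significant: pd.DataFrame
    regions: list
    loci: list
    pleiotropy: pd.DataFrame
    polygenicity: pd.DataFrame
    signals: dict[str, list]
    mwas_table: pd.DataFrame
    mr_table: pd.DataFrame
    coloc_table: pd.DataFrame
    evidence: pd.DataFrame
    studywide_p: float
    qc_reports: list = field(default_factory=list)


#: planted structure of the reference synthetic study (variant column index
#: -> metabolites and effects); indices are spaced > 2 Mb apart so every
#: planted QTL seeds its own locus except the pleiotropic one.
def reference_qtl_plan(variant_ids: list[str]) -> tuple[list[QtlSpec], dict]:
    n = len(variant_ids)
    # eight planted variants spaced by >= 12% of the simulated map, which at
    # 20 kb spacing keeps every pair of loci well over 2 Mb apart for any
    # n_variants >= 1000
    pick = lambda frac: variant_ids[int(frac * n)]
    qtls = [
        # pleiotropic locus: one variant drives three metabolites
        QtlSpec("M000", pick(0.05), 0.30, pleiotropy_group="pleio"),
        QtlSpec("M001", pick(0.05), 0.28, pleiotropy_group="pleio"),
        QtlSpec("M002", pick(0.05), -0.32, pleiotropy_group="pleio"),
        # polygenic metabolite: two distant loci
        QtlSpec("M003", pick(0.17), 0.30),
        QtlSpec("M003", pick(0.29), 0.26),
        # the trait-mediating metabolite
        QtlSpec("M004", pick(0.41), 0.35),
        # three further single-QTL metabolites
        QtlSpec("M005", pick(0.53), 0.30),
        QtlSpec("M006", pick(0.65), -0.30),
        QtlSpec("M007", pick(0.77), 0.28),
    ]
    expectations = {
        "pleiotropic_locus_variant": pick(0.05),
        "pleiotropy_count": 3,
        "polygenic_metabolite": "M003",
        "polygenicity": 2,
        "causal_metabolite": "M004",
        "n_loci": 7,  # 8 planted variants, two shared by M003 -> distinct loci
        "regions_per_metabolite": {
            "M000": 1, "M001": 1, "M002": 1, "M003": 2, "M004": 1,
            "M005": 1, "M006": 1, "M007": 1,
        },
    }
    return qtls, expectations


def simulate_study(
    seed: int,
    n_per_cohort: int = 1000,
    n_variants: int = 5000,
    n_metabolites: int = 40,
    causal_effect: float = 0.5,
    noise_sd: float = 0.25,
    missing: MissingSpec | None = None,
) -> StudyData:
    """The reference synthetic study: see the module docstring."""
    geno = syndata.simulate_genotypes(
        2 * n_per_cohort,
        n_variants,
        maf_range=(0.1, 0.5),
        ld_block_size=10,
        seed=child_seed(seed, "genotypes"),
    )
    cohorts = pd.Series(
        ["discovery"] * n_per_cohort + ["replication"] * n_per_cohort,
        index=geno.samples,
    )
    disease = syndata.simulate_disease_labels(
        geno.n_samples, 0.4, seed=child_seed(seed, "labels")
    )
    qtls, _ = reference_qtl_plan(geno.variant_ids)
    missing = missing or MissingSpec(random_rate=0.02, lod_quantile=0.02)
    metabolome, truth = syndata.simulate_metabolome(
        geno,
        qtls,
        n_metabolites=n_metabolites,
        cohorts=cohorts.to_numpy(),
        batch_shifts={"replication": 0.2},
        missing=missing,
        noise_sd=noise_sd,
        seed=child_seed(seed, "metabolome"),
        disease_status=disease,
    )
    truth.causal_metabolite = "M004"
    truth.causal_effect = causal_effect
    trait, trait_stats = syndata.simulate_trait(
        geno, metabolome, truth, mode="mediated",
        seed=child_seed(seed, "trait"), noise_sd=1.0,
    )
    return StudyData(geno, metabolome, truth, cohorts, disease, trait, trait_stats)


def _region_stats(meta_stats: pd.DataFrame, region) -> pd.DataFrame:
    df = meta_stats[meta_stats["phenotype"] == region.metabolite_id]
    return df[
        (df["CHR"].astype(str) == str(region.chrom))
        & (df["BP"] >= region.start)
        & (df["BP"] <= region.end)
    ].reset_index(drop=True)


def run_pipeline(
    study: StudyData,
    seed: int = 0,
    h2_gate_p: float = 0.01,
    h4_cut: float = 0.6,
    fdr_alpha: float = 0.05,
    run_trait_analyses: bool = True,
) -> PipelineResult:
    geno = study.genotypes
    cohorts = study.cohorts

    # metabolomics QC (per-cohort imputation/outlier rules) and genotype QC
    clean, reports = qc_mod.run_metabolite_qc(
        study.metabolome,
        disease_status=pd.Series(
            np.where(study.disease, "case", "control"), index=study.metabolome.samples
        ),
        cohorts=cohorts,
    )
    outlier_samples = qc_mod.sample_outliers_pca(clean)
    if outlier_samples:
        clean = MetaboliteMatrix(
            clean.values.drop(index=outlier_samples), clean.meta, clean.log_scale
        )
    geno_clean, geno_report = qc_mod.genotype_qc(geno)
    reports = list(reports) + [geno_report]

    # per-stage mGWAS with cohort covariate handled by the stage split
    stage_stats = {}
    for stage in ("discovery", "replication"):
        samples = [s for s in clean.samples if cohorts.get(s) == stage]
        sub_met = MetaboliteMatrix(
            clean.values.loc[samples], clean.meta, clean.log_scale
        )
        sub_gen = geno_clean.subset_samples(samples)
        stage_stats[stage] = gwas_mod.run_mgwas(sub_met, sub_gen)

    meta_stats = gwas_mod.ivw_meta([stage_stats["discovery"], stage_stats["replication"]])
    studywide_p = gwas_mod.derive_studywide_threshold(len(clean.metabolites))
    criteria = gwas_mod.SignificanceCriteria(studywide_p=studywide_p)
    significant = gwas_mod.apply_replication_criteria(
        stage_stats["discovery"], stage_stats["replication"], meta_stats, criteria
    )

    regions = loci_mod.build_regions(significant)
    loci_list, pleiotropy, polygenicity = loci_mod.build_loci(regions, significant)
    signals = {}
    for r in regions:
        rs = _region_stats(meta_stats, r)
        signals[f"{r.metabolite_id}:{r.lead_variant}"] = loci_mod.cojo_stepwise(
            rs, geno_clean, p_threshold=studywide_p
        )
        r.independent_signals = signals[f"{r.metabolite_id}:{r.lead_variant}"]

    mwas_rows, coloc_rows, mr_results = [], [], []
    if run_trait_analyses:
        trait_stats = study.trait_stats
        trait_by_snp = trait_stats.set_index("SNP")
        for r in regions:
            m = r.metabolite_id
            samples = clean.samples
            sub_gen = geno_clean.subset_samples(samples)
            rs = _region_stats(meta_stats, r)
            region_snps = [s for s in rs["SNP"] if s in trait_by_snp.index]
            if len(region_snps) < 2:
                continue
            Greg = np.column_stack([sub_gen.column(s) for s in region_snps])
            y = clean.values[m].to_numpy(dtype=float)

            # MWAS: h2 gate, weight fitting, weighted-z association
            try:
                h2_hat, h2_p = mwas_mod.estimate_cis_h2(Greg, y)
            except ValueError:
                continue
            if h2_p < h2_gate_p:
                wm = mwas_mod.fit_weights(
                    Greg, y, variant_ids=region_snps, seed=seed,
                    region=(r.chrom, r.start, r.end), h2_result=(h2_hat, h2_p),
                )
                if wm is not None:
                    z = trait_by_snp.loc[region_snps, "BETA"].to_numpy() / \
                        trait_by_snp.loc[region_snps, "SE"].to_numpy()
                    R = sub_gen.ld_corr(region_snps)
                    try:
                        Z, p = mwas_mod.mwas_test(wm, z, np.nan_to_num(R))
                        mwas_rows.append(
                            {"metabolite": m, "trait": "trait", "region": wm.region,
                             "z": Z, "p": p, "model": wm.model_tag,
                             "h2": wm.h2_cis, "h2_p": wm.h2_p, "cv_r2": wm.cv_r2}
                        )
                    except ValueError:
                        pass

            # colocalization in the region window
            d_met = coloc_mod.dataset_from_sumstats(rs)
            d_trait = coloc_mod.dataset_from_sumstats(
                trait_by_snp.loc[region_snps].reset_index()
            )
            idx = [rs.index[rs["SNP"] == s][0] for s in region_snps]
            d_met = coloc_mod.ColocDataset(
                beta=d_met.beta[idx], varbeta=d_met.varbeta[idx], snps=region_snps
            )
            res = coloc_mod.coloc_abf(d_met, d_trait)
            coloc_rows.append(
                {"metabolite": m, "trait": "trait", "pp_h4": res["PP.H4"],
                 "pp_h3": res["PP.H3"], "pp_h0": res["PP.H0"], "n_snps": res.n_snps}
            )

        # MR per metabolite over clumped, pleiotropy-pruned instruments
        positions = meta_stats[["SNP", "CHR", "BP"]].drop_duplicates("SNP")
        for m in sorted(significant["phenotype"].unique()):
            exp = significant[significant["phenotype"] == m]
            inst_ids = mr_mod.clump(exp, geno_clean)
            inst_ids = mr_mod.exclude_pleiotropic(
                inst_ids, pleiotropy, mode="main", variant_positions=positions
            )
            exp_kept = exp[exp["SNP"].isin(inst_ids)]
            instruments = mr_mod.harmonize(exp_kept, study.trait_stats)
            if not instruments:
                continue
            mr_results.append(
                mr_mod.ivw_mr(instruments, exposure=m, outcome="trait")
                if len(instruments) > 1
                else mr_mod.wald_ratio(instruments[0], exposure=m, outcome="trait")
            )

    mwas_table = pd.DataFrame(mwas_rows)
    if not mwas_table.empty:
        adj, rej = mwas_mod.fdr_bh(mwas_table["p"].clip(lower=5e-324), alpha=fdr_alpha)
        mwas_table["fdr_p"] = adj
        mwas_table["significant"] = rej
    mr_table = mr_mod.mr_grid_fdr(mr_results, alpha=fdr_alpha)
    coloc_table = pd.DataFrame(coloc_rows)

    if len(mwas_table) and len(mr_table) and len(coloc_table):
        # a polygenic metabolite contributes several regions; collapse to one
        # record per (metabolite, trait) pair, keeping the strongest evidence
        mwas_pairs = (
            mwas_table.groupby(["metabolite", "trait"], as_index=False)["significant"]
            .any()
        )
        coloc_pairs = (
            coloc_table.groupby(["metabolite", "trait"], as_index=False)["pp_h4"].max()
        )
        evidence = integrate_mod.triangulate(
            mwas_pairs,
            mr_table.rename(columns={"exposure": "metabolite", "outcome": "trait"})[
                ["metabolite", "trait", "significant"]
            ],
            coloc_pairs,
            h4_cut=h4_cut,
        )
    else:
        evidence = pd.DataFrame(
            columns=["metabolite", "trait", "mwas_sig", "mr_sig", "pp_h4",
                     "coloc_sig", "tier", "missing_analyses"]
        )

    return PipelineResult(
        sumstats_meta=meta_stats,
        significant=significant,
        regions=regions,
        loci=loci_list,
        pleiotropy=pleiotropy,
        polygenicity=polygenicity,
        signals=signals,
        mwas_table=mwas_table,
        mr_table=mr_table,
        coloc_table=coloc_table,
        evidence=evidence,
        studywide_p=studywide_p,
        qc_reports=reports,
    )
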