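"""Triangulation of MWAS, MR and colocalization into causal calls,
effector-gene nomination, and cell-type specificity/enrichment.

A metabolite-trait pair reaches the ``three-way`` tier when it is
FDR-significant in both MWAS and MR and colocalizes (PP.H4 > 0.6);
``two-way`` when exactly two lines of evidence hold, ``one-way`` for one,
``none`` otherwise. A missing analysis counts as non-support and is
flagged.

Effector genes are nominated per signal by a fixed decision tree over
precomputed annotation tables: (1) a protein-sequence-altering variant
names its gene (preferring genes overlapping the signal's LD region);
(2) else a gene supported by both the bottom-up (proximity/eQTL) and the
top-down (metabolic-pathway membership) routes; (3) else the nearest gene
with an eQTL overlapping the association; (4) else the nearest gene. A
curated metabolite-to-gene knowledge table overrides the tree when it
names a different gene among the ten nearest, and classifies the action
as cis when the gene is a direct enzyme or transporter of the metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EvidenceRecord:
    metabolite: str
    trait: str
    mwas_fdr_significant: bool
    mr_fdr_significant: bool
    coloc_pp_h4: float | None
    tier: str
    missing_analyses: tuple[str, ...] = ()


@dataclass
class GeneNomination:
    signal: str
    gene: str | None
    evidence_class: str  # protein-altering | eqtl | both | nearest | knowledge-override | unresolved
    action: str  # "cis" or "trans"
    protein_role: str = "other"
    overridden_gene: str | None = None


def triangulate(
    mwas_results: pd.DataFrame,
    mr_results: pd.DataFrame,
    coloc_results: pd.DataFrame,
    h4_cut: float = 0.6,
) -> pd.DataFrame:
    """Tier every tested (metabolite, trait) pair by its evidence count.

    Inputs are keyed on (metabolite, trait): ``mwas_results`` and
    ``mr_results`` carry a boolean ``significant`` (FDR < 0.05) column,
    ``coloc_results`` a ``pp_h4`` column. Pairs absent from an analysis
    count as unsupported there and are flagged in ``missing_analyses``.
    """
    key = ["metabolite", "trait"]
    pairs = (
        pd.concat([df[key] for df in (mwas_results, mr_results, coloc_results)])
        .drop_duplicates()
        .reset_index(drop=True)
    )
    m = pairs.merge(
        mwas_results[key + ["significant"]].rename(columns={"significant": "mwas_sig"}),
        on=key, how="left",
    ).merge(
        mr_results[key + ["significant"]].rename(columns={"significant": "mr_sig"}),
        on=key, how="left",
    ).merge(coloc_results[key + ["pp_h4"]], on=key, how="left")

    missing = []
    for _, r in m.iterrows():
        gaps = []
        if pd.isna(r["mwas_sig"]):
            gaps.append("mwas")
        if pd.isna(r["mr_sig"]):
            gaps.append("mr")
        if pd.isna(r["pp_h4"]):
            gaps.append("coloc")
        missing.append(",".join(gaps))
    m["missing_analyses"] = missing
    m["mwas_sig"] = np.where(m["mwas_sig"].isna(), False, m["mwas_sig"]).astype(bool)
    m["mr_sig"] = np.where(m["mr_sig"].isna(), False, m["mr_sig"]).astype(bool)
    m["coloc_sig"] = m["pp_h4"].fillna(0.0) > h4_cut
    n_support = m[["mwas_sig", "mr_sig", "coloc_sig"]].sum(axis=1)
    m["tier"] = np.select(
        [n_support == 3, n_support == 2, n_support == 1],
        ["three-way", "two-way", "one-way"],
        default="none",
    )
    return m


def nominate_effector_gene(
    signal_variants: pd.DataFrame,
    genes: pd.DataFrame,
    eqtl_overlaps: pd.DataFrame | None = None,
    knowledge: pd.DataFrame | None = None,
    metabolite_id: str | None = None,
    signal_id: str = "",
) -> GeneNomination:
    """Nominate one effector gene for an association signal.

    ``signal_variants``: lead + proxy variants with columns variant_id,
    gene, consequence (e.g. missense), protein_altering (bool),
    in_ld_region (bool). ``genes``: nearest-10 table with columns gene,
    distance, metabolic_pathway (bool), with optional protein_role.
    ``eqtl_overlaps``: columns gene, eqtl_flag (bool). ``knowledge``:
    columns metabolite_id, gene, relation (enzyme/transporter/pathway/
    literature).
    """
    if genes is None or genes.empty:
        return GeneNomination(signal_id, None, "unresolved", "trans")
    genes = genes.sort_values(["distance", "gene"], kind="mergesort").reset_index(drop=True)
    eqtl_genes = set()
    if eqtl_overlaps is not None and not eqtl_overlaps.empty:
        eqtl_genes = set(eqtl_overlaps.loc[eqtl_overlaps["eqtl_flag"].astype(bool), "gene"])

    gene, evidence = None, None
    # rule 1: protein-sequence-altering variant
    if "protein_altering" in signal_variants.columns:
        hits = signal_variants[signal_variants["protein_altering"].astype(bool)]
        if not hits.empty:
            in_region = hits[hits.get("in_ld_region", pd.Series(True, index=hits.index)).astype(bool)]
            chosen = in_region if not in_region.empty else hits
            order = {g: i for i, g in enumerate(genes["gene"])}
            gene = sorted(set(chosen["gene"]), key=lambda g: (order.get(g, 1e9), g))[0]
            evidence = "protein-altering"
            if gene in eqtl_genes:
                evidence = "both"
    # rule 2: bottom-up (proximity/eQTL) and top-down (pathway) agreement
    if gene is None and "metabolic_pathway" in genes.columns:
        both = genes[genes["metabolic_pathway"].astype(bool) & genes["gene"].isin(eqtl_genes)]
        if not both.empty:
            gene, evidence = str(both.iloc[0]["gene"]), "eqtl"
    # rule 3: nearest gene with an overlapping eQTL
    if gene is None:
        with_eqtl = genes[genes["gene"].isin(eqtl_genes)]
        if not with_eqtl.empty:
            gene, evidence = str(with_eqtl.iloc[0]["gene"]), "eqtl"
    # rule 4: nearest gene
    if gene is None:
        gene, evidence = str(genes.iloc[0]["gene"]), "nearest"

    # knowledge override within the nearest-10
    overridden = None
    relation = None
    if knowledge is not None and metabolite_id is not None and not knowledge.empty:
        known = knowledge[knowledge["metabolite_id"] == metabolite_id]
        in_near = known[known["gene"].isin(set(genes["gene"]))]
        if not in_near.empty:
            k_gene = str(in_near.iloc[0]["gene"])
            relation = str(in_near.iloc[0]["relation"])
            if k_gene != gene:
                overridden, gene, evidence = gene, k_gene, "knowledge-override"
            else:
                relation = relation  # concordant; keep tree evidence class
    action = "cis" if relation in ("enzyme", "transporter") else "trans"
    role = "other"
    if "protein_role" in genes.columns:
        row = genes[genes["gene"] == gene]
        if not row.empty:
            role = str(row.iloc[0]["protein_role"])
    elif relation in ("enzyme", "transporter"):
        role = relation
    return GeneNomination(signal_id, gene, evidence, action, role, overridden)


def cell_type_specificity(expression: pd.DataFrame) -> pd.Series:
    """Per-gene specific cell type, or None.

    ``expression``: genes x cell types mean expression (nonnegative). A
    gene is specific to the cell type carrying strictly more than 50% of
    its summed expression; all-zero genes map to None.
    """
    expr = expression.astype(float)
    if (expr < 0).any().any():
        raise ValueError("expression must be nonnegative")
    totals = expr.sum(axis=1)
    out = pd.Series([None] * len(expr), index=expr.index, dtype=object)
    nz = totals > 0
    props = expr.loc[nz].div(totals[nz], axis=0)
    best = props.idxmax(axis=1)
    frac = props.max(axis=1)
    out.loc[nz] = [b if f > 0.5 else None for b, f in zip(best, frac)]
    return out


def celltype_enrichment(
    nominated: set[str],
    background: set[str],
    specificity: pd.Series,
) -> pd.DataFrame:
    """Fisher's exact enrichment of nominated genes per cell type.

    For each cell type the 2x2 table crosses nominated-vs-rest with
    specific-vs-not; log2FC is the ratio of specific proportions in the
    nominated set vs the whole background (NaN when the background
    proportion is zero).
    """
    nominated = set(nominated)
    background = set(background)
    if not nominated <= background:
        raise ValueError("nominated genes must be a subset of the background")
    rest = background - nominated
    cell_types = sorted({c for c in specificity.dropna().unique()})
    rows = []
    for ct in cell_types:
        spec = set(specificity.index[specificity == ct]) & background
        a = len(nominated & spec)
        b = len(nominated - spec)
        c = len(rest & spec)
        d = len(rest - spec)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        prop_nom = a / len(nominated) if nominated else 0.0
        prop_bg = len(spec & background) / len(background) if background else 0.0
        log2fc = np.log2(prop_nom / prop_bg) if prop_bg > 0 and prop_nom > 0 else (
            np.nan if prop_bg == 0 else -np.inf
        )
        rows.append({"cell_type": ct, "log2fc": log2fc, "p": p,
                     "n_nominated_specific": a, "n_background_specific": len(spec)})
    return pd.DataFrame(rows)
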