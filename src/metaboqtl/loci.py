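"""Association regions, cross-metabolite loci, conditional signals,
novelty calls and cross-tissue sharing.

Regions: for one metabolite, the study-wide-significant variants go
through forward selection on p-value rank; each index variant claims a
window of +/- 1 Mb and overlapping or touching windows of the same
metabolite are merged (so merged regions may exceed 2 Mb). Loci apply the
same forward-selection-and-merge to the region lead variants of all
metabolites; a locus associated with more than one metabolite is
pleiotropic, and a metabolite with several loci is polygenic.

Independent signals within a region come from stepwise approximate
conditional analysis on summary statistics: conditional and joint effects
are reconstructed from the marginal estimates and an LD reference, with a
collinearity guard (squared multiple correlation < 0.9 with the selected
set) and a 10 Mb conditioning window, mirroring the summary-data
conditional-and-joint (COJO) approach.

Novelty: a region is "reported" when the reference catalogue holds a
significant variant of the matched metabolite inside the window; a
reported region's signal is nevertheless novel when colocalization with
the catalogue study gives PP.H4 <= 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

WINDOW_HALFWIDTH = 1_000_000


@dataclass
class AssociationRegion:
    metabolite_id: str
    lead_variant: str
    chrom: str
    lead_pos: int
    start: int
    end: int
    member_variants: list[str] = field(default_factory=list)
    independent_signals: list[dict] = field(default_factory=list)

    @property
    def window(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Locus:
    lead_variant: str
    chrom: str
    lead_pos: int
    start: int
    end: int
    member_metabolites: set[str] = field(default_factory=set)

    @property
    def pleiotropy_count(self) -> int:
        return len(self.member_metabolites)


def _forward_select(df: pd.DataFrame, halfwidth: int) -> list[dict]:
    """Iteratively claim +/- halfwidth windows around the best remaining
    p-value; ties broken by (chrom, pos, allele)."""
    work = df.sort_values(
        ["P", "CHR", "BP", "A1"], kind="mergesort"
    ).reset_index(drop=True)
    claimed = np.zeros(len(work), dtype=bool)
    windows = []
    for i in range(len(work)):
        if claimed[i]:
            continue
        lead = work.iloc[i]
        # 1-based inclusive 2 Mb window around the lead
        start = max(1, int(lead["BP"]) - halfwidth + 1)
        end = int(lead["BP"]) + halfwidth
        inside = (
            (work["CHR"] == lead["CHR"])
            & (work["BP"] >= start)
            & (work["BP"] <= end)
            & ~claimed
        )
        members = work.loc[inside, "SNP"].tolist()
        claimed |= inside.to_numpy()
        windows.append(
            {
                "lead": lead["SNP"],
                "chrom": lead["CHR"],
                "lead_pos": int(lead["BP"]),
                "lead_p": float(lead["P"]),
                "start": start,
                "end": end,
                "members": members,
            }
        )
    return windows


def _merge_windows(windows: list[dict]) -> list[dict]:
    """Merge touching/overlapping windows on the same chromosome, keeping
    the most significant lead."""
    merged: list[dict] = []
    for w in sorted(windows, key=lambda w: (str(w["chrom"]), w["start"])):
        if merged and merged[-1]["chrom"] == w["chrom"] and w["start"] <= merged[-1]["end"] + 1:
            prev = merged[-1]
            prev["end"] = max(prev["end"], w["end"])
            prev["members"] = prev["members"] + w["members"]
            if w["lead_p"] < prev["lead_p"]:
                prev.update(lead=w["lead"], lead_pos=w["lead_pos"], lead_p=w["lead_p"])
        else:
            merged.append(dict(w))
    return merged


def build_regions(
    significant: pd.DataFrame,
    window_halfwidth: int = WINDOW_HALFWIDTH,
) -> list[AssociationRegion]:
    """Metabolite-level association regions from study-wide-significant
    summary statistics (long format, any number of metabolites)."""
    regions: list[AssociationRegion] = []
    for metabolite, df in significant.groupby("phenotype", sort=True):
        for w in _merge_windows(_forward_select(df, window_halfwidth)):
            regions.append(
                AssociationRegion(
                    metabolite_id=str(metabolite),
                    lead_variant=w["lead"],
                    chrom=str(w["chrom"]),
                    lead_pos=w["lead_pos"],
                    start=w["start"],
                    end=w["end"],
                    member_variants=sorted(set(w["members"])),
                )
            )
    return regions


def build_loci(
    regions: list[AssociationRegion],
    significant: pd.DataFrame | None = None,
    window_halfwidth: int = WINDOW_HALFWIDTH,
) -> tuple[list[Locus], pd.DataFrame, pd.DataFrame]:
    """Cross-metabolite loci plus pleiotropy and polygenicity tables.

    Region leads (one row per region, p of the lead in its own scan when
    ``significant`` is given, else rank by position) go through the same
    forward-selection-and-merge; each locus counts its member metabolites.
    """
    if not regions:
        return [], pd.DataFrame(columns=["locus", "pleiotropy_count"]), pd.DataFrame(
            columns=["metabolite_id", "polygenicity"]
        )
    rows = []
    for r in regions:
        p = 0.0
        if significant is not None:
            hit = significant[
                (significant["phenotype"] == r.metabolite_id)
                & (significant["SNP"] == r.lead_variant)
            ]
            if len(hit):
                p = float(hit["P"].iloc[0])
        rows.append(
            {"SNP": r.lead_variant, "CHR": r.chrom, "BP": r.lead_pos,
             "A1": "", "P": p, "metabolite": r.metabolite_id}
        )
    leads = pd.DataFrame(rows)
    unique_leads = leads.drop_duplicates("SNP")[["SNP", "CHR", "BP", "A1", "P"]]
    windows = _merge_windows(_forward_select(unique_leads, window_halfwidth))

    loci = []
    for w in windows:
        members = set(
            leads.loc[
                (leads["CHR"] == w["chrom"])
                & (leads["BP"] >= w["start"])
                & (leads["BP"] <= w["end"]),
                "metabolite",
            ]
        )
        loci.append(
            Locus(
                lead_variant=w["lead"],
                chrom=str(w["chrom"]),
                lead_pos=w["lead_pos"],
                start=w["start"],
                end=w["end"],
                member_metabolites=members,
            )
        )
    pleiotropy = pd.DataFrame(
        {
            "locus": [l.lead_variant for l in loci],
            "chrom": [l.chrom for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "pleiotropy_count": [l.pleiotropy_count for l in loci],
            "metabolites": [",".join(sorted(l.member_metabolites)) for l in loci],
        }
    )
    counts: dict[str, int] = {}
    for l in loci:
        for m in l.member_metabolites:
            counts[m] = counts.get(m, 0) + 1
    polygenicity = pd.DataFrame(
        sorted(counts.items()), columns=["metabolite_id", "polygenicity"]
    )
    return loci, pleiotropy, polygenicity


# ---------------------------------------------------------------------------
# approximate conditional / joint analysis from summary statistics
# ---------------------------------------------------------------------------


def _cojo_setup(region_stats: pd.DataFrame, ld_reference) -> dict:
    snps = list(region_stats["SNP"])
    R = ld_reference.ld_corr(snps)
    f = ld_reference.subset_variants(snps).empirical_freqs()
    s2 = 2.0 * f * (1.0 - f)  # per-variant dosage variance under HWE
    b = region_stats["BETA"].to_numpy(dtype=float)
    se = region_stats["SE"].to_numpy(dtype=float)
    n = region_stats["N"].to_numpy(dtype=float)
    # phenotypic variance from the median marginal relation
    var_y = float(np.median(n * se**2 * s2 + b**2 * s2))
    return {
        "snps": snps, "R": np.nan_to_num(R), "s": np.sqrt(s2), "b": b,
        "se": se, "n": float(np.median(n)), "var_y": var_y,
        "bp": region_stats["BP"].to_numpy(), "p": region_stats["P"].to_numpy(),
    }


def _joint_fit(ctx: dict, idx: list[int]) -> tuple[np.ndarray, np.ndarray]:
    """Joint effects and SEs of the selected variant set from summary data."""
    s = ctx["s"][idx]
    R = ctx["R"][np.ix_(idx, idx)]
    n = ctx["n"]
    XtX = n * (np.outer(s, s) * R)
    Xty = n * (ctx["s"][idx] ** 2) * ctx["b"][idx]
    beta = np.linalg.solve(XtX, Xty)
    rss = n * ctx["var_y"] - beta @ Xty
    df = max(n - len(idx) - 1, 1)
    sigma2 = max(rss, 1e-12) / df
    cov = sigma2 * np.linalg.inv(XtX)
    return beta, np.sqrt(np.diag(cov))


def cojo_stepwise(
    region_stats: pd.DataFrame,
    ld_reference,
    p_threshold: float,
    collinearity_r2: float = 0.9,
    window: int = 10_000_000,
) -> list[dict]:
    """Stepwise forward selection of approximately independent signals.

    Starts from the most significant variant; at each step every
    remaining candidate's effect conditional on the selected set is
    reconstructed from marginal statistics and the reference LD, and the
    best candidate joins the set when its conditional p passes the
    threshold and its squared multiple correlation with the set stays
    below the collinearity cut. Returns the selected signals with their
    joint effects.
    """
    df = region_stats.reset_index(drop=True)
    if df.empty:
        return []
    ctx = _cojo_setup(df, ld_reference)
    order = np.argsort(ctx["p"], kind="mergesort")
    top = int(order[0])
    if ctx["p"][top] >= p_threshold:
        return []
    selected = [top]

    while True:
        best = None
        for j in range(len(df)):
            if j in selected:
                continue
            if min(abs(ctx["bp"][j] - ctx["bp"][k]) for k in selected) > window:
                continue
            r_js = ctx["R"][j, selected]
            R_ss = ctx["R"][np.ix_(selected, selected)]
            try:
                mult_r2 = float(r_js @ np.linalg.solve(R_ss, r_js))
            except np.linalg.LinAlgError:
                continue
            if mult_r2 >= collinearity_r2:
                continue
            try:
                beta, se = _joint_fit(ctx, selected + [j])
            except np.linalg.LinAlgError:
                continue
            z = beta[-1] / se[-1]
            p_cond = 2 * stats.norm.sf(abs(z))
            if p_cond < p_threshold and (best is None or p_cond < best[1]):
                best = (j, p_cond)
        if best is None:
            break
        selected.append(best[0])

    beta, se = _joint_fit(ctx, selected)
    out = []
    for k, idx in enumerate(selected):
        z = beta[k] / se[k]
        out.append(
            {
                "variant_id": ctx["snps"][idx],
                "joint_beta": float(beta[k]),
                "joint_se": float(se[k]),
                "conditional_p": float(2 * stats.norm.sf(abs(z))),
                "marginal_beta": float(ctx["b"][idx]),
                "marginal_p": float(ctx["p"][idx]),
                "rank": k,
            }
        )
    return out


# ---------------------------------------------------------------------------
# novelty and sharing
# ---------------------------------------------------------------------------


def classify_novelty(
    region: AssociationRegion,
    catalogue: pd.DataFrame,
    coloc_pp_h4: float | None = None,
    h4_cut: float = 0.6,
) -> str:
    """Classify a region against a reference association catalogue.

    Returns ``"reported-region"``, ``"novel-region"`` or
    ``"novel-signal-in-reported-region"``. Catalogue columns:
    metabolite_id, SNP, CHR, BP (P, study optional).
    """
    hits = catalogue[
        (catalogue["metabolite_id"] == region.metabolite_id)
        & (catalogue["CHR"].astype(str) == str(region.chrom))
        & (catalogue["BP"] >= region.start)
        & (catalogue["BP"] <= region.end)
    ]
    if hits.empty:
        return "novel-region"
    if coloc_pp_h4 is not None and coloc_pp_h4 <= h4_cut:
        return "novel-signal-in-reported-region"
    return "reported-region"


def novelty_summary(signals: list[str] | pd.Series) -> dict:
    """Counts and one-decimal percentage of novel entries.

    ``signals`` holds classification labels; anything starting with
    ``"novel"`` counts as novel.
    """
    labels = list(signals)
    total = len(labels)
    novel = sum(1 for s in labels if str(s).startswith("novel"))
    pct = round(100.0 * novel / total, 1) if total else 0.0
    return {"total": total, "novel": novel, "percent_novel": pct}


def pairwise_sharing(
    effects_a: np.ndarray,
    effects_b: np.ndarray,
    magnitude_factor: float = 0.0,
) -> float:
    """Fraction of aligned effects shared between two tissues.

    factor = 0: same sign. factor = 0.5: same sign and magnitude ratio
    within [factor, 1/factor] (two-fold). Zero effects are sign-agnostic
    matches.
    """
    a = np.asarray(effects_a, dtype=float)
    b = np.asarray(effects_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("effect vectors must be aligned")
    zero = (a == 0) | (b == 0)
    same_sign = (np.sign(a) == np.sign(b)) | zero
    if magnitude_factor <= 0:
        return float(same_sign.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(a) / np.abs(b)
    within = (ratio >= magnitude_factor) & (ratio <= 1.0 / magnitude_factor)
    within = within | zero
    return float((same_sign & within).mean())


def regions_to_bed(regions: list[AssociationRegion]) -> pd.DataFrame:
    """BED-like table (chrom, start, end, lead, metabolites) for export."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "lead": [r.lead_variant for r in regions],
            "metabolite": [r.metabolite_id for r in regions],
        }
    )
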