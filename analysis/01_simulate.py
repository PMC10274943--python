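"""Simulate the reference two-cohort study and record its ground truth.

Two cohorts of 1,000 samples, 5,000 variants in LD blocks, 40
metabolites. Planted structure: one pleiotropic variant driving three
metabolites, one polygenic metabolite with two distant QTLs, one
metabolite mediating a quantitative trait, three further single-QTL
metabolites, and 32 purely environmental metabolites. Writes the truth
table and a small design summary to results/; the full genotype and
metabolite matrices go to scratch/ (they are large and reproducible from
the seed).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import DEFAULT_SEED, SCRATCH, load_or_run, outdir

from metaboqtl import syndata

study, _ = load_or_run(DEFAULT_SEED)
out = outdir()

syndata.write_truth_table(study.truth, out / "truth_table.tsv")
SCRATCH.mkdir(exist_ok=True)
syndata.write_dosage_tsv(study.genotypes, SCRATCH / "dosages.tsv")
syndata.write_metabolome_tsv(
    study.metabolome, SCRATCH / "metabolome.tsv", out / "metabolite_meta.tsv"
)
syndata.write_sumstats(study.trait_stats, SCRATCH / "trait_sumstats.tsv")

print(f"samples: {study.genotypes.n_samples} in 2 cohorts")
print(f"variants: {study.genotypes.n_variants}")
print(f"metabolites: {len(study.metabolome.metabolites)}")
print(f"planted QTLs: {len(study.truth.qtls)}")
print(f"causal metabolite: {study.truth.causal_metabolite} "
      f"(effect {study.truth.causal_effect} trait units / SD)")
print(f"overall missingness: "
      f"{study.metabolome.values.isna().to_numpy().mean():.3f}")
print(f"truth table -> {out / 'truth_table.tsv'}")
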