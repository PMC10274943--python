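"""Metabolomics and genotype QC on the reference study.

Replays the staged metabolomics rule set (sample missingness, metabolite
missingness with disease-recovery check, per-cohort half-minimum
imputation, log10, low-variation filter, per-cohort IQR outlier masking,
minimum-observation filter) plus PCA sample outliers and variant-level
genotype QC, and writes the per-stage audit trail as JSON lines.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import DEFAULT_SEED, load_or_run, outdir

import numpy as np
import pandas as pd

from metaboqtl import qc

study, result = load_or_run(DEFAULT_SEED)
out = outdir()

clean, reports = qc.run_metabolite_qc(
    study.metabolome,
    disease_status=pd.Series(
        np.where(study.disease, "case", "control"), index=study.metabolome.samples
    ),
    cohorts=study.cohorts,
)
outliers = qc.sample_outliers_pca(clean)
_, geno_report = qc.genotype_qc(study.genotypes)

with open(out / "qc_report.jsonl", "w") as fh:
    for r in reports + [geno_report]:
        fh.write(json.dumps(r.to_dict()) + "\n")

for r in reports:
    print(f"{r.stage}: -{len(r.removed_samples)} samples, "
          f"-{len(r.removed_metabolites)} metabolites, "
          f"{r.masked_values} values masked")
print(f"PCA sample outliers: {len(outliers)}")
print(f"genotype QC removals: {geno_report.parameters['removed_per_filter']}")
print(f"audit trail -> {out / 'qc_report.jsonl'}")
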