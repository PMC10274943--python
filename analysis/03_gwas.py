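"""Per-metabolite GWAS, IVW meta-analysis and two-stage replication.

Each cohort is scanned separately (discovery / replication), the stages
are combined by fixed-effect inverse-variance weighting, and a
(metabolite, variant) pair is called significant when both stages are
nominally significant with consistent direction and the meta p passes
the study-wide threshold 5e-8 / n_metabolites. Writes the significant
associations and reports the genomic-control lambda of a null
metabolite as a calibration check.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import DEFAULT_SEED, load_or_run, outdir

from metaboqtl import gwas
from metaboqtl.syndata import write_sumstats

study, result = load_or_run(DEFAULT_SEED)
out = outdir()

sig = result.significant
write_sumstats(sig, out / "significant_associations.tsv")

print(f"study-wide threshold: {result.studywide_p:.3g}")
print(f"significant (metabolite, variant) pairs: {len(sig)}")
print(f"metabolites with >= 1 association: {sig['phenotype'].nunique()}")

# calibration: a metabolite without planted QTLs should be uninflated
null_met = "M020"
null_p = result.sumstats_meta.loc[
    result.sumstats_meta["phenotype"] == null_met, "P"
]
lam = gwas.genomic_inflation(null_p.to_numpy())
print(f"genomic inflation lambda for null metabolite {null_met}: {lam:.3f}")
print(f"associations -> {out / 'significant_associations.tsv'}")
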