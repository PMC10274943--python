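"""Shared plumbing for the numbered analysis drivers.

Simulating the reference study and carrying it through the pipeline
takes about a minute, so the result is cached (pickled) under scratch/
keyed by seed; delete scratch/ to force a fresh run. All tables the
drivers report are re-derived from that one PipelineResult.
"""

from __future__ import annotations

import pickle
from pathlib import Path

from metaboqtl import pipeline

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
DEFAULT_SEED = 11


def load_or_run(seed: int = DEFAULT_SEED):
    """Return (StudyData, PipelineResult), cached under scratch/."""
    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / f"pipeline_seed{seed}.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    study = pipeline.simulate_study(seed=seed)
    result = pipeline.run_pipeline(study, seed=seed)
    with open(cache, "wb") as fh:
        pickle.dump((study, result), fh)
    return study, result


def outdir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
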