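"""Shared cohort run for the analysis scripts.

All drivers analyse the same simulated wild-type cohort (60 train/yoked/blank
triplets, root seed 20200407).  The full pipeline output is cached under
``scratch/`` so the scripts can be run in any order; small summary tables go
to ``results/``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from opariant import SimConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "wild_type_run"

COHORT_SEED = 20200407
N_TRIPLETS = 60


def wild_type_run(make_figures: bool = False):
    """The cached pipeline result for the main cohort."""
    RESULTS.mkdir(exist_ok=True)
    marker = SCRATCH / "manifest.json"
    if not marker.exists():
        run_pipeline(sim=SimConfig(n_triplets=N_TRIPLETS, seed=COHORT_SEED),
                     out_dir=SCRATCH, make_figures=make_figures)
    return {
        "metrics": pd.read_csv(SCRATCH / "metrics.csv"),
        "per_fly": pd.read_csv(SCRATCH / "per_fly.csv"),
        "stats": json.loads((SCRATCH / "stats_report.json").read_text()),
        "curation": json.loads((SCRATCH / "curation.json").read_text()),
        "manifest": json.loads((SCRATCH / "manifest.json").read_text()),
    }
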