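"""Shared configuration and caching for the numbered analysis drivers.

The study cohort analysed by the drivers: 45 subjects per risk group,
90-node parcellation, nine metric layers, with the canonical left-hemisphere
lesion (attenuation 0.3 on a quarter of the intra-left edges) in the high
group.  Heavy intermediates are cached under ``scratch/`` (not part of the
deliverable); tables land in ``results/``.
"""

from __future__ import annotations

import pickle
from pathlib import Path

from semiconn.pipeline import CohortResults, RunConfig, run_cohort
from semiconn.synthetic import SyntheticConfig, generate_cohort, generate_volumes

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "analysis"
SCRATCH = ROOT / "scratch" / "analysis"

STUDY = SyntheticConfig(n_per_group=45, n_nodes=90, seed=2026)
RUN = RunConfig(synthetic=STUDY)

_CACHE = SCRATCH / "cohort_results.pkl"


def study_cohort() -> CohortResults:
    """The processed study cohort, cached across drivers."""
    if _CACHE.exists():
        with open(_CACHE, "rb") as fh:
            return pickle.load(fh)
    subjects, manifest = generate_cohort(STUDY)
    vols = generate_volumes(STUDY)
    res = run_cohort(subjects, manifest, RUN, subject_volumes=vols)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    with open(_CACHE, "wb") as fh:
        pickle.dump(res, fh)
    return res


def outdir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
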