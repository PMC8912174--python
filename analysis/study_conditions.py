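"""Shared study conditions for the numbered analysis scripts.

One synthetic cohort stands in for the restricted body-scan data: 400
participants (200 per sex) under the generator's default conditions.  All
scripts derive their inputs from this spec (or from the CSVs written by an
earlier script), so the whole analysis is reproducible from a single seed.
"""

from pathlib import Path

from torsoshape import pipeline, synth

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_SEED = 2026
COHORT = synth.CohortSpec(n=400, seed=STUDY_SEED)
CONFIG = pipeline.PipelineConfig(cohort=COHORT, seed=STUDY_SEED,
                                 output_dir=str(RESULTS))
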