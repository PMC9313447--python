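"""Shared configuration of the synthetic study the analysis drivers run.

200 patients (HT fraction as in the reference cohort, 11/71) on a 24x24x12
grid — the scaled-down study grid used for all Monte-Carlo work; the package
default of 32x32x16 remains available through ``CohortConfig()``.  Lesion
effect 2.0 standardized units; HT effect 1.0 on the lesioned hemisphere and
0.5 contralaterally.
"""

from pathlib import Path

from htpipe.cohort import CohortConfig

STUDY_DIR = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 0


def study_cohort_config() -> CohortConfig:
    return CohortConfig(n_patients=200, grid_shape=(24, 24, 12), seed=SEED)
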