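import numpy as np
import pytest

from s2cavd.pcg_synth import SynthProtocol, SyntheticSubject, synthesize_recording
from s2cavd.workbench import PipelineConfig, build_s2_dataset, imaging_labels
from s2cavd.pcg_synth import CohortSpec, synthesize_cohort


#: Compact acquisition scale used by signal-level tests: same physiology,
#: reduced rate/duration so a recording renders in milliseconds.
COMPACT_RATE = 20_000.0


@pytest.fixture(scope="session")
def compact_protocol() -> SynthProtocol:
    return SynthProtocol(sampling_rate_hz=COMPACT_RATE, duration_s=10.0, seed=7)


@pytest.fixture(scope="session")
def healthy_recording(compact_protocol):
    subj = SyntheticSubject("t01", "M", "Control")
    return synthesize_recording(compact_protocol, subj)


@pytest.fixture(scope="session")
def cohort_dataset():
    """Default synthetic cohort at compact scale: (subjects, records, calcification)."""
    cfg = PipelineConfig(seed=11)
    cohort = synthesize_cohort(CohortSpec(seed=11))
    labels = {s.subject_id: s.label for s in cohort}
    records = build_s2_dataset(cohort, cfg, labels)
    calcification = {s.subject_id: s.planted_calcification_pct for s in cohort}
    return cohort, records, calcification
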