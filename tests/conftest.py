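import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

import pepticlass as pc


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded discovery-sized cohort with planted markers and smooth drift."""
    spec = pc.CohortSpec(seed=11, marker_spec=pc.default_marker_spec(),
                         ce_drift_model="smooth")
    samples, truth = pc.generate_cohort(spec)
    return spec, samples, truth


@pytest.fixture(scope="session")
def preprocessed_matrix(small_cohort):
    """The small cohort calibrated, normalized and clustered."""
    _, samples, truth = small_cohort
    processed = []
    for s in samples:
        s2, _ = pc.calibrate_ce_time(s, truth.reference_table)
        processed.append(pc.normalize_amplitudes(s2, truth.housekeeping_table))
    return pc.match_peptides(processed), truth


def toy_peaklist(sample_id, rows, group="unlabeled"):
    return pc.PeakList(sample_id=sample_id, group=group,
                       peaks=np.array(rows, dtype=float))
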