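import numpy as np
import pandas as pd
import pytest

import thymeth as tm


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (4000 probes) with the default planted structure."""
    return tm.simulate_cohort(tm.SimulationConfig(n_probes=4000, seed=11))


@pytest.fixture(scope="session")
def small_filtered(small_cohort):
    beta, report = tm.filter_probes(
        small_cohort.beta, small_cohort.annotation, small_cohort.qc
    )
    return beta, report


@pytest.fixture(scope="session")
def fitted_results(small_cohort, small_filtered):
    beta, _ = small_filtered
    model = tm.PrognosticDLDA.from_cohort(
        beta, small_cohort.annotation.subset(beta.probe_ids), small_cohort.metadata
    )
    return model.fit()


@pytest.fixture()
def tiny_beta():
    """3 probes x 4 samples with known values."""
    vals = np.array(
        [
            [0.10, 0.20, 0.80, 0.90],
            [0.50, 0.50, 0.50, 0.50],
            [0.00, 1.00, 0.30, 0.70],
        ]
    )
    return tm.BetaMatrix.from_arrays(vals, ["cg1", "cg2", "cg3"], ["s1", "s2", "s3", "s4"])


def make_metadata(records: dict) -> tm.SampleMetadata:
    """Helper: records maps sample_id -> (histology, outcome)."""
    rows = {
        sid: {
            "histology": h,
            "outcome": o,
            "multifocal": False,
            "followup_months": 60.0,
            "recurrence_event": o == "PP",
            "batch": "b1",
        }
        for sid, (h, o) in records.items()
    }
    return tm.SampleMetadata(pd.DataFrame.from_dict(rows, orient="index"))
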