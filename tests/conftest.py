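import numpy as np
import pandas as pd
import pytest

import methylomp as M


@pytest.fixture(scope="session")
def small_cohort():
    """Planted cohort small enough for fast unit tests (2,000 CpGs)."""
    # extra saliva-side noise at displaced probes sized to emulate the
    # reported gap between outlier-CpG and non-outlier-CpG stability
    spec = M.CohortSpec(n_probes=2000, seed=11, omp_saliva_noise_sd=0.15)
    cord, saliva, sheet, ann, truth = M.simulate_cohort(spec)
    return {
        "spec": spec, "cord": cord, "saliva": saliva,
        "sheet": sheet, "ann": ann, "truth": truth,
    }


@pytest.fixture(scope="session")
def null_cohort():
    """Unplanted cohort for calibration-style unit tests."""
    spec = M.CohortSpec(n_probes=2000, seed=12, omp_individuals=())
    cord, saliva, sheet, ann, truth = M.simulate_cohort(spec)
    return {
        "spec": spec, "cord": cord, "saliva": saliva,
        "sheet": sheet, "ann": ann, "truth": truth,
    }


@pytest.fixture
def tiny_matrix():
    return M.BetaMatrix.from_arrays(
        ["p1", "p2"], ["s1", "s2"], np.array([[0.1, 0.9], [0.5, 0.5]])
    )


@pytest.fixture
def paired_sheet():
    """31 individuals; 24 with both tissues, 4 cord-only, 3 saliva-only."""
    rows = []
    for i in range(31):
        ind = f"i{i:02d}"
        fam = f"f{i:02d}"
        if i < 24:
            rows.append((f"{ind}_cb", ind, fam, "cord_blood", "birth", ""))
            rows.append((f"{ind}_sal", ind, fam, "saliva", "childhood", ""))
        elif i < 28:
            rows.append((f"{ind}_cb", ind, fam, "cord_blood", "birth", ""))
        else:
            rows.append((f"{ind}_sal", ind, fam, "saliva", "childhood", ""))
    return M.SampleSheet(
        pd.DataFrame(
            rows,
            columns=["sample_id", "individual_id", "family_id",
                     "tissue", "timepoint", "group"],
        )
    )
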