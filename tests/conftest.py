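import numpy as np
import pandas as pd
import pytest

import methimmune as mi
from methimmune.synthetic import DEFAULT_CELL_TYPES

CELL_TYPES = list(DEFAULT_CELL_TYPES)


@pytest.fixture(scope="session")
def ref_panel():
    """Default synthetic reference panel: 7 types x 6 replicates, 2000 genes,
    50 planted markers/type, contrast 0.4, replicate noise 0.02."""
    return mi.generate_reference_panel(seed=11)


@pytest.fixture(scope="session")
def signature(ref_panel):
    panel, sheet, _ = ref_panel
    cfg = mi.RunConfig(entropy_threshold_mode="top_m", entropy_threshold_value=350)
    return mi.select_markers(panel, sheet, cfg)


@pytest.fixture(scope="session")
def cohort():
    """Default two-pseudo-cancer synthetic cohort with planted subtypes."""
    return mi.generate_cohort(seed=7)


@pytest.fixture(scope="session")
def pipeline_result(cohort):
    cfg = mi.RunConfig(entropy_threshold_value=350, k_max=8, seed=7)
    return mi.run_pipeline(cohort.reference, cohort.reference_sheet,
                           cohort.bulk, cohort.sheet, cfg)


def make_fraction_cohort(rng, n_tumor=80, n_normal=40, shift_cell_type=None,
                         shift=0.15, concentration=300.0, mass=(0.1, 0.3)):
    """Fraction matrix + sheet + labels for annotation simulations, drawn from
    the cohort generator's compositional model without the mixing step."""
    mean = np.full(7, 1 / 7)
    tum_mean = mean.copy()
    if shift_cell_type is not None:
        j = CELL_TYPES.index(shift_cell_type)
        tum_mean[j] += shift
        tum_mean = tum_mean / tum_mean.sum()
    comp_t = rng.dirichlet(concentration * tum_mean, size=n_tumor)
    comp_n = rng.dirichlet(concentration * mean, size=n_normal)
    m = rng.uniform(*mass, size=n_tumor + n_normal)
    frac = np.vstack([comp_t, comp_n]) * (1 - m)[:, None]
    ids = [f"s{i:03d}" for i in range(n_tumor + n_normal)]
    df = pd.DataFrame(frac, index=ids, columns=CELL_TYPES)
    sheet = mi.SampleSheet(pd.DataFrame({
        "sample_id": ids,
        "group": ["tumor"] * n_tumor + ["normal"] * n_normal,
        "cancer_type": "SIM",
    }))
    labels = pd.Series("S1", index=ids[:n_tumor])
    return df, sheet, labels
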