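import numpy as np
import pandas as pd
import pytest

from lifemet import generate_cohort, scenario_presets
from lifemet.metabolites import MetaboliteMatrix, fasting_adjust


@pytest.fixture(scope="session")
def null_cohort():
    """Default-sized cohort with every effect parameter zero."""
    cfg = scenario_presets("null", seed=101)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def mediated_cohort():
    """Cohort with a -8/10k PY HLS effect, half mediated by three metabolites."""
    cfg = scenario_presets("mediated", seed=202)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_matrix():
    """A tiny 3-metabolite matrix for metabolite-level unit tests."""
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        {
            "lipoprotein_1": rng.normal(5, 1, 40),
            "amino_acid_1": rng.normal(0.4, 0.1, 40),
            "bacterial_1": rng.normal(1.2, 0.3, 40),
        }
    )
    groups = {
        "lipoprotein_1": "lipoprotein",
        "amino_acid_1": "amino_acid",
        "bacterial_1": "bacterial",
    }
    return MetaboliteMatrix(values=values, groups=groups)


@pytest.fixture(scope="session")
def prospective(mediated_cohort):
    """Prospective analysis set of the mediated cohort (fasting-adjusted)."""
    part, mat, outc, truth = mediated_cohort
    keep = ((outc["prevalent_diabetes"] == 0) & (outc["lost_to_follow_up"] == 0)).to_numpy()
    part = part.loc[keep].reset_index(drop=True)
    outc = outc.loc[keep].reset_index(drop=True)
    adj = fasting_adjust(
        MetaboliteMatrix(
            values=mat.values.loc[keep].reset_index(drop=True), groups=mat.groups
        ),
        part["fasting_hours"].to_numpy(),
    )
    return part, adj, outc, truth
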