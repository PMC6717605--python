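import numpy as np
import pandas as pd
import pytest

from swallowscreen.core import (
    BolusTrial,
    CohortDataset,
    Consistency,
    PipelineConfig,
    VfssRating,
)
from swallowscreen.synthetic import make_table2_fixture


@pytest.fixture(scope="session")
def table2_cohort() -> CohortDataset:
    return make_table2_fixture()


@pytest.fixture()
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture()
def fast_config() -> PipelineConfig:
    """Documented fast mode for Monte-Carlo tests."""
    return PipelineConfig(n_iterations=200, seed=0)


def make_trial(pid="P1", consistency=Consistency.thin, idx=1, pas=1, vall=0.0, pyr=0.0):
    return BolusTrial(
        participant_id=pid,
        consistency=consistency,
        bolus_index=idx,
        rating=VfssRating(pas=pas, vallecular_fill=vall, pyriform_fill=pyr),
    )


def gaussian_feature_table(
    n_participants: int = 60,
    n_boluses: int = 4,
    n_features: int = 8,
    effect: float = 0.0,
    prevalence: float = 0.4,
    seed: int = 0,
    consistency: Consistency = Consistency.thin,
) -> pd.DataFrame:
    """Synthetic feature table shaped like ``build_feature_table`` output.

    Impaired participants' boluses get a mean shift of ``effect`` (in units
    of the within-class SD) on every feature; bolus noise is independent.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        pid = f"G{i:03d}"
        impaired = int(rng.random() < prevalence)
        for b in range(1, n_boluses + 1):
            x = rng.normal(0.0, 1.0, n_features) + effect * impaired
            row = {
                "participant_id": pid,
                "consistency": consistency.name,
                "bolus_index": b,
                "safety_label": impaired,
                "efficiency_label": impaired,
                "n_segments": 1,
            }
            row.update({f"f{j}": x[j] for j in range(n_features)})
            rows.append(row)
    return pd.DataFrame(rows)
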