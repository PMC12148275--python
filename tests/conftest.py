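import numpy as np
import pandas as pd
import pytest

from spatialtil import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured synthetic cohort shared across tests.

    Intensities are reduced (and QC bounds in pipeline tests relaxed to
    match) so the whole suite stays fast; the statistical structure —
    clustered tumor, diffuse lymphocytes, PH survival, logistic labels —
    is the same as at full scale.
    """
    config = SimulationConfig(
        n_participants=40,
        cores_per_participant=2,
        tumor_intensity=300,
        lymphocyte_intensity=60,
        stroma_intensity=120,
        seed=101,
    )
    return simulate_cohort(config, qc_min_tumor=50, qc_min_total=100)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_survival(n, rng, frac_low=0.5, beta=0.0,
                  baseline=0.015, censor=0.085, metric="proximity"):
    """Binary-metric PH survival data via the package generator."""
    from spatialtil import SimulationConfig, simulate_survival

    binary = pd.DataFrame(
        {metric: np.where(rng.random(n) < frac_low, "low", "high")},
        index=pd.Index([f"p{i}" for i in range(n)], name="participant_id"),
    )
    cfg = SimulationConfig(
        n_participants=max(n, 1),
        survival_betas={metric: beta},
        baseline_hazard=baseline,
        censor_rate=censor,
        seed=0,
    )
    surv = pd.DataFrame(
        {
            "participant_id": binary.index,
            **{
                c: v
                for c, v in simulate_survival(binary, cfg, rng=rng)
                .drop(columns="participant_id")
                .items()
            },
        }
    )
    surv["low"] = (binary[metric].to_numpy() == "low").astype(float)
    return surv
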