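import numpy as np
import pytest

import atpmax as am


@pytest.fixture
def mammalian_like_model() -> am.CellModel:
    """Two-pathway model in the Warburg regime: respiration has the higher
    yield, glycolysis the higher specific activity of ATP production."""
    return am.CellModel(
        (
            am.PathwayParams(
                "glycolysis", atp_yield=2, specific_activity=1.0,
                byproduct_per_glucose=2, byproduct_name="lactate",
            ),
            am.PathwayParams(
                "respiration", atp_yield=24, specific_activity=0.08,
                o2_per_glucose=6,
            ),
        ),
        phi_total_atp=0.1,
    )


@pytest.fixture
def ecoli_model() -> am.CellModel:
    return am.load_cell_model("ecoli")


@pytest.fixture
def yeast_truth_config() -> am.SyntheticConfig:
    """Synthetic yeast-like ground truth inside the Warburg parameter regime
    (gamma*Vmax: fermentation 7.5 > respiration 4.6)."""
    return am.SyntheticConfig(
        true_phi={"glycolysis": 0.05, "respiration": 0.10},
        true_vmax={"glycolysis": 3.75, "respiration": 0.2875},
        true_gamma={"glycolysis": 2, "respiration": 16},
        organism="yeast",
        n_proteomics_samples=20,
        n_measurements_per_kind=20,
        noise_cv=0.0,
        seed=0,
    )


def random_warburg_params(rng: np.random.Generator) -> am.CellModel:
    """Random two-pathway model with all five parameters log-uniform over
    three decades, conditioned on nothing (any yield/rate ordering)."""
    g1, g2 = 10 ** rng.uniform(-1, 2, 2)
    v1, v2 = 10 ** rng.uniform(-2, 1, 2)
    phi = 10 ** rng.uniform(-2, 0)
    return am.CellModel(
        (
            am.PathwayParams("glycolysis", g1, v1, byproduct_per_glucose=2,
                             byproduct_name="lactate"),
            am.PathwayParams("respiration", g2, v2, o2_per_glucose=6),
        ),
        phi_total_atp=phi,
    )
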