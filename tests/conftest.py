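import numpy as np
import pytest

from coldstress import ahp, fce, io


@pytest.fixture(scope="session")
def expert_config():
    return io.load_model(io.fixture_path("expert.yaml"))


@pytest.fixture(scope="session")
def expert_hierarchy(expert_config):
    return expert_config.panels["expert"]


@pytest.fixture(scope="session")
def farmer_config():
    return io.load_model(io.fixture_path("farmer.yaml"))


@pytest.fixture(scope="session")
def farmer_hierarchy(farmer_config):
    return farmer_config.panels["farmer"]


@pytest.fixture(scope="session")
def worked_example_config():
    return io.load_model(io.fixture_path("worked_example.yaml"))


@pytest.fixture(scope="session")
def default_spec():
    return io.default_membership_spec()


@pytest.fixture(scope="session")
def nov9_record():
    """The published November-9 calf-day used in the worked example."""
    return fce.CalfDailyRecord(
        calf_id="calf_ex",
        date="2022-11-09",
        temperature_c=1.21,
        humidity_pct=71.30,
        wind=9.34,
        weight_kg=36.7,
        height_cm=76.0,
        diagonal_cm=55.0,
        chest_cm=80.0,
        lying_min=1290.39,
        standing_min=149.61,
        rr_per_min=34.0,
        urination_n=2.0,
    )


def consistent_matrix(w: np.ndarray, labels=None) -> ahp.JudgmentMatrix:
    """Perfectly consistent judgment matrix a_ij = w_i / w_j."""
    w = np.asarray(w, dtype=float)
    if labels is None:
        labels = tuple(f"x{i + 1}" for i in range(w.size))
    return ahp.JudgmentMatrix(w[:, None] / w[None, :], labels)
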