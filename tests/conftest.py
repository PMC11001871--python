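import pytest

from pulsim import model, preprocess, synthdata
from pulsim.synthdata import DynamicsParams, GroupDesign


def small_designs(n_groups: int = 5) -> list[GroupDesign]:
    """A few contrasting arms: control, drug-only, RT, RT+drug, two-pulse."""
    ms = (1, 4, 7, 10, 14, 18)
    eod = tuple(range(1, 19, 2))
    designs = [
        GroupDesign("g1", (), "isotype", eod, 4, ms),
        GroupDesign("g2", (), "anti_pdl1", eod, 4, ms),
        GroupDesign("g3", ((3, 6.0),), "isotype", eod, 4, ms),
        GroupDesign("g4", ((3, 6.0),), "anti_pdl1", eod, 4, ms),
        GroupDesign("g5", ((3, 6.0), (13, 6.0)), "anti_pdl1", eod, 4, ms),
        GroupDesign("g6", ((3, 3.0),), "anti_pdl1", eod, 4, ms),
    ]
    return designs[:n_groups]


@pytest.fixture(scope="session")
def tiny_study():
    return synthdata.generate_study(small_designs(6), seed=101)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_study):
    return preprocess.build_dataset(tiny_study, n_samples=10, seed=102)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    """A cheaply trained surrogate — functional, not accurate."""
    cfg = model.ModelConfig(hidden_units=16, epochs=60, batch_size=30, seed=103)
    result = model.train(tiny_dataset, cfg, validation_groups=())
    return result.model


@pytest.fixture(scope="session")
def recovery():
    """The timing-recovery experiment: study with known 7-day immune delay
    and a surrogate trained on drug-timing-varied arms (500 epochs, 50 units).
    """
    study = synthdata.generate_study(
        synthdata.offset_recovery_config(), seed=1, params=DynamicsParams()
    )
    dataset = preprocess.build_dataset(study, n_samples=50, seed=2)
    cfg = model.ModelConfig(hidden_units=50, epochs=500, seed=3)
    result = model.train(dataset, cfg, validation_groups=())
    return study, result.model
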