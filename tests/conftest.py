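import numpy as np
import pytest

from respiroflux import synth_data, trace_io


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def noiseless_config():
    return synth_data.CohortConfig(
        n_control=3, n_disease=2, noise=synth_data.NoiseModel().zeroed()
    )


@pytest.fixture
def small_config():
    return synth_data.CohortConfig(n_control=6, n_disease=5)


def make_well(
    basal=(100.0, 100.0, 100.0),
    oligo=(45.0, 40.0, 42.0),
    fccp=(140.0, 150.0, 145.0),
    aarot=(22.0, 20.0, 21.0),
    seeding=20e6,
    well_id="W1",
    animal_id="M001",
    group="control",
    o2_level=150.0,
):
    """Hand-built 12-cycle stress-test well with injections after cycles 3/6/9."""
    values = list(basal) + list(oligo) + list(fccp) + list(aarot)
    cycles = []
    for i, v in enumerate(values):
        t = (i + 1) * 360.0 - 90.0
        ticks = [(t - 60.0 + 20.0 * j, o2_level - j) for j in range(4)]
        cycles.append(trace_io.Cycle(i + 1, t, float(v), ticks))
    injections = [
        trace_io.InjectionEvent(trace_io.OLIGOMYCIN, "A", 3 * 360.0, "2.5 uM"),
        trace_io.InjectionEvent(trace_io.FCCP, "B", 6 * 360.0, "0.4 uM"),
        trace_io.InjectionEvent(trace_io.ANTIMYCIN_ROTENONE, "C", 9 * 360.0, "5 uM"),
    ]
    return trace_io.WellSeries(
        well_id=well_id, group_label=group, animal_id=animal_id,
        seeding_count=seeding, cycles=cycles, injections=injections,
    )


@pytest.fixture
def well_factory():
    return make_well
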