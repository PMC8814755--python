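import numpy as np
import pytest

from mechanonps import AcquisitionConfig, ChannelGeometry, PipelineConfig
from mechanonps.simulate import sigma_for_snr, stiff_viscous_group


@pytest.fixture(scope="session")
def geometry() -> ChannelGeometry:
    return ChannelGeometry()


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture()
def noiseless_acq() -> AcquisitionConfig:
    return AcquisitionConfig(noise_sigma=0.0, seed=11)


@pytest.fixture()
def snr20_acq() -> AcquisitionConfig:
    return AcquisitionConfig(noise_sigma=sigma_for_snr(20), seed=11)


@pytest.fixture(scope="session")
def small_noiseless_run(geometry):
    """Five noiseless simulated cells processed end to end (shared across
    tests that only read the result)."""
    from mechanonps import match_events_to_truth, process_trace, simulate_trace

    cfg = PipelineConfig()
    acq = AcquisitionConfig(noise_sigma=0.0, seed=21)
    trace, truth = simulate_trace([(stiff_viscous_group(), 5)], acq, geometry)
    events, subpulses, features, counts = process_trace(trace, cfg)
    merged = match_events_to_truth(features, truth)
    return {
        "trace": trace,
        "truth": truth,
        "events": events,
        "subpulses": subpulses,
        "features": features,
        "counts": counts,
        "merged": merged,
    }


@pytest.fixture(autouse=True)
def _seed_numpy():
    np.random.seed(0)
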