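import logging

import pytest

from twitchtaxis.pipeline_cli import analyze_simulation
from twitchtaxis.synthetic_microscopy import (
    alternating_gradient_scenario,
    default_event_script,
    simulate_experiment,
)

logging.getLogger("twitchtaxis").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def closure_sim():
    """Alternating-gradient experiment at study scale: 200 cells, 90 min,
    one gradient swap, a mixed script of 12 repolarization events,
    noise-free rendering."""
    cfg = alternating_gradient_scenario(
        n_cells=200, duration=90.0, swap_times=(44.0,),
        events=default_event_script(), rng_seed=1)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def closure_analysis(closure_sim):
    """Full pipeline output (tracks, polarity, events) for the closure
    simulation, with thresholds calibrated from the data."""
    return analyze_simulation(closure_sim)
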