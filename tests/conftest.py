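import numpy as np
import pandas as pd
import pytest

from hurdlecall.simulator import SimulationConfig, simulate_reads

PROB_FLOOR = 1e-15

# Worked probability vectors over HPL 0..n for three archetypal flows:
# a long-homopolymer undercall candidate, an overcall candidate, and a
# zero call with appreciable mass at one base.  Unprinted cells sit at
# the display floor.
TABLE1_PROBS = np.array([PROB_FLOOR, PROB_FLOOR, PROB_FLOOR, 7.4e-9, 0.83, 0.17, 6.3e-11])
TABLE2_PROBS = np.array([PROB_FLOOR, 1.7e-10, 0.29, 0.71, 3e-9, PROB_FLOOR])
TABLE3_PROBS = np.array([0.75, 0.25, 2.9e-8, PROB_FLOOR, PROB_FLOOR])


@pytest.fixture(scope="session")
def small_sim():
    """A small signal-based simulation shared across read-level tests."""
    config = SimulationConfig(n_reads=40, read_length=80, seed=42)
    flows, truth = simulate_reads(config)
    return config, flows, truth


@pytest.fixture(scope="session")
def trained_model(small_sim):
    """A hurdle model trained on a modest simulated run (shared; slow)."""
    import warnings

    from hurdlecall.gam import HurdleBaseCaller

    _, flows, _ = small_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return HurdleBaseCaller(theta_grid=(0.0, 0.2, 0.8), penalty_grid=(1e-2, 1.0, 1e2)).fit(
            flows
        )
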