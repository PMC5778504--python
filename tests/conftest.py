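import numpy as np
import pytest

import bubblefret as bf


@pytest.fixture(scope="session")
def wt_scenario():
    return bf.load_scenario("wt_dsDNA_22C")


@pytest.fixture(scope="session")
def wt_dynamic_scheme(wt_scenario):
    return next(
        s.scheme for s in wt_scenario.subpopulations if s.label == "dynamic"
    )


def two_state_scheme(k12: float, k21: float, fret=(0.2, 0.45)):
    return bf.KineticScheme.from_rates(
        ["closed", "open"], list(fret), ["closed", "open"],
        {("closed", "open"): k12, ("open", "closed"): k21},
    )


@pytest.fixture(scope="session")
def noiseless_params():
    return bf.PhotophysicsParams(
        donor_bleach_rate=0.0, acceptor_bleach_rate=0.0,
        background_per_channel=0.0, read_noise_sd=0.0, shot_noise=False,
    )
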