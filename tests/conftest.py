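import numpy as np
import pytest

from dropmap import calibration as cal
from dropmap import synth
from dropmap.config import AcquisitionSchedule, AssayChemistry, NoiseModel


@pytest.fixture(scope="session")
def chem():
    return AssayChemistry()


@pytest.fixture(scope="session")
def sched():
    return AcquisitionSchedule()


@pytest.fixture(scope="session")
def model(chem, sched):
    """Calibration model fitted from the default synthetic anchor panel."""
    return cal.fit_calibration(cal.make_anchor_panel(chem, sched), chem)


@pytest.fixture(scope="session")
def noiseless():
    return NoiseModel(read_noise_sd=0.0, shot_noise=False,
                      movement_fraction=0.0, artifact_fraction=0.0)


@pytest.fixture(scope="session")
def small_secretor_stack(chem, sched, noiseless):
    """12 rendered droplets, each with one secreting cell (known truth)."""
    rates = np.array([5.0, 10.0, 20.0, 33.0, 50.0, 80.0, 120.0, 200.0,
                      15.0, 25.0, 40.0, 60.0])
    kds = np.array([0.5, 1.0, 2.3, 5.0, 10.0, 30.0, 65.0, 100.0,
                    20.0, 50.0, 80.0, 3.0]) * 1e-9
    cfg, droplets, cells, traces = synth.make_secretor_cohort(rates, kds, chem, sched)
    rng = np.random.default_rng(1234)
    red, green, info = synth.render_stack(
        droplets, traces, noiseless, sched, synth.chamber_shape_for(cfg), rng
    )
    return {
        "config": cfg,
        "droplets": droplets,
        "cells": cells,
        "traces": traces,
        "red": red,
        "green": green,
        "info": info,
        "rates": rates,
        "kds": kds,
    }
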