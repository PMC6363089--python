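"""Shared fixtures: the CBB model, synthetic inputs and a reduced ensemble.

The expensive session fixtures (the reduced-scale ensemble run) are shared
across stability, control-analysis and acceptance tests so the pipeline is
executed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from cbbkin import fixtures, kinetics, sampling
from cbbkin.model import load_cbb_model
from cbbkin.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def cbb_model():
    model = load_cbb_model()
    flux = fixtures.generate_flux_vector(model, seed=1)
    fixtures.apply_flux(model, flux)
    return model


@pytest.fixture(scope="session")
def cbb_flux(cbb_model):
    return np.array([cbb_model.reaction(r).v0 for r in cbb_model.reaction_ids])


@pytest.fixture(scope="session")
def small_fmcs(cbb_model):
    """A handful of feasible metabolomes for unit-level tests."""
    return sampling.generate_fmcs(
        cbb_model, max_rounds=2_000_000, target=5, seed=7
    )


@pytest.fixture(scope="session")
def calibrated_ensemble(cbb_model, cbb_flux, small_fmcs):
    """40 calibrated parameter sets around the first feasible metabolome."""
    s = small_fmcs.samples[0]
    x0 = sampling.full_concentration_vector(cbb_model, s)
    ens = kinetics.sample_parameter_ensemble(cbb_model, s, 40, seed=7)
    kinetics.calibrate_vmax_ensemble(cbb_model, ens, x0, cbb_flux)
    return s, x0, ens


@pytest.fixture(scope="session")
def reduced_ensemble_run(tmp_path_factory):
    """The reduced-scale ensemble: 300 fMCSs x 200 parameter sets.

    This is the scale used for the distributional reproductions; the decile
    contrast in particular needs a few hundred metabolomes for its deciles
    to be informative.
    """
    outdir = tmp_path_factory.mktemp("ensemble") / "run"
    cfg = RunConfig(
        outdir=str(outdir),
        target_fmcs=300,
        sets_per_fmcs=200,
        max_rounds=40_000_000,
        seed=1,
        n_bootstrap=100,
    )
    summary = run_pipeline(cfg)
    return cfg, summary
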