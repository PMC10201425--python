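"""Shared fixtures: expensive synthetic studies computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

import ribomech as rm
from ribomech.fes import GridSpec
from ribomech.synthetic import AnalyticPotential, SamplerConfig, dense_grid_extrema


@pytest.fixture(scope="session")
def double_well_windows() -> rm.UmbrellaWindowSet:
    """Umbrella study of the a=5 double well: 16 windows, 5000 samples each."""
    pot = AnalyticPotential.make("double_well_1d", a=5.0)
    centers = [[c] for c in np.linspace(-1.5, 1.5, 16)]
    cfg = SamplerConfig(n_samples_per_window=5000, burn_in=500, seed=42)
    return rm.gen_umbrella_samples(pot, centers, 100.0, cfg)


@pytest.fixture(scope="session")
def double_well_fes(double_well_windows) -> rm.FreeEnergySurface:
    return rm.wham(double_well_windows, GridSpec((-1.5,), (1.5,), (0.05,)))


@pytest.fixture(scope="session")
def two_channel_study() -> dict:
    """Analytic two-channel surface, its grid-search oracle and converged string."""
    pot = AnalyticPotential.make("two_channel_2d")  # a=2, tilt c=0.6
    grid = GridSpec((-1.6, -1.6), (1.6, 1.6), (0.04, 0.04))
    surface = rm.FreeEnergySurface.from_function(pot.energy, grid)
    oracle = dense_grid_extrema(pot)
    path = rm.string_mfep(
        surface,
        rm.ReactionPath.straight((-1.0, -1.0), (1.0, 1.0), 32),
        n_images=32,
        tol=1e-4,
    )
    return {"potential": pot, "surface": surface, "oracle": oracle, "path": path}


@pytest.fixture(scope="session")
def isotropic_toy_structure():
    """5000-model toy structure with uniform per-residue sigma 0.5 Å."""
    return rm.gen_toy_structure(
        n_residues=8, atoms_per_residue=3, per_residue_sigma=0.5, n_models=5000, seed=9
    )
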