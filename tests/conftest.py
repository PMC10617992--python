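"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's vectorized evaluation paths:
they loop over explicitly enumerated states and use plain ``math.exp`` so
that agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from zincsite.statespace import (
    Condition,
    SiteModel,
    TitratableResidue,
    enumerate_microstates,
)


def brute_force_weights(model: SiteModel, cond: Condition) -> list[float]:
    """Boltzmann weights by explicit per-state looping (independent oracle)."""
    weights = []
    for state in enumerate_microstates(model.n_residues):
        idx = state.proton_code + (int(state.zinc_bound) << model.n_residues)
        g = model.g[idx] + state.n_protons * math.log(10.0) * cond.pH
        if state.zinc_bound:
            if cond.zn_free == 0:
                weights.append(0.0)
                continue
            g -= math.log(cond.zn_free / model.c0)
        weights.append(math.exp(-g))
    return weights


def brute_force_probabilities(model: SiteModel, cond: Condition) -> list[float]:
    w = brute_force_weights(model, cond)
    z = sum(w)
    return [v / z for v in w]


def brute_force_bound_fraction(model: SiteModel, cond: Condition) -> float:
    p = brute_force_probabilities(model, cond)
    m = 1 << model.n_residues
    return sum(p[m:])


def brute_force_deprotonation_fraction(
    model: SiteModel, residue: str, cond: Condition
) -> float:
    bit = model.residue(residue).bit_index
    p = brute_force_probabilities(model, cond)
    total = 0.0
    for state in enumerate_microstates(model.n_residues):
        if state.protons[bit] == 0:
            total += p[state.proton_code + (int(state.zinc_bound) << model.n_residues)]
    return total


def random_model(rng: np.random.Generator, n_residues: int) -> SiteModel:
    """A random but valid SiteModel with moderate energies."""
    n_states = 1 << (n_residues + 1)
    g = rng.uniform(-12.0, 12.0, n_states)
    g[0] = 0.0
    residues = [TitratableResidue(f"R{i}", i) for i in range(n_residues)]
    return SiteModel(residues, g)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
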