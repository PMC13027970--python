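"""Shared fixtures: small geometries and cached coarse-grid solves."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from poreflow.geometry import DomainSpec, build_mask, seal_membrane
from poreflow.solver import (
    FluidProperties,
    InletSpec,
    SolverConfig,
    solve_steady,
)


@pytest.fixture(scope="session")
def props() -> FluidProperties:
    return FluidProperties()


@pytest.fixture(scope="session")
def inlet() -> InletSpec:
    return InletSpec()


@pytest.fixture(scope="session")
def tiny_spec() -> DomainSpec:
    """Single pore, coarse grid: the fastest full-physics configuration."""
    return DomainSpec(n_pores=1, dx_um=0.5)


@pytest.fixture(scope="session")
def tiny_mask(tiny_spec):
    return build_mask(tiny_spec)


@pytest.fixture(scope="session")
def tiny_solution(tiny_spec, tiny_mask, props, inlet):
    """Converged coupled solve of the tiny 1-pore case (cached per session)."""
    field, report = solve_steady(tiny_spec, props, inlet, SolverConfig(), mask=tiny_mask)
    return field, report


@pytest.fixture(scope="session")
def two_pore_spec() -> DomainSpec:
    return DomainSpec(n_pores=2, dx_um=0.5)


@pytest.fixture(scope="session")
def two_pore_solution(two_pore_spec, props, inlet):
    mask = build_mask(two_pore_spec)
    field, report = solve_steady(two_pore_spec, props, inlet, SolverConfig(), mask=mask)
    return mask, field, report


@pytest.fixture(scope="session")
def sealed_solution(props, inlet):
    """Sealed-membrane (plain duct) solve used for Poiseuille recovery."""
    spec = DomainSpec(n_pores=1, dx_um=0.5)
    mask = seal_membrane(build_mask(spec))
    field, report = solve_steady(spec, props, inlet, SolverConfig(), mask=mask)
    return spec, mask, field, report


def max_abs(a: np.ndarray) -> float:
    return float(np.max(np.abs(a)))
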