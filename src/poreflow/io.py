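"""File export, run manifests and named test fixtures.

All outputs are plain text: CSV for fields, summaries and residual
histories, legacy-VTK ``STRUCTURED_POINTS`` and Tecplot ASCII ``POINT``
zones for visualisation tools, and a JSON manifest that records every
resolved parameter of a run so it can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import DomainSpec, GridMask
from .solver import FlowField, FluidProperties, InletSpec, SolverConfig, SolverReport

__all__ = [
    "RunManifest",
    "field_to_dataframe",
    "write_field_csv",
    "write_vtk",
    "write_tecplot",
    "write_residuals_csv",
    "round_to_sig_figs",
    "make_fixture",
    "Fixture",
    "FIXTURE_NAMES",
]


def round_to_sig_figs(value: float, n: int) -> float:
    """Decimal round-half-up to ``n`` significant figures.

    Used when reporting values at a table's printed precision; a plain
    float format would round 1.875 down because of its binary
    representation, whereas tables round it up to 1.88.
    """
    if value == 0 or not np.isfinite(value):
        return value
    from decimal import ROUND_HALF_UP, Decimal

    # shed binary representation noise first (12 significant digits), then
    # round half-up at the requested precision
    d = Decimal(f"{value:.12e}")
    shift = d.adjusted()  # exponent of the leading digit
    quantum = Decimal(1).scaleb(shift - n + 1)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RunManifest:
    """Fully resolved inputs and outputs of one simulation run."""

    spec: DomainSpec
    props: FluidProperties
    inlet: InletSpec
    cfg: SolverConfig
    sealed: bool
    version: str
    timestamp: str
    outputs: tuple[str, ...] = ()

    @classmethod
    def create(
        cls,
        spec: DomainSpec,
        props: FluidProperties,
        inlet: InletSpec,
        cfg: SolverConfig,
        sealed: bool = False,
        outputs: tuple[str, ...] = (),
    ) -> "RunManifest":
        return cls(
            spec=spec,
            props=props,
            inlet=inlet,
            cfg=cfg,
            sealed=sealed,
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
            outputs=outputs,
        )

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "timestamp": self.timestamp,
            "sealed": self.sealed,
            "domain": dataclasses.asdict(self.spec),
            "fluid": dataclasses.asdict(self.props),
            "inlet": dataclasses.asdict(self.inlet),
            "solver": dataclasses.asdict(self.cfg),
            "outputs": list(self.outputs),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def field_to_dataframe(field: FlowField, mask: GridMask) -> pd.DataFrame:
    """Long-format (i, j, x_m, y_m, u, v, p) table of the whole grid."""
    jj, ii = np.mgrid[0 : mask.ny, 0 : mask.nx]
    return pd.DataFrame(
        {
            "i": ii.ravel(),
            "j": jj.ravel(),
            "x_m": ii.ravel() * mask.dx_m,
            "y_m": jj.ravel() * mask.dx_m,
            "u": field.u.ravel(),
            "v": field.v.ravel(),
            "p": field.p.ravel(),
        }
    )


def write_field_csv(field: FlowField, mask: GridMask, path: str | Path) -> None:
    field_to_dataframe(field, mask).to_csv(path, index=False)


def write_vtk(field: FlowField, mask: GridMask, path: str | Path) -> None:
    """Legacy ASCII VTK STRUCTURED_POINTS with pressure and velocity arrays."""
    ny, nx = field.p.shape
    dx = mask.dx_m
    lines = [
        "# vtk DataFile Version 3.0",
        "poreflow counter-current membrane channel flow",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        "ORIGIN 0 0 0",
        f"SPACING {dx:.9e} {dx:.9e} {dx:.9e}",
        f"POINT_DATA {nx * ny}",
        "SCALARS pressure double 1",
        "LOOKUP_TABLE default",
    ]
    lines.extend(f"{val:.9e}" for val in field.p.ravel())
    lines.append("VECTORS velocity double")
    zeros = np.zeros_like(field.u)
    for uu, vv, ww in zip(field.u.ravel(), field.v.ravel(), zeros.ravel()):
        lines.append(f"{uu:.9e} {vv:.9e} {ww:.9e}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_tecplot(field: FlowField, mask: GridMask, path: str | Path) -> None:
    """Tecplot-style ASCII POINT zone with X, Y, U, V, P variables."""
    ny, nx = field.p.shape
    dx = mask.dx_m
    lines = [
        'TITLE = "poreflow counter-current membrane channel flow"',
        'VARIABLES = "X","Y","U","V","P"',
        f"ZONE I={nx}, J={ny}, F=POINT",
    ]
    for j in range(ny):
        y = j * dx
        for i in range(nx):
            lines.append(
                f"{i * dx:.9e} {y:.9e} {field.u[j, i]:.9e} {field.v[j, i]:.9e} {field.p[j, i]:.9e}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_residuals_csv(report: SolverReport, path: str | Path) -> None:
    hist = np.atleast_2d(report.residual_history)
    df = pd.DataFrame(
        {
            "iteration": np.arange(1, len(hist) + 1),
            "momentum_residual": hist[:, 0],
            "divergence_residual": hist[:, 1],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fixture registry: small, fast configurations used by the test suite


@dataclass(frozen=True)
class Fixture:
    """A named, ready-to-run test configuration."""

    name: str
    spec: DomainSpec
    cfg: SolverConfig
    sealed: bool = False


_FIXTURES = {
    # single pore on a coarse grid: fastest full physics
    "tiny-1pore": lambda: Fixture(
        name="tiny-1pore",
        spec=DomainSpec(n_pores=1, dx_um=0.5),
        cfg=SolverConfig(),
    ),
    # five pores, sealed: Poiseuille recovery check
    "sealed-poiseuille": lambda: Fixture(
        name="sealed-poiseuille",
        spec=DomainSpec(n_pores=5, dx_um=0.5),
        cfg=SolverConfig(),
        sealed=True,
    ),
    # two pores: smallest case with an interior wall segment
    "symmetric-2pore": lambda: Fixture(
        name="symmetric-2pore",
        spec=DomainSpec(n_pores=2, dx_um=0.5),
        cfg=SolverConfig(),
    ),
    # the full-resolution 60-pore configuration of the reference study
    "paper-60pore": lambda: Fixture(
        name="paper-60pore",
        spec=DomainSpec(n_pores=60, dx_um=0.25),
        cfg=SolverConfig(),
    ),
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def make_fixture(name: str) -> Fixture:
    """Look up a named coarse/fast configuration from the registry."""
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return factory()
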