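"""Headline metrics and profiles extracted from a converged flow field.

The reported quantities mirror the quantities used to characterise
counter-current membrane-channel runs: the maximum inlet pressure of the
feed (lower) channel, the horizontal velocity at mid-length and
channel mid-height, the peak vertical velocity near the inlet at
mid-height, the transmembrane pressure, and their non-dimensional ratios
against the sealed-channel Poiseuille references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analytical import poiseuille_inlet_pressure
from .geometry import DomainSpec, GridMask
from .solver import FlowField, FluidProperties, InletSpec

__all__ = [
    "SummaryMetrics",
    "ProfileSet",
    "extract_summary",
    "extract_profiles",
    "nondimensionalize",
]


@dataclass(frozen=True)
class SummaryMetrics:
    """Headline scalar metrics of one counter-current run (SI units).

    ``tmp`` (transmembrane pressure) equals ``p_inlet_max`` because the
    outlet pressure is pinned to zero.  ``v_inlet_max`` is signed: positive
    means upward flow (feed channel into the membrane) near the feed inlet.
    """

    p_inlet_max: float
    u_mid: float
    v_inlet_max: float
    tmp: float
    u_ratio: float
    p_ratio: float
    p_analytical: float
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class ProfileSet:
    """Centreline and membrane-pore profiles of one run.

    Centreline arrays run along x at the mid-height of each channel; pore
    profiles are sampled at the pore-centre x stations on the membrane's
    lower interface, mid-height, and upper interface rows.
    """

    x_um: np.ndarray
    u_lower: np.ndarray
    v_lower: np.ndarray
    p_lower: np.ndarray
    u_upper: np.ndarray
    v_upper: np.ndarray
    p_upper: np.ndarray
    pore_x_um: np.ndarray
    pore_heights_um: np.ndarray
    pore_u: np.ndarray  # shape (3, n_pores)
    pore_v: np.ndarray
    pore_p: np.ndarray
    off_grid: bool = False


def _mid_row_lower(mask: GridMask) -> int:
    return mask.spec.h_lower_steps // 2


def _mid_row_upper(mask: GridMask) -> int:
    return mask.j_interface_top + mask.spec.h_upper_steps // 2


def extract_summary(
    field: FlowField,
    mask: GridMask,
    spec: DomainSpec,
    inlet: InletSpec,
    props: FluidProperties,
    converged: bool = True,
) -> SummaryMetrics:
    """Compute the headline metrics of a converged counter-current field.

    ``u_mid`` is sampled at the grid column nearest x = L/2 and the row
    nearest the lower-channel mid-height; ``v_inlet_max`` is the
    largest-magnitude vertical velocity (signed) over the first pore pitch
    of the feed channel at mid-height.  A non-converged field yields a
    warning attached to the result, not an error.
    """
    jm = _mid_row_lower(mask)
    jb = mask.j_interface_bottom
    ic = spec.length_steps // 2

    p_inlet_max = float(np.max(field.p[1:jb, 0]))
    u_mid = float(field.u[jm, ic])
    seg = field.v[jm, : spec.pitch_steps + 1]
    v_inlet_max = float(seg[int(np.argmax(np.abs(seg)))])

    p_analytical = poiseuille_inlet_pressure(
        props.mu, inlet.u_mean, spec.length_m, spec.channel_height_lower_m
    )
    warnings: tuple[str, ...] = ()
    if not converged:
        warnings = ("solver did not report convergence; metrics may be inaccurate",)
    return SummaryMetrics(
        p_inlet_max=p_inlet_max,
        u_mid=u_mid,
        v_inlet_max=v_inlet_max,
        tmp=p_inlet_max,
        u_ratio=abs(u_mid) / inlet.u_max,
        p_ratio=p_inlet_max / p_analytical if p_analytical > 0 else np.nan,
        p_analytical=p_analytical,
        warnings=warnings,
    )


def extract_profiles(field: FlowField, mask: GridMask, spec: DomainSpec) -> ProfileSet:
    """Centreline profiles along both channels plus per-pore samples.

    Pore stations are the pore-centre x positions at the lower interface,
    membrane mid-height and upper interface rows; positions that do not
    coincide with grid nodes are snapped to the nearest node and flagged.
    """
    jm_lo = _mid_row_lower(mask)
    jm_up = _mid_row_upper(mask)
    jb, jt = mask.j_interface_bottom, mask.j_interface_top

    x_um = mask.x_um()
    centers = spec.pore_center_positions_um()
    ci = np.round(centers / spec.dx_um).astype(int)
    off_grid = bool(np.max(np.abs(ci * spec.dx_um - centers)) > 1e-9)

    jmid = (jb + jt) // 2
    rows = np.array([jb, jmid, jt])
    heights = rows * spec.dx_um
    off_grid = off_grid or abs((jb + jt) / 2 - jmid) > 0

    return ProfileSet(
        x_um=x_um,
        u_lower=field.u[jm_lo, :].copy(),
        v_lower=field.v[jm_lo, :].copy(),
        p_lower=field.p[jm_lo, :].copy(),
        u_upper=field.u[jm_up, :].copy(),
        v_upper=field.v[jm_up, :].copy(),
        p_upper=field.p[jm_up, :].copy(),
        pore_x_um=centers,
        pore_heights_um=heights,
        pore_u=field.u[np.ix_(rows, ci)].copy(),
        pore_v=field.v[np.ix_(rows, ci)].copy(),
        pore_p=field.p[np.ix_(rows, ci)].copy(),
        off_grid=off_grid,
    )


def nondimensionalize(
    metrics: SummaryMetrics,
    spec: DomainSpec,
    props: FluidProperties,
    inlet: InletSpec,
) -> pd.Series:
    """One summary-table row in the layout used for the length sweep.

    Columns: channel length, pore count, peak inlet vertical velocity,
    mid-length horizontal velocity, its ratio to the inlet maximum, the
    simulated and analytical (Poiseuille) inlet pressures and their ratio.
    """
    return pd.Series(
        {
            "L_um": spec.length_um,
            "n_pores": spec.n_pores,
            "v_inlet_m_s": metrics.v_inlet_max,
            "u_mid_m_s": metrics.u_mid,
            "u_mid_over_u_max": metrics.u_ratio,
            "p_cfd_pa": metrics.p_inlet_max,
            "p_analytical_pa": metrics.p_analytical,
            "p_cfd_over_p_analytical": metrics.p_ratio,
        }
    )
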