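"""Closed-form hydraulic references for the membrane-channel geometry.

Plane Poiseuille pressure drop, 2D-channel Darcy permeability, membrane
open-area fraction, and a lumped 1D counter-current model of two channels
exchanging flow through a permeable wall (lubrication pressure gradient in
each channel, Darcy-type leakage proportional to the local transmembrane
pressure).  All functions take SI inputs unless the name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_bvp

from .geometry import DomainSpec, UM

__all__ = [
    "poiseuille_inlet_pressure",
    "permeability_2d",
    "open_area_fraction",
    "hydraulic_permeability_estimate",
    "OneDModelSpec",
    "OneDSolution",
    "oned_countercurrent",
]


def poiseuille_inlet_pressure(mu: float, u_mean: float, length: float, height: float) -> float:
    """Inlet pressure of fully developed plane Poiseuille flow, Pa.

    P = 12 * mu * u_mean * L / h**2 for a channel of height ``height`` and
    length ``length`` with zero outlet pressure.

    Parameters are SI: Pa*s, m/s, m, m.
    """
    if height <= 0:
        raise ValueError(f"channel height must be positive, got {height}")
    if mu < 0 or u_mean < 0 or length < 0:
        raise ValueError("mu, u_mean and length must be non-negative")
    return 12.0 * mu * u_mean * length / height**2


def permeability_2d(height: float) -> float:
    """Darcy permeability of a plane 2D channel, K = h**2 / 12 (m^2)."""
    if height < 0:
        raise ValueError(f"height must be non-negative, got {height}")
    return height**2 / 12.0


def open_area_fraction(spec: DomainSpec, squared: bool = False) -> float:
    """Open-area fraction of the membrane perforation.

    The linear (1D) fraction is ``n * pore_width / L`` with
    ``L = n * (pore_width + wall_width) + wall_width``; it tends to
    ``pore_width / (pore_width + wall_width)`` as the pore count grows.
    With ``squared=True`` the square of that fraction is returned, the
    areal (2D) reading of the same layout.
    """
    phi = spec.n_pores * spec.pore_width_um / spec.length_um
    return phi**2 if squared else phi


def hydraulic_permeability_estimate(spec: DomainSpec, mu: float) -> float:
    """Rough lumped hydraulic permeability of the perforated membrane, m/(Pa*s).

    Estimate only: treats each pore as a plane channel of width
    ``pore_width`` and length ``membrane_height`` (K_pore = w_p**2 / 12) and
    scales by the open-area fraction:

        Lp_est = K_pore / (mu * h_m) * phi

    Measured or fitted values should be preferred when available.
    """
    k_pore = permeability_2d(spec.pore_width_um * UM)
    return k_pore / (mu * spec.membrane_height_m) * open_area_fraction(spec)


@dataclass(frozen=True)
class OneDModelSpec:
    """Inputs of the lumped 1D counter-current permeable-wall model (SI).

    Channel 1 flows in +x with inlet at x = 0 and outlet (p = 0) at x = L;
    channel 2 flows in -x with inlet at x = L and outlet (p = 0) at x = 0.
    ``Lp`` is the wall hydraulic permeability; ``Lp = 0`` is the sealed
    (pure Poiseuille) limit.
    """

    Lp: float
    h1: float
    h2: float
    L: float
    mu: float
    u_mean_1: float = 1.0
    u_mean_2: float = 1.0

    def __post_init__(self) -> None:
        if min(self.h1, self.h2, self.L, self.mu) <= 0:
            raise ValueError("h1, h2, L and mu must be positive")
        if self.Lp < 0:
            raise ValueError("Lp must be non-negative")


@dataclass(frozen=True)
class OneDSolution:
    """Per-x solution arrays of the 1D model (SI units).

    ``u2`` is signed: negative values mean flow in -x.  ``v_wall`` is the
    wall (transmembrane) velocity, positive from channel 1 into channel 2.
    """

    x: np.ndarray
    u1: np.ndarray
    p1: np.ndarray
    u2: np.ndarray
    p2: np.ndarray
    v_wall: np.ndarray


def oned_countercurrent(spec: OneDModelSpec, n_x: int = 201) -> OneDSolution:
    """Solve the lumped 1D counter-current permeable-wall model.

    Per unit width, with q_k the signed volumetric flux of channel k:

        dp_k/dx = -12 mu q_k / h_k**3          (lubrication)
        dq_1/dx = -v_w,   dq_2/dx = +v_w       (continuity)
        v_w     = Lp * (p_1 - p_2)             (Darcy leakage)

    Boundary conditions: q_1(0) = u_mean_1 * h1, q_2(L) = -u_mean_2 * h2,
    p_1(L) = 0, p_2(0) = 0.  The system is linear; it is solved as a
    two-point boundary-value problem and evaluated on ``n_x`` uniform
    stations.
    """
    if n_x < 3:
        raise ValueError("n_x must be at least 3")

    mu, Lp = spec.mu, spec.Lp
    h1, h2, L = spec.h1, spec.h2, spec.L
    q1_in = spec.u_mean_1 * h1
    q2_in = -spec.u_mean_2 * h2

    def rhs(x, y):
        q1, q2, p1, p2 = y
        vw = Lp * (p1 - p2)
        return np.vstack(
            [
                -vw,
                +vw,
                -12.0 * mu * q1 / h1**3,
                -12.0 * mu * q2 / h2**3,
            ]
        )

    def bc(ya, yb):
        return np.array([ya[0] - q1_in, yb[1] - q2_in, yb[2], ya[3]])

    x0 = np.linspace(0.0, L, n_x)
    # linear initial guess: sealed-limit fluxes and pressure ramps
    y0 = np.vstack(
        [
            np.full(n_x, q1_in),
            np.full(n_x, q2_in),
            12.0 * mu * (q1_in / h1**3) * (L - x0),
            12.0 * mu * (-q2_in / h2**3) * x0,
        ]
    )
    sol = solve_bvp(rhs, bc, x0, y0, tol=1e-10, max_nodes=200_000)
    if not sol.success:
        raise RuntimeError(f"1D counter-current BVP failed to converge: {sol.message}")

    y = sol.sol(x0)
    q1, q2, p1, p2 = y
    return OneDSolution(
        x=x0,
        u1=q1 / h1,
        p1=p1,
        u2=q2 / h2,
        p2=p2,
        v_wall=Lp * (p1 - p2),
    )
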