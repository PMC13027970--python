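"""Parametric counter-current membrane-channel geometry on a uniform grid.

The domain is two parallel rectangular microchannels separated by a
perforated membrane band.  The lower channel carries flow in +x, the upper
channel in -x (counter-current).  The membrane is a horizontal band of
solid wall segments interrupted by rectangular pore openings (vertical
channels) that connect the two flow channels.

All user-facing lengths are micrometres; conversion to metres happens at
the solver interface via the ``*_m`` properties.  The grid is uniform and
square (spacing ``dx`` in both directions), node-centred, with node (0, 0)
at the bottom-left corner of the lower channel wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
import pandas as pd

UM = 1e-6  # metres per micrometre

__all__ = [
    "UM",
    "NodeClass",
    "InvalidSpecError",
    "DomainSpec",
    "GridMask",
    "domain_length",
    "build_mask",
    "seal_membrane",
    "mask_to_ascii",
    "mask_to_dataframe",
]


class InvalidSpecError(ValueError):
    """Raised when a geometry specification is inconsistent or off-grid."""


class NodeClass(IntEnum):
    """Role of a grid node in the masked domain."""

    FLUID = 0
    SOLID = 1
    WALL = 2
    INLET_LOWER = 3
    INLET_UPPER = 4
    OUTLET_LOWER = 5
    OUTLET_UPPER = 6


_ASCII_CHAR = {
    NodeClass.FLUID: "F",
    NodeClass.SOLID: "S",
    NodeClass.WALL: "W",
    NodeClass.INLET_LOWER: "I",
    NodeClass.INLET_UPPER: "I",
    NodeClass.OUTLET_LOWER: "O",
    NodeClass.OUTLET_UPPER: "O",
}


def _steps(value_um: float, dx_um: float, name: str) -> int:
    """Length expressed as a whole number of grid steps, or raise."""
    k = round(value_um / dx_um)
    if k <= 0 or abs(k * dx_um - value_um) > 1e-9 * max(1.0, abs(value_um)):
        raise InvalidSpecError(
            f"{name} = {value_um} um is not a positive multiple of dx = {dx_um} um"
        )
    return k


@dataclass(frozen=True)
class DomainSpec:
    """Geometry of the two channels, membrane perforation and grid.

    Parameters
    ----------
    n_pores
        Number of pore openings in the membrane; the channel length is
        ``n_pores * (pore_width + wall_width) + wall_width`` so the membrane
        starts and ends with a wall segment.
    pore_width_um, wall_width_um
        Width of one pore opening and of one wall segment (micrometres).
    channel_height_lower_um, channel_height_upper_um, membrane_height_um
        Heights of the three horizontal bands (micrometres).
    dx_um
        Uniform square grid spacing (micrometres).  Every stated length must
        be a whole number of grid steps.
    """

    n_pores: int = 60
    pore_width_um: float = 4.0
    wall_width_um: float = 1.0
    channel_height_lower_um: float = 15.0
    channel_height_upper_um: float = 15.0
    membrane_height_um: float = 15.0
    dx_um: float = 0.25

    def __post_init__(self) -> None:
        if not isinstance(self.n_pores, (int, np.integer)) or self.n_pores < 1:
            raise InvalidSpecError(f"n_pores must be a positive integer, got {self.n_pores!r}")
        if self.dx_um <= 0:
            raise InvalidSpecError(f"dx must be positive, got {self.dx_um}")
        # materialise the step counts now so bad specs fail at construction
        self.pore_steps
        self.wall_steps
        self.h_lower_steps
        self.h_upper_steps
        self.h_membrane_steps

    # --- grid-step bookkeeping -------------------------------------------
    @property
    def pore_steps(self) -> int:
        return _steps(self.pore_width_um, self.dx_um, "pore_width")

    @property
    def wall_steps(self) -> int:
        return _steps(self.wall_width_um, self.dx_um, "wall_width")

    @property
    def pitch_steps(self) -> int:
        return self.pore_steps + self.wall_steps

    @property
    def h_lower_steps(self) -> int:
        return _steps(self.channel_height_lower_um, self.dx_um, "channel_height_lower")

    @property
    def h_upper_steps(self) -> int:
        return _steps(self.channel_height_upper_um, self.dx_um, "channel_height_upper")

    @property
    def h_membrane_steps(self) -> int:
        return _steps(self.membrane_height_um, self.dx_um, "membrane_height")

    @property
    def length_steps(self) -> int:
        return self.n_pores * self.pitch_steps + self.wall_steps

    @property
    def height_steps(self) -> int:
        return self.h_lower_steps + self.h_membrane_steps + self.h_upper_steps

    # --- derived physical dimensions -------------------------------------
    @property
    def length_um(self) -> float:
        return self.length_steps * self.dx_um

    @property
    def height_um(self) -> float:
        return self.height_steps * self.dx_um

    @property
    def nx(self) -> int:
        return self.length_steps + 1

    @property
    def ny(self) -> int:
        return self.height_steps + 1

    @property
    def dx_m(self) -> float:
        return self.dx_um * UM

    @property
    def length_m(self) -> float:
        return self.length_um * UM

    @property
    def channel_height_lower_m(self) -> float:
        return self.channel_height_lower_um * UM

    @property
    def channel_height_upper_m(self) -> float:
        return self.channel_height_upper_um * UM

    @property
    def membrane_height_m(self) -> float:
        return self.membrane_height_um * UM

    def pore_center_positions_um(self) -> np.ndarray:
        """x positions of pore centres, in micrometres."""
        pitch = self.pore_width_um + self.wall_width_um
        return self.wall_width_um + self.pore_width_um / 2.0 + pitch * np.arange(self.n_pores)


def domain_length(spec: DomainSpec) -> float:
    """Total channel/membrane length L in micrometres.

    L = n_pores * (pore_width + wall_width) + wall_width, so that the
    membrane begins and ends with a wall segment.
    """
    return spec.length_um


@dataclass(frozen=True)
class GridMask:
    """Node-level fluid/solid classification on the uniform grid.

    ``node_class`` has shape ``(ny, nx)`` with row index j (y, bottom-up)
    and column index i (x, left-to-right); values are :class:`NodeClass`.
    """

    spec: DomainSpec
    node_class: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.node_class.shape != (self.spec.ny, self.spec.nx):
            raise InvalidSpecError("node_class shape does not match spec grid")

    @property
    def nx(self) -> int:
        return self.spec.nx

    @property
    def ny(self) -> int:
        return self.spec.ny

    @property
    def dx_m(self) -> float:
        return self.spec.dx_m

    def x_um(self) -> np.ndarray:
        return np.arange(self.nx) * self.spec.dx_um

    def y_um(self) -> np.ndarray:
        return np.arange(self.ny) * self.spec.dx_um

    # --- convenience boolean views ---------------------------------------
    @property
    def is_solid(self) -> np.ndarray:
        return (self.node_class == NodeClass.SOLID) | (self.node_class == NodeClass.WALL)

    @property
    def is_fluid(self) -> np.ndarray:
        """Strictly interior fluid nodes (excludes inlet/outlet columns)."""
        return self.node_class == NodeClass.FLUID

    @property
    def carries_flow(self) -> np.ndarray:
        """All nodes where velocity may be nonzero (fluid + open boundaries)."""
        return ~self.is_solid

    # --- row bookkeeping used by solver and postprocessing ---------------
    @property
    def j_interface_bottom(self) -> int:
        """Row index of the lower channel/membrane interface (y = h_lower)."""
        return self.spec.h_lower_steps

    @property
    def j_interface_top(self) -> int:
        """Row index of the membrane/upper channel interface."""
        return self.spec.h_lower_steps + self.spec.h_membrane_steps

    def lower_channel_rows(self) -> slice:
        """Open-interval rows of the lower channel (excludes walls/interface)."""
        return slice(1, self.j_interface_bottom)

    def upper_channel_rows(self) -> slice:
        return slice(self.j_interface_top + 1, self.ny - 1)

    def pore_fluid_count(self) -> int:
        band = self.node_class[self.j_interface_bottom : self.j_interface_top + 1]
        return int(np.count_nonzero(band == NodeClass.FLUID))


def build_mask(spec: DomainSpec) -> GridMask:
    """Classify every grid node of the counter-current domain.

    Wall segments of the membrane occupy closed intervals
    ``[k*pitch, k*pitch + wall_width]`` (k = 0..n_pores) in x; a node lying
    exactly on a pore/wall boundary is solid, so each pore opening is
    ``pore_width`` of strictly-interior fluid.  The channel/membrane
    interface rows follow the same rule, making each pore a true vertical
    channel connecting the two horizontal channels.
    """
    nx, ny = spec.nx, spec.ny
    cls = np.full((ny, nx), NodeClass.FLUID, dtype=np.uint8)

    jb = spec.h_lower_steps
    jt = jb + spec.h_membrane_steps

    # membrane band: solid over wall segments, fluid strictly inside pores
    i = np.arange(nx)
    phase = i % spec.pitch_steps
    in_wall = phase <= spec.wall_steps
    # the trailing wall segment [n*pitch, n*pitch + wall] is covered by
    # phase <= wall for i <= length_steps since length = n*pitch + wall
    cls[jb : jt + 1, in_wall] = NodeClass.SOLID

    # top and bottom domain boundaries are solid walls
    cls[0, :] = NodeClass.WALL
    cls[-1, :] = NodeClass.WALL

    # open boundary columns: lower channel flows +x, upper channel flows -x
    lo = slice(1, jb)
    up = slice(jt + 1, ny - 1)
    cls[lo, 0] = NodeClass.INLET_LOWER
    cls[lo, nx - 1] = NodeClass.OUTLET_LOWER
    cls[up, nx - 1] = NodeClass.INLET_UPPER
    cls[up, 0] = NodeClass.OUTLET_UPPER

    return GridMask(spec=spec, node_class=cls)


def seal_membrane(mask: GridMask) -> GridMask:
    """Return a copy with every membrane-band node solid.

    The two channels become independent solid-wall ducts; used for the
    Poiseuille-limit validation of the analytical inlet-pressure formula.
    """
    cls = mask.node_class.copy()
    cls[mask.j_interface_bottom : mask.j_interface_top + 1, :] = NodeClass.SOLID
    return GridMask(spec=mask.spec, node_class=cls)


def mask_to_ascii(mask: GridMask) -> str:
    """One character per node (F/S/I/O/W), top row first (y decreasing)."""
    lut = np.array([_ASCII_CHAR[NodeClass(k)] for k in range(7)])
    chars = lut[mask.node_class]
    return "\n".join("".join(row) for row in chars[::-1])


def mask_to_dataframe(mask: GridMask) -> pd.DataFrame:
    """Long-format node table (i, j, x_um, y_um, node_class) for debugging."""
    jj, ii = np.mgrid[0 : mask.ny, 0 : mask.nx]
    return pd.DataFrame(
        {
            "i": ii.ravel(),
            "j": jj.ravel(),
            "x_um": ii.ravel() * mask.spec.dx_um,
            "y_um": jj.ravel() * mask.spec.dx_um,
            "node_class": [NodeClass(v).name for v in mask.node_class.ravel()],
        }
    )
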