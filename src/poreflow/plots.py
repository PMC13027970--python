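"""Optional matplotlib views of profiles and model comparisons."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analytical import OneDSolution
from .postprocess import ProfileSet

__all__ = ["plot_centerline_profiles", "plot_model_comparison"]


def plot_centerline_profiles(prof: ProfileSet, path: str | Path) -> None:
    """Three-panel u / v / p centreline figure for both channels."""
    fig, axes = plt.subplots(3, 1, figsize=(8, 9), sharex=True)
    for ax, lower, upper, label in (
        (axes[0], prof.u_lower, prof.u_upper, "u (m/s)"),
        (axes[1], prof.v_lower, prof.v_upper, "v (m/s)"),
        (axes[2], prof.p_lower, prof.p_upper, "p (Pa)"),
    ):
        ax.plot(prof.x_um, lower, label="lower channel (feed)")
        ax.plot(prof.x_um, upper, "--", label="upper channel (counter-flow)")
        ax.set_ylabel(label)
        ax.axvline(prof.x_um[-1] / 2, color="0.8", lw=0.8)
    axes[0].legend(loc="best", fontsize=8)
    axes[2].set_xlabel("x (um)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_model_comparison(
    lengths_um: np.ndarray,
    p_cfd: np.ndarray,
    p_poiseuille: np.ndarray,
    path: str | Path,
    p_oned: np.ndarray | None = None,
) -> None:
    """Inlet pressure vs channel length: pore-resolved, 1D model, Poiseuille."""
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.plot(lengths_um, p_cfd, "o-", label="pore-resolved 2D")
    if p_oned is not None:
        ax.plot(lengths_um, p_oned, "s--", label="lumped 1D permeable wall")
    ax.plot(lengths_um, p_poiseuille, "k:", label="Poiseuille (sealed)")
    ax.set_xlabel("channel length (um)")
    ax.set_ylabel("inlet pressure (Pa)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_oned_solution(sol: OneDSolution, path: str | Path) -> None:
    """Mean velocities, pressures and wall velocity of the 1D model."""
    fig, axes = plt.subplots(3, 1, figsize=(8, 9), sharex=True)
    x_um = sol.x * 1e6
    axes[0].plot(x_um, sol.u1, label="u1 (feed)")
    axes[0].plot(x_um, sol.u2, "--", label="u2 (counter)")
    axes[0].set_ylabel("mean u (m/s)")
    axes[0].legend(fontsize=8)
    axes[1].plot(x_um, sol.p1, label="p1")
    axes[1].plot(x_um, sol.p2, "--", label="p2")
    axes[1].set_ylabel("p (Pa)")
    axes[1].legend(fontsize=8)
    axes[2].plot(x_um, sol.v_wall)
    axes[2].set_ylabel("wall velocity (m/s)")
    axes[2].set_xlabel("x (um)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
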