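"""Run orchestration: geometry -> solve -> postprocess -> export.

``run_simulation`` executes one fully configured case and writes its
manifest, summary, fields and residual history; ``run_sweep`` repeats it
over a list of pore counts and aggregates the summary rows into one table
ordered by channel length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .geometry import DomainSpec, build_mask, seal_membrane
from .io import (
    RunManifest,
    write_field_csv,
    write_residuals_csv,
    write_tecplot,
    write_vtk,
)
from .postprocess import SummaryMetrics, extract_summary, nondimensionalize
from .solver import (
    FlowField,
    FluidProperties,
    InletSpec,
    SolverConfig,
    SolverReport,
    solve_steady,
)

__all__ = ["RunResult", "run_simulation", "run_sweep"]

logger = logging.getLogger("poreflow")


@dataclass
class RunResult:
    """Everything produced by one simulation run."""

    spec: DomainSpec
    field: FlowField
    report: SolverReport
    summary: SummaryMetrics
    table_row: pd.Series
    manifest: RunManifest
    out_dir: Path | None = None


def run_simulation(
    spec: DomainSpec,
    props: FluidProperties | None = None,
    inlet: InletSpec | None = None,
    cfg: SolverConfig | None = None,
    sealed: bool = False,
    out_dir: str | Path | None = None,
    export: tuple[str, ...] = ("csv",),
) -> RunResult:
    """Execute one case end to end and optionally export its artefacts.

    With ``sealed=True`` the membrane band is closed so both channels are
    plain ducts (Poiseuille validation mode).  Exports are selected from
    {"csv", "vtk", "tecplot"}; a manifest, summary row and residual
    history are always written when ``out_dir`` is given.
    """
    props = props or FluidProperties()
    inlet = inlet or InletSpec()
    cfg = cfg or SolverConfig()

    mask = build_mask(spec)
    if sealed:
        mask = seal_membrane(mask)

    logger.info(
        "solving %d-pore domain (L = %.6g um, %d x %d nodes, sealed=%s)",
        spec.n_pores, spec.length_um, spec.nx, spec.ny, sealed,
    )
    field, report = solve_steady(spec, props, inlet, cfg, mask=mask, log=logger.info)
    if not report.converged:
        logger.warning(
            "solver did not converge in %d iterations (residual %.3e)",
            report.iterations, report.final_residual,
        )

    summary = extract_summary(field, mask, spec, inlet, props, converged=report.converged)
    row = nondimensionalize(summary, spec, props, inlet)

    outputs: list[str] = []
    out_path: Path | None = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        if "csv" in export:
            write_field_csv(field, mask, out_path / "field.csv")
            outputs.append("field.csv")
        if "vtk" in export:
            write_vtk(field, mask, out_path / "field.vtk")
            outputs.append("field.vtk")
        if "tecplot" in export:
            write_tecplot(field, mask, out_path / "field.dat")
            outputs.append("field.dat")
        row.to_frame().T.to_csv(out_path / "summary.csv", index=False)
        outputs.append("summary.csv")
        write_residuals_csv(report, out_path / "residuals.csv")
        outputs.append("residuals.csv")

    manifest = RunManifest.create(spec, props, inlet, cfg, sealed=sealed, outputs=tuple(outputs))
    if out_path is not None:
        manifest.write(out_path / "manifest.json")

    return RunResult(
        spec=spec,
        field=field,
        report=report,
        summary=summary,
        table_row=row,
        manifest=manifest,
        out_dir=out_path,
    )


def run_sweep(
    pore_counts: list[int],
    base_spec: DomainSpec | None = None,
    props: FluidProperties | None = None,
    inlet: InletSpec | None = None,
    cfg: SolverConfig | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run several pore counts and aggregate their summary rows.

    Rows are ordered by channel length; a case that fails is recorded in
    its row (``error`` column) and the sweep continues.
    """
    if not pore_counts:
        raise ValueError("pore_counts must be a non-empty list")
    base = base_spec or DomainSpec()

    rows = []
    for n in sorted(set(pore_counts)):
        spec = DomainSpec(
            n_pores=n,
            pore_width_um=base.pore_width_um,
            wall_width_um=base.wall_width_um,
            channel_height_lower_um=base.channel_height_lower_um,
            channel_height_upper_um=base.channel_height_upper_um,
            membrane_height_um=base.membrane_height_um,
            dx_um=base.dx_um,
        )
        sub_dir = None if out_dir is None else Path(out_dir) / f"n{n:03d}"
        try:
            result = run_simulation(spec, props, inlet, cfg, out_dir=sub_dir)
            row = result.table_row
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - recorded per row, sweep continues
            logger.error("case n_pores=%d failed: %s", n, exc)
            row = pd.Series({"L_um": spec.length_um, "n_pores": n, "error": str(exc)})
        rows.append(row)

    table = pd.DataFrame(rows).sort_values("L_um").reset_index(drop=True)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(out_dir) / "sweep.csv", index=False)
    return table
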