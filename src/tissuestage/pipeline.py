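"""End-to-end pipeline: geometry -> transport -> dissipation -> free energy -> staging.

``run_pipeline`` sweeps the dissipated energy over the configured stiffness
grid (one transport solve per grid point, porosity slaved to phi(Y)),
builds the non-equilibrium free-energy landscape and configuration
probability, computes the progression current, segments stages and
evaluates transition and conditional stage probabilities.  Everything is
deterministic given the configuration; ``write_report`` emits the CSV and
JSON artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .dissipation import EnergyLandscape, build_energy_landscape
from .free_energy import FreeEnergyLandscape, total_free_energy
from .staging import (
    StageModel,
    TransitionResult,
    probability_current,
    segment_stages,
    stage_transitions,
)
from .transport import R_GAS

log = logging.getLogger("tissuestage")

__all__ = ["PipelineResult", "run_pipeline", "write_report"]


@dataclass
class PipelineResult:
    config: RunConfig
    landscape: EnergyLandscape
    free_energy: FreeEnergyLandscape
    stages: StageModel
    transitions: TransitionResult

    # -- derived headline quantities -------------------------------------
    def log10_probability_ratio(self) -> float:
        """log10 rho(healthy anchor) / rho(carcinogenic anchor)."""
        st = self.config.staging
        beta = 1.0 / (R_GAS * self.config.tissue.T)
        dGh = self.free_energy.dG_at(st.Y_healthy)
        dGc = self.free_energy.dG_at(st.Y_cancer)
        return float(-beta * (dGh - dGc) / np.log(10.0))

    def energy_at(self, Y: float) -> float:
        return float(np.interp(Y, self.landscape.Y_grid, self.landscape.E_d_of_Y))

    def W_by_name(self) -> dict[str, float]:
        return dict(zip(self.transitions.transitions, self.transitions.W))

    def P_by_stage(self) -> dict[str, float]:
        return dict(zip(self.transitions.P_labels, self.transitions.P))

    def P_at(self, canonical_label: str) -> float:
        """Conditional probability of the stage carrying a canonical label."""
        idx = self.stages.stage_index(canonical_label)
        return float(self.transitions.P[idx])


def run_pipeline(config: RunConfig, progress: bool = False) -> PipelineResult:
    """Execute the full model chain for one configuration."""
    sw = config.sweep
    st = config.staging
    Y_grid = sw.grid_Y()
    log.info(
        "landscape sweep: %d stiffness points in [%.3g, %.3g] Pa",
        sw.n_Y, sw.Y_min, sw.Y_max,
    )
    land = build_energy_landscape(
        Y_grid,
        config.tissue,
        config.species,
        config.grid,
        n_periods=sw.n_periods,
        rel_smooth=sw.rel_smooth,
        progress=progress,
    )
    log.info("dissipation extremum Y* = %.4g Pa (boundary=%s)",
             land.Y_star, land.boundary_extremum)
    fel = total_free_energy(
        land,
        dG_r=st.dG_r,
        mode=st.mode,
        n_mol=st.n_mol,
        T=config.tissue.T,
    )
    J, dJ = probability_current(
        fel.rho, fel.dG, Y_grid, D_Y=st.D_Y, T=config.tissue.T, drift=st.drift
    )
    model = segment_stages(
        J, dJ, Y_grid,
        rho=fel.rho,
        prominence_rel=st.prominence_rel,
        stable_tol=st.stable_tol,
    )
    log.info("stages: %s at boundaries %s", model.labels,
             np.array2string(model.boundaries, precision=3))
    trans = stage_transitions(model, c_k=st.c_k)
    return PipelineResult(
        config=config,
        landscape=land,
        free_energy=fel,
        stages=model,
        transitions=trans,
    )


def write_report(result: PipelineResult, outdir: str | Path) -> dict:
    """Write landscape/free-energy/current CSVs and the stage JSON report.

    Returns the report dictionary that was written.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    land = result.landscape
    pd.DataFrame(
        {
            "Y": land.Y_grid,
            "phi": land.phi_of_Y,
            "E_d": land.E_d_of_Y,
            "E_d_raw": land.E_d_raw,
            "dEdY": land.dEdY,
            "d2EdY2": land.d2EdY2,
        }
    ).to_csv(out / "energy_landscape.csv", index=False)
    result.free_energy.to_dataframe().to_csv(out / "free_energy.csv", index=False)
    result.stages.to_dataframe().to_csv(out / "probability_current.csv", index=False)

    tr = result.transitions
    report = {
        "Y_star": result.landscape.Y_star,
        "boundary_extremum": result.landscape.boundary_extremum,
        "stage_boundaries_pa": [float(b) for b in result.stages.boundaries],
        "stage_labels": list(result.stages.labels),
        "stable_flags": list(result.stages.stable_flags),
        "merged": result.stages.merged,
        "transition_probabilities": {
            name: float(w) for name, w in zip(tr.transitions, tr.W)
        },
        "conditional_probabilities": {
            lab: float(p) for lab, p in zip(tr.P_labels, tr.P)
        },
        "log10_healthy_cancer_ratio": result.log10_probability_ratio(),
        "effective_parameters": result.config.to_dict(),
    }
    (out / "stage_report.json").write_text(json.dumps(report, indent=2))
    return report
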