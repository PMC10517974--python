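"""Calibrate the shipped paper-regime configuration.

Two constants of the configuration are not identifiable from first
principles and are fixed once, from a single uncalibrated landscape run:

* ``n_mol`` - the molar conversion of the per-element dissipated energy,
  chosen so the healthy/carcinogenic configuration-probability ratio is
  10^3 (the reported healthy-vs-cancer odds);
* ``c_k`` - the tanh gain constant, chosen so the smallest transition
  probability among the advanced-stage transitions (everything beyond the
  healthy exit, excluding the transition leaving the carcinogenic stage)
  is 0.9, i.e. the tanh arguments are order one.

The healthy anchor itself is fixed a priori at (phi = 0.0129,
Y = 5 kPa) - soft healthy pancreas on the shipped porosity trend.

Run from the repository root:

    python scripts/calibrate.py [--out src/tissuestage/data/paper_regime.yaml]

The script rewrites the shipped YAML in place by default and prints the
calibrated constants with the headline quantities of the recalibrated run.
"""

import argparse
from pathlib import Path

import numpy as np

from tissuestage.config import RunConfig, paper_regime
from tissuestage.dissipation import build_energy_landscape, porosity_from_young
from tissuestage.free_energy import configurational_free_energy, total_free_energy
from tissuestage.pipeline import run_pipeline
from tissuestage.staging import (
    probability_current,
    segment_stages,
    stage_transitions,
)
from tissuestage.transport import R_GAS

LOG10_RATIO_TARGET = 3.0  # healthy vs carcinogenic probability, decades
W_MIN_ADVANCED = 0.9  # smallest advanced-stage transition probability


def calibrate(cfg: RunConfig) -> RunConfig:
    Y_grid = cfg.sweep.grid_Y()
    land = build_energy_landscape(
        Y_grid,
        cfg.tissue,
        cfg.species,
        cfg.grid,
        n_periods=cfg.sweep.n_periods,
        rel_smooth=cfg.sweep.rel_smooth,
    )

    # 1. molar scale from the probability-ratio anchor (dG is linear in
    #    1/n_mol, so the ratio condition has a closed-form solution)
    beta = 1.0 / (R_GAS * cfg.tissue.T)
    G_raw = land.E_d_of_Y + configurational_free_energy(land, mode=cfg.staging.mode)
    G_h = float(np.interp(cfg.staging.Y_healthy, Y_grid, G_raw))
    G_c = float(np.interp(cfg.staging.Y_cancer, Y_grid, G_raw))
    if G_c <= G_h:
        raise RuntimeError("carcinogenic anchor not uphill of the healthy anchor")
    n_mol = beta * (G_c - G_h) / (LOG10_RATIO_TARGET * np.log(10.0))
    cfg.staging.n_mol = float(n_mol)

    # 2. gain constant: order-one tanh arguments for the advanced
    #    transitions (skip the healthy exit and the transition leaving the
    #    carcinogenic stage, whose currents the model does not constrain)
    fel = total_free_energy(
        land, dG_r=cfg.staging.dG_r, mode=cfg.staging.mode,
        n_mol=n_mol, T=cfg.tissue.T,
    )
    J, dJ = probability_current(
        fel.rho, fel.dG, Y_grid, D_Y=cfg.staging.D_Y,
        T=cfg.tissue.T, drift=cfg.staging.drift,
    )
    model = segment_stages(
        J, dJ, Y_grid, rho=fel.rho,
        prominence_rel=cfg.staging.prominence_rel,
        stable_tol=cfg.staging.stable_tol,
    )
    unit = stage_transitions(model, c_k=1.0)
    args = unit.k_i * unit.avg_J
    try:
        leaving_c = model.stage_index("C")
    except KeyError:
        leaving_c = None
    advanced = [
        a for i, a in enumerate(args)
        if i > 0 and i != leaving_c
    ]
    if not advanced or min(advanced) <= 0.0:
        raise RuntimeError("advanced-stage currents not all positive")
    cfg.staging.c_k = float(np.arctanh(2.0 * W_MIN_ADVANCED - 1.0) / min(advanced))
    return cfg


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument(
        "--out",
        default="src/tissuestage/data/paper_regime.yaml",
        help="where to write the calibrated configuration",
    )
    args = ap.parse_args()

    cfg = paper_regime()
    cfg = calibrate(cfg)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    cfg.save(args.out)
    print(f"calibrated configuration written to {args.out}")
    print(f"  Y_healthy = {cfg.staging.Y_healthy:.6g} Pa "
          f"(phi_h = {cfg.tissue.phi:.6g})")
    print(f"  n_mol     = {cfg.staging.n_mol:.6g} mol")
    print(f"  c_k       = {cfg.staging.c_k:.6g}")

    # verification pass with the calibrated constants
    res = run_pipeline(cfg)
    print("verification run:")
    print(f"  log10 rho(H)/rho(C) = {res.log10_probability_ratio():.4f}")
    print(f"  stages: {res.stages.labels} at "
          f"{np.array2string(res.stages.boundaries, precision=1)}")
    for name, w in res.W_by_name().items():
        print(f"  W[{name}] = {w:.4g}")
    for lab, p in res.P_by_stage().items():
        print(f"  P[{lab}] = {p:.4g}")


if __name__ == "__main__":
    main()
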