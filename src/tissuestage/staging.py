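"""Stage segmentation and transition probabilities in stiffness space.

Cancer progression is pictured as a drift-diffusion process over Young's
modulus.  Two drift conventions are provided:

* ``driven`` (default): progression is maintained by active internal
  processes (self-replication, remodelling) that climb the free-energy
  gradient toward the high-dissipation attractor,

      J(Y) = -D_Y (drho/dY - (rho/RT) d(dG)/dY);

  for the Boltzmann density this reduces to J = 2 D_Y beta rho dG', so the
  current is positive wherever the landscape rises - the fibrosis-to-cancer
  sweep - and changes sign at the dissipation maximum, the carcinogenic
  attractor.

* ``relaxational``: the passive Smoluchowski form

      J(Y) = -D_Y (drho/dY + (rho/RT) d(dG)/dY),

  which vanishes identically for the Boltzmann density (detailed balance);
  it serves as the equilibrium sanity check.

Stage boundaries sit at the extrema of dJ/dY; intervals are labelled in
ascending stiffness with the fixed sequence H, F0, F, T, C, T_C, RC
(healthy, early fibrous, fibrous, fibrous-to-carcinogenic transition,
carcinogenic, carcinogenic-to-rigid transition, rigid carcinogenic).
The transition probability between consecutive stages maps the current
integrated over both stages through a hyperbolic tangent,

    W_{i -> i+1} = (1/2) (1 + tanh(k_i <J>)),      <J> = int J dY,

with per-stage gain k_i = c_k / <|dJ/dY|> so the argument is scale-free in
the local current magnitude; conditional stage probabilities are the
telescoping products P_i = prod_{j<=i} W (with P_1 = 1 - W_{1->2}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .transport import R_GAS

STAGE_LABELS = ("H", "F0", "F", "T", "C", "T_C", "RC")

__all__ = [
    "STAGE_LABELS",
    "StageModel",
    "TransitionResult",
    "probability_current",
    "segment_stages",
    "average_current",
    "transition_probability",
    "stage_transitions",
    "conditional_probabilities",
]


@dataclass
class StageModel:
    """Probability current over stiffness and the stage segmentation."""

    Y_grid: np.ndarray
    J_of_Y: np.ndarray
    dJdY: np.ndarray
    D_Y: float
    boundaries: np.ndarray  # interior stage boundaries, ascending [Pa]
    labels: tuple[str, ...]  # one label per interval
    stable_flags: tuple[bool, ...]  # |dJ/dY| ~ 0 over the interval
    merged: bool = False  # fewer intervals detected than labels
    single_stage: bool = False  # no boundaries found at all

    def stage_edges(self) -> np.ndarray:
        """Full edge sequence: grid ends plus interior boundaries."""
        return np.concatenate(
            [[self.Y_grid[0]], self.boundaries, [self.Y_grid[-1]]]
        )

    def stage_index(self, label: str) -> int:
        """Index of the interval carrying ``label`` (possibly merged)."""
        for i, lab in enumerate(self.labels):
            if label == lab or label in lab.split("+"):
                return i
        raise KeyError(f"no stage carries label {label!r}")

    def stage_interval(self, label: str) -> tuple[float, float]:
        idx = self.stage_index(label)
        edges = self.stage_edges()
        return float(edges[idx]), float(edges[idx + 1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Y": self.Y_grid, "J": self.J_of_Y, "dJdY": self.dJdY}
        )


@dataclass
class TransitionResult:
    """Per-transition currents, gains, probabilities, and stage occupancies."""

    transitions: tuple[str, ...]  # "H->F0", ...
    avg_J: np.ndarray
    k_i: np.ndarray
    W: np.ndarray
    P_labels: tuple[str, ...]
    P: np.ndarray


def probability_current(
    rho: np.ndarray,
    dG: np.ndarray,
    Y_grid: np.ndarray,
    D_Y: float = 1.0,
    T: float = 310.0,
    drift: str = "driven",
) -> tuple[np.ndarray, np.ndarray]:
    """Probability current J(Y) and its derivative (central differences)."""
    rho = np.asarray(rho, dtype=float)
    dG = np.asarray(dG, dtype=float)
    Y_grid = np.asarray(Y_grid, dtype=float)
    if not (rho.shape == dG.shape == Y_grid.shape):
        raise ValueError("rho, dG and Y_grid must share one grid")
    beta = 1.0 / (R_GAS * T)
    drho = np.gradient(rho, Y_grid)
    ddG = np.gradient(dG, Y_grid)
    if drift == "driven":
        J = -D_Y * (drho - beta * rho * ddG)
    elif drift == "relaxational":
        J = -D_Y * (drho + beta * rho * ddG)
    else:
        raise ValueError(f"unknown drift convention {drift!r}")
    dJdY = np.gradient(J, Y_grid)
    return J, dJdY


def _boundary_candidates(
    Y_grid: np.ndarray, dJdY: np.ndarray, prominence_rel: float
) -> np.ndarray:
    """Locations of local extrema of dJ/dY, refined by quadratic interpolation."""
    span = np.max(dJdY) - np.min(dJdY)
    if span <= 0.0:
        return np.array([])
    prom = prominence_rel * span
    # extrema hugging the grid ends are discretisation artifacts, not stages
    margin = max(2, len(Y_grid) // 50)
    locs = []
    for sgn in (1.0, -1.0):
        peaks, _ = find_peaks(sgn * dJdY, prominence=prom)
        for p in peaks:
            if margin <= p < len(Y_grid) - margin:
                # quadratic vertex through the three neighbouring samples
                y0, y1, y2 = Y_grid[p - 1 : p + 2]
                v0, v1, v2 = sgn * dJdY[p - 1 : p + 2]
                denom = (v0 - 2.0 * v1 + v2)
                if denom != 0.0:
                    offset = 0.5 * (v0 - v2) / denom
                    offset = np.clip(offset, -1.0, 1.0)
                    locs.append(y1 + offset * (y2 - y1 if offset >= 0 else y1 - y0))
                else:
                    locs.append(y1)
    return np.sort(np.array(locs))


def segment_stages(
    J: np.ndarray,
    dJdY: np.ndarray,
    Y_grid: np.ndarray,
    rho: np.ndarray | None = None,
    prominence_rel: float = 0.02,
    stable_tol: float = 0.05,
) -> StageModel:
    """Segment the stiffness axis into stages at the extrema of the
    current-derivative profile.

    When ``rho`` is given (the pipeline default), boundaries are located on
    the derivative of the *specific* current j = J / rho - the drift
    velocity of the progression process.  The probability density spans
    several decades across the stiffness range, so the bare current dies
    exponentially away from the probability peak and its derivative extrema
    all cluster there; the velocity field is scale-free in rho and exposes
    the stage structure over the whole range.  Without ``rho`` the bare
    dJ/dY is used.

    At most ``len(STAGE_LABELS) - 1`` boundaries are kept (the most
    prominent ones); if fewer intervals are found, labels merge from the
    advanced (right) end and a flag is raised.  Intervals on which the mean
    of |dJ/dY| is below ``stable_tol`` times its global maximum are marked
    dynamically stable.
    """
    Y_grid = np.asarray(Y_grid, dtype=float)
    J = np.asarray(J, dtype=float)
    dJdY = np.asarray(dJdY, dtype=float)
    if rho is not None:
        rho = np.asarray(rho, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            vel = np.where(rho > 0.0, J / rho, 0.0)
        signal = np.gradient(vel, Y_grid)
    else:
        signal = dJdY
    bounds = _boundary_candidates(Y_grid, signal, prominence_rel)

    n_max = len(STAGE_LABELS) - 1
    if len(bounds) > n_max:
        # keep the n_max most prominent extrema: rank by |signal| at the site
        vals = np.interp(bounds, Y_grid, np.abs(signal))
        keep = np.sort(np.argsort(vals)[-n_max:])
        bounds = bounds[keep]

    single = len(bounds) == 0
    n_int = len(bounds) + 1
    merged = n_int < len(STAGE_LABELS)
    if merged:
        # the advanced stages collapse into the last (stiffest) interval
        labels = STAGE_LABELS[: n_int - 1] + (
            "+".join(STAGE_LABELS[n_int - 1 :]),
        )
    else:
        labels = STAGE_LABELS

    edges = np.concatenate([[Y_grid[0]], bounds, [Y_grid[-1]]])
    ref = np.max(np.abs(dJdY))
    flags = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (Y_grid >= lo) & (Y_grid <= hi)
        mean_abs = np.mean(np.abs(dJdY[sel])) if np.any(sel) else 0.0
        flags.append(bool(ref == 0.0 or mean_abs < stable_tol * ref))

    return StageModel(
        Y_grid=Y_grid,
        J_of_Y=J,
        dJdY=dJdY,
        D_Y=1.0,
        boundaries=bounds,
        labels=tuple(labels),
        stable_flags=tuple(flags),
        merged=merged,
        single_stage=single,
    )


def average_current(
    J: np.ndarray, Y_grid: np.ndarray, Y_lo: float, Y_hi: float, normalise: bool = False
) -> float:
    """<J> = int_{Y_lo}^{Y_hi} J dY (trapezoid; optionally per unit width)."""
    if not Y_lo < Y_hi:
        raise ValueError("empty integration interval")
    ys = np.asarray(Y_grid, dtype=float)
    inner = ys[(ys > Y_lo) & (ys < Y_hi)]
    pts = np.concatenate([[Y_lo], inner, [Y_hi]])
    vals = np.interp(pts, ys, np.asarray(J, dtype=float))
    integral = float(np.trapezoid(vals, pts))
    if normalise:
        integral /= Y_hi - Y_lo
    return integral


def transition_probability(avg_J: float, k_i: float) -> float:
    """W = (1 + tanh(k_i <J>)) / 2; one half at zero average current."""
    if k_i <= 0.0:
        raise ValueError("gain k_i must be positive")
    return 0.5 * (1.0 + np.tanh(k_i * avg_J))


def stage_transitions(
    model: StageModel, c_k: float, eps: float = 1.0e-300
) -> TransitionResult:
    """Transition probabilities between consecutive stages and stage occupancies.

    For each consecutive stage pair the current is integrated over both
    stages; the gain k_i = c_k / <|dJ/dY|> uses the mean absolute current
    derivative over the same span, making the tanh argument invariant to
    the local current magnitude.
    """
    labels = model.labels
    edges = model.stage_edges()
    names, avgs, ks, Ws = [], [], [], []
    for i in range(len(labels) - 1):
        lo, hi = edges[i], edges[i + 2]  # union of stage i and i+1
        avg = average_current(model.J_of_Y, model.Y_grid, lo, hi)
        sel = (model.Y_grid >= lo) & (model.Y_grid <= hi)
        mean_abs_dJ = float(np.mean(np.abs(model.dJdY[sel]))) if np.any(sel) else 0.0
        k_i = c_k / max(eps, mean_abs_dJ)
        names.append(f"{labels[i]}->{labels[i + 1]}")
        avgs.append(avg)
        ks.append(k_i)
        Ws.append(transition_probability(avg, k_i))
    P = conditional_probabilities(np.array(Ws))
    return TransitionResult(
        transitions=tuple(names),
        avg_J=np.array(avgs),
        k_i=np.array(ks),
        W=np.array(Ws),
        P_labels=tuple(labels),
        P=P,
    )


def conditional_probabilities(W: np.ndarray) -> np.ndarray:
    """P_1 = 1 - W_{1->2}; P_i = prod_{j=2..i} W_{j-1->j} for i > 1."""
    W = np.asarray(W, dtype=float)
    if W.size == 0:
        raise ValueError("need at least one transition probability")
    if np.any((W < 0.0) | (W > 1.0)):
        raise ValueError("transition probabilities must lie in [0, 1]")
    P = np.empty(W.size + 1)
    P[0] = 1.0 - W[0]
    P[1:] = np.cumprod(W)
    return P
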