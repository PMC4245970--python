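"""Rescaled reactivities (rho) and pseudo-free-energy folding constraints.

theta values are probabilities and therefore small (they sum to 1 over the
RNA); folding engines expect reactivities on a scale where "highly
reactive" is about 1. Multiplying by the scored length L' gives

    rho_i = L' * theta_i,          mean(rho) = 1 exactly,

and the per-nucleotide pseudo-free-energy bonus/penalty applied during
thermodynamic folding is

    dG_i = m * ln(rho_i + 1) + b        [kcal/mol].

Two parameter presets are provided: the slope/intercept pair tuned for
this rho scale (m = 1.1, b = -0.3) and the long-standing values used with
conventional SHAPE reactivities (m = 1.8, b = -0.6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ReactivityResults

__all__ = [
    "FoldingConstraintParams",
    "RHO_TUNED",
    "SHAPE_CLASSIC",
    "theta_to_rho",
    "pseudo_free_energy",
    "write_shape_constraints",
    "read_shape_constraints",
]

#: sentinel written for positions with no reactivity data
NO_DATA = -999.0


@dataclass(frozen=True)
class FoldingConstraintParams:
    """Slope and intercept of the pseudo-free-energy term (kcal/mol)."""

    m: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.m) and np.isfinite(self.b)):
            raise ValueError("m and b must be finite")


#: parameters tuned for the mean-1 rho scale
RHO_TUNED = FoldingConstraintParams(m=1.1, b=-0.3)
#: conventional SHAPE-reactivity parameters
SHAPE_CLASSIC = FoldingConstraintParams(m=1.8, b=-0.6)


def theta_to_rho(profile: ReactivityResults | np.ndarray) -> np.ndarray:
    """Rescale a normalized theta profile to rho = L' * theta (mean 1).

    Accepts either fitted :class:`~shapeseq.model.ReactivityResults` or a
    bare theta vector. A degenerate (all-zero) profile cannot be rescaled
    — there is no reactivity signal to constrain folding with — and raises.
    """
    if isinstance(profile, ReactivityResults):
        if profile.degenerate:
            raise ValueError(
                "degenerate profile (no modification signal): folding "
                "constraints cannot be generated"
            )
        theta = profile.theta
    else:
        theta = np.asarray(profile, dtype=float)
        if theta.ndim != 1 or theta.size == 0:
            raise ValueError("theta must be a non-empty 1-D vector")
        if np.any(theta < 0) or not np.isclose(theta.sum(), 1.0, atol=1e-8):
            raise ValueError("theta must be a normalized distribution")
    return theta.size * theta


def pseudo_free_energy(rho: np.ndarray,
                       params: FoldingConstraintParams = RHO_TUNED) -> np.ndarray:
    """Per-position pseudo-free energy dG = m * ln(rho + 1) + b (natural log)."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be non-negative")
    return params.m * np.log1p(rho) + params.b


def write_shape_constraints(rho: np.ndarray, scored_positions, path,
                            length: int | None = None) -> None:
    """Write a two-column SHAPE constraint file for folding engines.

    One line per nucleotide: 1-based index and reactivity; positions
    outside ``scored_positions`` get the no-data sentinel (-999).
    ``length`` defaults to the largest scored position.
    """
    rho = np.asarray(rho, dtype=float)
    scored = [int(i) for i in scored_positions]
    if len(scored) != rho.size:
        raise ValueError("rho and scored_positions must have equal length")
    if not np.all(np.isfinite(rho)):
        raise ValueError("rho must be finite")
    n = length if length is not None else (max(scored) if scored else 0)
    values = {i: v for i, v in zip(scored, rho)}
    with open(path, "w") as fh:
        for i in range(1, n + 1):
            v = values.get(i, NO_DATA)
            fh.write(f"{i}\t{v:.8g}\n")


def read_shape_constraints(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a constraint file back: (scored positions, rho values).

    Sentinel (-999) lines are reported as no-data and excluded.
    """
    positions, values = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i, v = line.split()
            if float(v) == NO_DATA:
                continue
            positions.append(int(i))
            values.append(float(v))
    return np.array(positions, dtype=int), np.array(values, dtype=float)
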