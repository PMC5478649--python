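"""Switch analysis of the coarse-grained SAC model.

The autocatalytic core tracks total MCC, MCCT = [MCC] + [APC/C:MCC], under
conserved totals APCT = [APC/C] + [APC/C:MCC] and MadT = [Mad2] + MCCT:

    dMCCT/dt = kM1 * Kin_U * (MadT - MCCT)
               - kM3 * Kin_A * [APC/C] * [APC/C:MCC]

with the bound complex taken from the quasi-steady-state of the binding
reaction.  Writing B = km + APCT + MCCT with km = (k_mM2 + kM3)/kM2, the
bound complex is the smaller root of x^2 - B*x + MCCT*APCT = 0:

    x = (B - sqrt(B^2 - 4*MCCT*APCT)) / 2

(the radicand is B^2, not B: the quadratic admits nothing else on dimensional
grounds).  The removal term vanishes both when no APC/C is free (x -> APCT,
checkpoint on) and when no complex is bound (x -> 0), which is what makes the
core bistable: free APC/C liberates more APC/C, but only if some is free to
begin with.

Scanning the unattached-kinetochore count Kin_U in [0, 92] as a continuous
bifurcation parameter yields the s-shaped branch structure; with the
MCC-formation rate at its reference value the checkpoint-on branch persists
down to Kin_U = 1 and the silenced state becomes the only attractor exactly
at Kin_U = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .parameters import ParameterSet

__all__ = [
    "ReducedState",
    "BifurcationResult",
    "apcmcc_steady",
    "mcct_rhs",
    "bifurcation_scan",
    "hysteresis_check",
    "attachments_to_silence",
]


@dataclass(frozen=True)
class ReducedState:
    """Constants and state of the coarse-grained balance."""

    APCT: float
    MadT: float
    MCCT: float
    Kin_U: float
    km: float

    def __post_init__(self):
        if self.km <= 0:
            raise ValueError("km must be > 0")
        if not (0.0 <= self.MCCT <= self.MadT + 1e-12):
            raise ValueError("need 0 <= MCCT <= MadT")


@dataclass
class BifurcationResult:
    """Steady-state branches of total MCC against Kin_U."""

    kin_grid: np.ndarray
    branches: list                       # per grid point: list of (MCCT, stable)
    fold_points: list                    # Kin_U values where root count changes
    bistable_range: tuple | None         # (lo, hi) Kin_U with >= 2 stable states

    def stable_roots(self, i: int) -> list:
        return [m for m, s in self.branches[i] if s]

    def n_stable(self) -> np.ndarray:
        return np.array([len(self.stable_roots(i))
                         for i in range(len(self.kin_grid))])


def apcmcc_steady(MCCT: float, APCT: float, km: float) -> float:
    """Quasi-steady concentration of the APC/C:MCC complex (uM).

    Smaller root of the binding quadratic; always within
    [0, min(APCT, MCCT)], and the discriminant (km + APCT + MCCT)^2
    - 4*MCCT*APCT = (APCT - MCCT)^2 + km*(km + 2*APCT + 2*MCCT) is
    non-negative for km >= 0.
    """
    if MCCT < 0 or APCT < 0 or km <= 0:
        raise ValueError("need MCCT >= 0, APCT >= 0, km > 0")
    B = km + APCT + MCCT
    disc = B * B - 4.0 * MCCT * APCT
    x = 0.5 * (B - np.sqrt(disc))
    return float(min(max(x, 0.0), min(APCT, MCCT)))


def _rates_from_params(params: ParameterSet) -> dict:
    return {"kM1": params.kM1, "kM3": params.kM3, "km": params.km,
            "n_kin": params.n_kinetochores}


def mcct_rhs(state: ReducedState, rates: dict | ParameterSet,
             include_kina: bool = True) -> float:
    """Production-minus-removal balance of total MCC (uM/s).

    Production: kinetochore-mediated conversion of the free Mad2 pool,
    kM1 * Kin_U * (MadT - MCCT).  Removal: the autocatalytic disassembly
    kM3 * [APC/C] * [APC/C:MCC], optionally (default) carrying the
    attached-kinetochore count as an additional factor.
    """
    if isinstance(rates, ParameterSet):
        rates = _rates_from_params(rates)
    x = apcmcc_steady(state.MCCT, state.APCT, state.km)
    apc_free = state.APCT - x
    kin_a = rates["n_kin"] - state.Kin_U
    removal = rates["kM3"] * apc_free * x
    if include_kina:
        removal *= kin_a
    return rates["kM1"] * state.Kin_U * (state.MadT - state.MCCT) - removal


def _roots_at(kin_u: float, rates: dict, APCT: float, MadT: float, km: float,
              include_kina: bool, n_grid: int = 2000):
    """All steady states of the MCCT balance in [0, MadT] at fixed Kin_U.

    Dense sign-change bracketing on ``n_grid`` points, brentq refinement to
    relative 1e-10; stability from the sign of the slope at the root.
    """
    f = lambda m: mcct_rhs(
        ReducedState(APCT, MadT, min(max(m, 0.0), MadT), kin_u, km),
        rates, include_kina)
    grid = np.linspace(0.0, MadT, n_grid)
    vals = np.array([f(m) for m in grid])
    roots = []
    for i in range(n_grid - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0:
            roots.append(brentq(f, grid[i], grid[i + 1],
                                xtol=1e-14, rtol=1e-12))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    # deduplicate and flag stability
    out = []
    for r in roots:
        if out and abs(r - out[-1][0]) < 1e-9 * max(MadT, 1.0):
            continue
        h = 1e-7 * max(MadT, 1.0)
        slope = (f(min(r + h, MadT)) - f(max(r - h, 0.0))) / (2 * h)
        out.append((float(r), bool(slope < 0)))
    return out


def bifurcation_scan(rates: dict | ParameterSet, APCT: float, MadT: float,
                     kin_grid: np.ndarray, include_kina: bool = True,
                     n_grid: int = 2000) -> BifurcationResult:
    """One-parameter scan of the MCCT steady states over Kin_U.

    ``kin_grid`` may be non-integer (the count is treated as a continuous
    bifurcation parameter; a count-valued parameter cannot fold otherwise).
    """
    if isinstance(rates, ParameterSet):
        rates = _rates_from_params(rates)
    km = rates["km"]
    kin_grid = np.asarray(kin_grid, dtype=float)
    if kin_grid.min() < 0 or kin_grid.max() > rates["n_kin"]:
        raise ValueError("kin_grid must lie within [0, n_kinetochores]")
    branches = [_roots_at(k, rates, APCT, MadT, km, include_kina, n_grid)
                for k in kin_grid]
    if any(len(b) == 0 for b in branches):
        raise RuntimeError("no steady state found at some grid point")

    order = np.argsort(kin_grid)
    nst = np.array([sum(s for _, s in branches[i]) for i in order])
    folds = []
    for j in range(1, len(order)):
        if nst[j] != nst[j - 1]:
            folds.append(float(0.5 * (kin_grid[order[j - 1]]
                                      + kin_grid[order[j]])))
    bist = kin_grid[order][nst >= 2]
    bistable = (float(bist.min()), float(bist.max())) if bist.size else None
    return BifurcationResult(kin_grid=kin_grid, branches=branches,
                             fold_points=folds, bistable_range=bistable)


def hysteresis_check(result: BifurcationResult) -> dict:
    """Path dependence of the scan: follow the nearest stable branch along a
    detaching (Kin_U increasing) and an attaching (decreasing) sweep and
    report where the two visits differ.

    Returns ``{"hysteretic": bool, "interval": (lo, hi) | None,
    "forward": ..., "backward": ...}``; the interval equals the scan's
    bistable range whenever the system is bistable.
    """
    order = np.argsort(result.kin_grid)
    kins = result.kin_grid[order]

    def sweep(indices, start_low):
        # branch following: start on the low (silenced) or high (checkpoint
        # on) branch and keep the stable root nearest the previous one
        visited = []
        prev = None
        for i in indices:
            stable = result.stable_roots(i)
            if not stable:
                stable = [m for m, _ in result.branches[i]]
            if prev is None:
                prev = min(stable) if start_low else max(stable)
            prev = min(stable, key=lambda m: abs(m - prev))
            visited.append(prev)
        return visited

    fw = sweep(list(order), start_low=False)           # attaching -> detaching
    bw = sweep(list(order)[::-1], start_low=True)[::-1]
    differ = np.abs(np.array(fw) - np.array(bw)) > 1e-6
    if not differ.any():
        return {"hysteretic": False, "interval": None,
                "forward": fw, "backward": bw}
    lo, hi = kins[differ].min(), kins[differ].max()
    return {"hysteretic": True, "interval": (float(lo), float(hi)),
            "forward": fw, "backward": bw}


def attachments_to_silence(params: ParameterSet, include_kina: bool = True
                           ) -> int:
    """Number of kinetochore attachments required before the silenced branch
    is the only remaining attractor of the coarse-grained balance.

    Scans integer unattached counts from 92 down to 0 and reports the first
    attached count at which the checkpoint-on branch (total MCC above half
    the Mad2 pool) has disappeared, leaving only the silenced low-MCC branch
    (which reaches total MCC = 0 exactly when Kin_U = 0 kills production).
    """
    n = params.n_kinetochores
    MadT = params.Mad2_reduced
    scan = bifurcation_scan(params, params.APC, MadT,
                            np.arange(n, -1, -1), include_kina=include_kina)
    for i, kin_u in enumerate(scan.kin_grid):
        stable = scan.stable_roots(i)
        if stable and max(stable) < 0.5 * MadT:
            return int(n - kin_u)
    return n + 1  # never silenced on the integer grid
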