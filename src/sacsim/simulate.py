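"""Time integration of the SAC networks.

Two treatments of the 92 kinetochores are supported:

* ``deterministic`` — the attachment reaction runs inside the ODE system, so
  Kin_U(t) = 92*exp(-k_attach*t) decays continuously; the last-attachment time
  is defined as the first time Kin_U drops below 0.5.
* ``hybrid`` — kinetochores are discrete: the 92 independent first-order
  attachments are sampled exactly (exponential clocks), the stiff integrator
  runs between events and is restarted with Kin_U decremented at each one.
  Concentrations stay deterministic throughout, which is justified because
  molecular copy numbers exceed the kinetochore count roughly a thousandfold;
  the count threshold separating the two treatments defaults to 100.

Concentrations may undershoot zero by integrator tolerance; reported values
are clipped at zero and an undershoot beyond 1e-8 uM triggers a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .network import ReactionNetwork, ode_rhs
from .parameters import ConfigurationError

__all__ = [
    "TimeCourse",
    "SolverSettings",
    "SolverError",
    "attachment_schedule",
    "simulate",
    "steady_state",
]

_CLIP_WARN = 1e-8  # uM; larger undershoots are reported


class SolverError(RuntimeError):
    """Integration failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time t = {last_time:.6g} s)")
        self.last_time = last_time


@dataclass
class SolverSettings:
    """Integration controls.

    ``seed`` is required in hybrid mode (attachment times are random) and is
    recorded in the resulting :class:`TimeCourse`.
    """

    mode: str = "deterministic"          # "deterministic" | "hybrid"
    hybrid_count_threshold: int = 100
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    t_end: float = 6000.0
    n_out: int = 1200
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("deterministic", "hybrid"):
            raise ConfigurationError(f"unknown solver mode {self.mode!r}")
        if self.t_end <= 0:
            raise ConfigurationError("t_end must be > 0")
        if self.mode == "hybrid" and self.seed is None:
            raise ConfigurationError("hybrid mode requires a seed")


@dataclass
class TimeCourse:
    """Trajectory on a fixed output grid plus the attachment-event record."""

    times: np.ndarray                    # (T,), seconds, strictly increasing
    values: np.ndarray                   # (T, S) concentrations / counts
    species: list
    attachment_events: list              # [(time, kinetochore index), ...]
    t_last_attach: float                 # seconds, or inf if never
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[:, self.species.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, species, value) frame."""
        t = np.repeat(self.times, len(self.species))
        sp = np.tile(np.array(self.species, dtype=object), len(self.times))
        return pd.DataFrame(
            {"time": t, "species": sp, "value": self.values.ravel()})

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.attachment_events,
                            columns=["time", "kinetochore"])


def attachment_schedule(n_kinetochores: int, k_attach: float, mode: str,
                        seed: int | None = None,
                        t_end: float = np.inf) -> list:
    """Attachment events for ``n_kinetochores`` independent first-order
    attachments at rate ``k_attach`` each.

    Hybrid mode samples one exponential waiting time per kinetochore (the
    sorted times are exactly the event times of the thinning Kin_U pool);
    deterministic mode has no discrete events and returns an empty list.
    """
    if k_attach < 0:
        raise ValueError("k_attach must be >= 0")
    if mode == "deterministic" or k_attach == 0:
        return []
    rng = np.random.default_rng(seed)
    waits = rng.exponential(1.0 / k_attach, size=n_kinetochores)
    order = np.argsort(waits)
    return [(float(waits[i]), int(i)) for i in order if waits[i] <= t_end]


def _t_last_deterministic(n_kin: int, k_attach: float) -> float:
    """First time the continuous Kin_U(t) = n*exp(-kt) falls below 0.5."""
    if k_attach <= 0 or n_kin == 0:
        return np.inf
    return float(np.log(2.0 * n_kin) / k_attach)


def _integrate(network: ReactionNetwork, y0, t0, t1, t_eval, settings,
               skip_schemes):
    fun = lambda t, y: network.rhs(np.maximum(y, 0.0), skip_schemes)
    sol = solve_ivp(fun, (t0, t1), y0, method="LSODA", t_eval=t_eval,
                    rtol=settings.rel_tol, atol=settings.abs_tol)
    if not sol.success:
        raise SolverError(sol.message, sol.t[-1] if sol.t.size else t0)
    return sol


def simulate(network: ReactionNetwork, settings: SolverSettings | None = None
             ) -> TimeCourse:
    """Integrate ``network`` from its initial state to ``settings.t_end``."""
    settings = settings or SolverSettings()
    n_kin = network.n_kinetochores
    k_att = network.params.k_attach
    times = np.linspace(0.0, settings.t_end, settings.n_out)
    iu, ia = network.index["Kin_U"], network.index["Kin_A"]
    attach_scheme = "R1" if network.name == "full" else "M1"
    y0 = network.initial_state()

    if settings.mode == "deterministic":
        sol = _integrate(network, y0, 0.0, settings.t_end, times, settings, ())
        values = sol.y.T
        events = []
        t_last = _t_last_deterministic(n_kin, k_att)
    else:
        events = attachment_schedule(n_kin, k_att, "hybrid", settings.seed,
                                     settings.t_end)
        values = np.empty((len(times), len(y0)))
        y = y0.copy()
        t_prev = 0.0
        breakpoints = [t for t, _ in events] + [settings.t_end]
        filled = 0
        for t_next in breakpoints:
            mask = (times > t_prev) & (times <= t_next)
            if t_prev == 0.0:
                mask |= times == 0.0
            t_eval = times[mask]
            if t_next > t_prev:
                # always evaluate at the segment end to carry the state over
                t_eval_run = t_eval if (t_eval.size and
                                        t_eval[-1] >= t_next) \
                    else np.append(t_eval, t_next)
                sol = _integrate(network, y, t_prev, t_next,
                                 t_eval_run, settings, (attach_scheme,))
                if t_eval.size:
                    values[filled:filled + t_eval.size] = \
                        sol.y[:, :t_eval.size].T
                    filled += t_eval.size
                y = sol.y[:, -1].copy()
            elif t_eval.size:
                values[filled:filled + t_eval.size] = y
                filled += t_eval.size
            if t_next < settings.t_end:        # an attachment event
                y[iu] -= 1.0
                y[ia] += 1.0
            t_prev = t_next
        if filled < len(times):                # grid points exactly at t_end
            values[filled:] = y
        t_last = events[-1][0] if len(events) == n_kin else np.inf

    undershoot = values.min()
    if undershoot < -_CLIP_WARN:
        warnings.warn(f"concentration undershoot {undershoot:.3g} uM clipped "
                      "to zero", RuntimeWarning)
    values = np.clip(values, 0.0, None)
    # kinetochore counters are integers in hybrid mode; keep exact pairing
    values[:, ia] = n_kin - values[:, iu]
    return TimeCourse(times=times, values=values,
                      species=list(network.species_names),
                      attachment_events=events, t_last_attach=t_last,
                      seed=settings.seed,
                      meta={"mode": settings.mode,
                            "params_hash": network.params.hash(),
                            "model": network.name})


def steady_state(network: ReactionNetwork, fixed_kinetochores: tuple,
                 guess: np.ndarray | None = None, tol: float = 1e-10,
                 presimulate: float = 0.0) -> np.ndarray:
    """A fixed point of the network with kinetochore counts frozen.

    ``fixed_kinetochores`` is (Kin_U, Kin_A) with the pair summing to the
    network's kinetochore count.  Multistable systems are handled by the
    caller supplying different ``guess`` vectors (optionally relaxed first by
    integrating for ``presimulate`` seconds).  Raises :class:`SolverError`
    with the residual if no fixed point is found.
    """
    kin_u, kin_a = fixed_kinetochores
    if abs(kin_u + kin_a - network.n_kinetochores) > 1e-9:
        raise ValueError("Kin_U + Kin_A must equal n_kinetochores")
    iu, ia = network.index["Kin_U"], network.index["Kin_A"]
    attach_scheme = "R1" if network.name == "full" else "M1"
    y = network.initial_state() if guess is None else np.array(guess, float)
    y[iu], y[ia] = kin_u, kin_a

    if presimulate > 0:
        fun = lambda t, s: network.rhs(np.maximum(s, 0.0), (attach_scheme,))
        sol = solve_ivp(fun, (0.0, presimulate), y, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        y = np.maximum(sol.y[:, -1], 0.0)

    free = [i for i in range(len(y)) if i not in (iu, ia)]

    # anchor the conserved totals of the guess so the root search cannot
    # drift to a fixed point on a different conservation manifold
    from .network import conservation_totals
    totals0 = conservation_totals(network, y)
    keys = sorted(totals0)

    def resid(x):
        s = y.copy()
        s[free] = x
        t = conservation_totals(network, np.maximum(s, 0.0))
        cons = [t[k] - totals0[k] for k in keys]
        return np.concatenate([
            network.rhs(np.maximum(s, 0.0), (attach_scheme,))[free],
            np.asarray(cons)])

    res = least_squares(resid, y[free], bounds=(0.0, np.inf),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    out = y.copy()
    out[free] = res.x
    norm = float(np.linalg.norm(network.rhs(out, (attach_scheme,))))
    if norm > tol:
        raise SolverError(f"steady state residual {norm:.3g} above tolerance "
                          f"{tol:.3g}", 0.0)
    return out
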