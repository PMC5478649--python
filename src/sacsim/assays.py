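"""In-silico perturbation assays: mutant screens and Securin treatments.

Depletion and over-expression rescale initial concentrations (to 5%/40% and
tenfold, respectively, in the default screen); Mad2-targeting siRNA is a
Mad2 depletion; nocodazole lowers the kinetochore attachment rate through a
dose-response map.  Each perturbed run is classified on two axes from the
relative APC/C:Cdc20 activity A(t):

* inhibition during the attachment window — FI (full), WI (weak), NI (none)
  from the maximum of A(t) before the last attachment;
* checkpoint exit — PE (proper), DE (delayed), IE (improper: never, or
  premature activation before the last attachment) from the delay until A(t)
  first reaches the activation threshold afterwards.

A(t) is normalised by the achievable ceiling min(total APC/C, total Cdc20):
an APC/C:Cdc20 complex needs one of each, so under strong Cdc20 depletion the
ceiling is the Cdc20 pool, not total APC/C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .network import build_full_network
from .parameters import ConfigurationError, ParameterSet
from .simulate import SolverSettings, TimeCourse, simulate

__all__ = [
    "Treatment",
    "Thresholds",
    "MutantClassification",
    "AssayError",
    "apply_treatment",
    "nocodazole_to_kattach",
    "classify",
    "run_mutant_screen",
    "securin_report",
    "DEFAULT_SCREEN",
]

# species name -> ParameterSet initial-concentration symbol
_TARGETS = {
    "Mad2": "OMad2",
    "O-Mad2": "OMad2",
    "C-Mad2": "CMad2",
    "BubR1:Bub3": "BubR1Bub3",
    "Cdc20": "Cdc20",
    "APC/C": "APC",
    "Securin": "Securin",
    "CyclinB": "CyclinB",
}


class AssayError(RuntimeError):
    pass


@dataclass(frozen=True)
class Treatment:
    """One perturbation of the reference conditions.

    ``magnitude`` is the retained fraction for depletion/siRNA (0.05 keeps
    5%) and the fold increase for over-expression (10 = tenfold); ``dose`` is
    the nocodazole concentration in ng/ml.
    """

    kind: str = "none"          # depletion | overexpression | nocodazole |
                                # siRNA_Mad2 | none
    target: str | None = None
    magnitude: float = 1.0
    dose: float = 0.0
    c50: float = 10.0           # ng/ml, half-effect nocodazole dose

    def __post_init__(self):
        if self.kind not in ("depletion", "overexpression", "nocodazole",
                             "siRNA_Mad2", "none"):
            raise ConfigurationError(f"unknown treatment kind {self.kind!r}")
        if self.magnitude <= 0:
            raise ConfigurationError("magnitude must be > 0")
        if self.dose < 0:
            raise ConfigurationError("dose must be >= 0")

    @property
    def label(self) -> str:
        if self.kind == "none":
            return "Wild-Type"
        if self.kind == "depletion":
            return f"{self.target} D {self.magnitude:.0%}"
        if self.kind == "overexpression":
            return f"{self.target} O (x{self.magnitude:g})"
        if self.kind == "siRNA_Mad2":
            return f"Mad2 siRNA ({self.magnitude:.0%})"
        return f"nocodazole {self.dose:g} ng/ml"


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds (fractions of the activity ceiling and
    delays in seconds).  Inhibition is FI below ``theta_fi``, NI above
    ``theta_ni``; exit is PE within ``tau_pe`` of the last attachment, DE
    within ``tau_de``, IE otherwise."""

    theta_fi: float = 0.15
    theta_ni: float = 0.5
    theta_act: float = 0.8
    tau_pe: float = 600.0
    tau_de: float = 3600.0


@dataclass(frozen=True)
class MutantClassification:
    inhibition: str                       # FI | WI | NI
    exit: str                             # PE | DE | IE
    activity_peak_during_attachment: float
    reactivation_delay: float             # seconds; inf if never
    thresholds_used: Thresholds

    @property
    def label(self) -> str:
        return f"({self.inhibition}) - ({self.exit})"


def nocodazole_to_kattach(dose: float, base_k_attach: float,
                          c50: float = 10.0,
                          table: dict | None = None) -> float:
    """Attachment rate under a nocodazole dose (ng/ml).

    Default map: base * 1/(1 + dose/c50) — monotone non-increasing, 1 at
    dose 0, half at ``c50``, 0 in the limit.  ``table`` switches to literal
    stepwise dosing: a mapping of dose breakpoints to retained fractions,
    applied as a step function (the largest breakpoint <= dose wins).
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if table is not None:
        frac = 1.0
        for d in sorted(table):
            if dose >= d:
                frac = table[d]
        return base_k_attach * frac
    return base_k_attach / (1.0 + dose / c50)


def apply_treatment(params: ParameterSet, t: Treatment) -> ParameterSet:
    """A new ParameterSet with the treatment applied.

    Depletion/over-expression and siRNA rescale only the targeted initial
    concentration; nocodazole rescales only ``k_attach``; ``none`` is the
    identity.
    """
    if t.kind == "none":
        return params
    if t.kind == "nocodazole":
        return params.replace(
            k_attach=nocodazole_to_kattach(t.dose, params.k_attach, t.c50))
    if t.kind == "siRNA_Mad2":
        target = "Mad2"
        factor = t.magnitude
    else:
        target = t.target
        factor = t.magnitude
    if target not in _TARGETS:
        raise ConfigurationError(f"unknown treatment target {target!r}")
    if target == "Mad2":  # total Mad2 = open + closed pools
        return params.replace(OMad2=params.OMad2 * factor,
                              CMad2=params.CMad2 * factor)
    symbol = _TARGETS[target]
    return params.replace(**{symbol: getattr(params, symbol) * factor})


def classify(tc: TimeCourse, apct: float,
             thresholds: Thresholds | None = None) -> MutantClassification:
    """Classify a trajectory on the (inhibition, exit) axes.

    ``apct`` is the normaliser of the activity A(t) = [APC/C:Cdc20]/apct
    (callers typically pass min(total APC/C, total Cdc20)).  The attachment
    window runs from the first attachment event (0 for continuous
    attachment) to the last-attachment time; the trajectory must cover the
    window plus a post-attachment horizon.
    """
    th = thresholds or Thresholds()
    if apct <= 0:
        raise AssayError("activity normaliser must be > 0")
    t_last = tc.t_last_attach
    if not np.isfinite(t_last) or tc.times[-1] <= t_last:
        raise AssayError("trajectory does not cover the attachment window "
                         "and a post-attachment horizon")
    A = tc["APC/C:Cdc20"] / apct
    t_first = tc.attachment_events[0][0] if tc.attachment_events else 0.0
    window = (tc.times >= t_first) & (tc.times <= t_last)
    peak = float(A[window].max())
    if peak < th.theta_fi:
        inhibition = "FI"
    elif peak > th.theta_ni:
        inhibition = "NI"
    else:
        inhibition = "WI"

    premature = bool((A[tc.times < t_last] >= th.theta_act).any())
    after = tc.times >= t_last
    hit = after & (A >= th.theta_act)
    if premature:
        exit_, delay = "IE", 0.0
    elif not hit.any():
        exit_, delay = "IE", np.inf
    else:
        delay = float(tc.times[hit][0] - t_last)
        exit_ = "PE" if delay <= th.tau_pe else \
            "DE" if delay <= th.tau_de else "IE"
    return MutantClassification(
        inhibition=inhibition, exit=exit_,
        activity_peak_during_attachment=peak,
        reactivation_delay=delay, thresholds_used=th)


#: (target, kind, magnitude) triples of the default screen
DEFAULT_SCREEN = [
    ("Mad2", "overexpression", 10.0),
    ("Mad2", "depletion", 0.05),
    ("Mad2", "depletion", 0.40),
    ("BubR1:Bub3", "overexpression", 10.0),
    ("BubR1:Bub3", "depletion", 0.05),
    ("BubR1:Bub3", "depletion", 0.40),
    ("Cdc20", "overexpression", 10.0),
    ("Cdc20", "depletion", 0.05),
    ("Cdc20", "depletion", 0.40),
]


def run_mutant_screen(params: ParameterSet, screen: list | None = None,
                      thresholds: Thresholds | None = None,
                      settings: SolverSettings | None = None) -> pd.DataFrame:
    """Classify the wild type plus every (target, kind, magnitude) triple.

    Returns one row per mutant with the treatment label, classification and
    the quantities it was derived from.
    """
    screen = DEFAULT_SCREEN if screen is None else screen
    settings = settings or SolverSettings(mode="deterministic", t_end=6000.0)
    treatments = [Treatment()] + [
        Treatment(kind=kind, target=target, magnitude=mag)
        for target, kind, mag in screen]
    rows = []
    for t in treatments:
        ptreat = apply_treatment(params, t)
        tc = simulate(build_full_network(ptreat), settings)
        ceiling = min(ptreat.APC, ptreat.Cdc20)
        cl = classify(tc, ceiling, thresholds)
        rows.append({
            "mutation": t.label, "target": t.target or "-", "kind": t.kind,
            "magnitude": t.magnitude, "inhibition": cl.inhibition,
            "exit": cl.exit, "classification": cl.label,
            "activity_peak": cl.activity_peak_during_attachment,
            "reactivation_delay_s": cl.reactivation_delay,
        })
    return pd.DataFrame(rows)


def securin_report(tc: TimeCourse, smooth_window: int = 21,
                   polyorder: int = 3):
    """Normalised Securin trace, its degradation rate, and anaphase onset.

    The rate trace is -dS/dt from a Savitzky-Golay local polynomial on the
    uniform output grid (raw finite differences amplify solver noise);
    anaphase onset is the time of the degradation-rate peak.
    Returns (normalised trace, rate trace, onset time).
    """
    if "Securin" not in tc.species:
        raise AssayError("Securin not present in trajectory")
    s = tc["Securin"]
    if s[0] <= 0:
        raise AssayError("Securin(0) must be > 0 to normalise")
    dt = float(tc.times[1] - tc.times[0])
    window = min(smooth_window, len(s) - (1 - len(s) % 2))
    if window % 2 == 0:
        window -= 1
    if window <= polyorder:
        raise AssayError("trajectory too short for the smoothing window")
    rate = -savgol_filter(s, window, polyorder, deriv=1, delta=dt)
    onset = float(tc.times[int(np.argmax(rate))])
    return s / s[0], rate, onset
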