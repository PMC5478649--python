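"""Reaction networks for the full and coarse-grained SAC models.

The full model couples two modules — checkpoint activation (MCC assembly at
unattached kinetochores, APC/C sequestration) and silencing (Mad2 stripping
catalysed by attached kinetochores, BCC decay) — as 17 mass-action reaction
schemes over 15 molecular species plus the two kinetochore state counters
Kin_U / Kin_A.  The coarse-grained model keeps only the autocatalytic core
(MCC formation, APC/C:MCC binding, APC/C-catalysed disassembly) plus the
Securin output, 5 schemes in total.

Kinetochore counts enter rate laws as dimensionless multipliers ("modifiers"):
the O-Mad2 -> C-Mad2 turnover is proportional to Kin_U, Mad2 stripping to
Kin_A, and the coarse-grained feedback to free APC/C (and, by default, Kin_A).

One deliberate mass-balance choice: stripping Mad2 from APC/C:Cdc20:MCC
releases the MCC-borne Cdc20 as a free molecule, so that total Cdc20 is
conserved exactly (every inhibitory complex carries its Cdc20 with it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import ConfigurationError, ParameterSet

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "build_full_network",
    "build_reduced_network",
    "ode_rhs",
    "conservation_totals",
    "FULL_SPECIES",
    "REDUCED_SPECIES",
]

# Core composition of every full-model species: copies of the conserved
# building blocks carried by one molecule of the complex.
_COMPOSITION = {
    "Kin_U":               {},
    "Kin_A":               {},
    "APC/C":               {"apc": 1},
    "Cdc20":               {"cdc20": 1},
    "APC/C:Cdc20":         {"apc": 1, "cdc20": 1},
    "Securin":             {"securin": 1},
    "CyclinB":             {"cyclinb": 1},
    "O-Mad2":              {"mad2": 1},
    "C-Mad2":              {"mad2": 1},
    "C-Mad2:Cdc20":        {"mad2": 1, "cdc20": 1},
    "BubR1:Bub3":          {"bub": 1},
    "MCC":                 {"mad2": 1, "cdc20": 1, "bub": 1},
    "BCC":                 {"cdc20": 1, "bub": 1},
    "APC/C:MCC":           {"apc": 1, "mad2": 1, "cdc20": 1, "bub": 1},
    "APC/C:Cdc20:C-Mad2":  {"apc": 1, "cdc20": 1, "mad2": 1},
    "APC/C:BCC":           {"apc": 1, "cdc20": 1, "bub": 1},
    "APC/C:Cdc20:MCC":     {"apc": 1, "cdc20": 2, "mad2": 1, "bub": 1},
}

FULL_SPECIES = tuple(_COMPOSITION)

REDUCED_SPECIES = ("Kin_U", "Kin_A", "Mad2", "MCC", "APC/C", "APC/C:MCC",
                   "Securin")

_ROLES = {
    "Kin_U": "kinetochore-state", "Kin_A": "kinetochore-state",
    "APC/C": "promoter", "Cdc20": "promoter", "APC/C:Cdc20": "promoter",
    "Securin": "output", "CyclinB": "output",
    "O-Mad2": "inhibitor", "C-Mad2": "inhibitor", "C-Mad2:Cdc20": "inhibitor",
    "BubR1:Bub3": "inhibitor", "MCC": "inhibitor", "BCC": "inhibitor",
    "APC/C:MCC": "inhibitor", "APC/C:Cdc20:C-Mad2": "inhibitor",
    "APC/C:BCC": "inhibitor", "APC/C:Cdc20:MCC": "inhibitor",
    "Mad2": "inhibitor",
}


@dataclass(frozen=True)
class Species:
    """One chemical species (or kinetochore state counter) of a network."""

    name: str
    role: str
    initial_amount: float

    def __post_init__(self):
        if self.initial_amount < 0:
            raise ConfigurationError(
                f"initial amount of {self.name} must be >= 0")
        if self.role not in ("inhibitor", "promoter", "neutral", "output",
                             "kinetochore-state"):
            raise ConfigurationError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction scheme (reversible schemes are one object).

    ``modifiers`` are species whose concentration multiplies the forward
    propensity without being consumed (kinetochore counters, free APC/C in
    the coarse-grained feedback).
    """

    scheme: str
    educts: tuple
    products: tuple
    rate_symbol: str
    modifiers: tuple = ()
    reverse_rate_symbol: str | None = None

    @property
    def reversible(self) -> bool:
        return self.reverse_rate_symbol is not None

    def __post_init__(self):
        for m in self.modifiers:
            if m in self.educts:
                raise ConfigurationError(
                    f"{self.scheme}: modifier {m} must not be consumed")


class ReactionNetwork:
    """Species + reactions + parameters, compiled for fast RHS evaluation."""

    def __init__(self, name: str, species: list, reactions: list,
                 params: ParameterSet):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ConfigurationError("species names must be unique")
        self.name = name
        self.species = list(species)
        self.species_names = names
        self.index = {n: i for i, n in enumerate(names)}
        self.reactions = list(reactions)
        self.params = params
        self.n_kinetochores = params.n_kinetochores
        for r in self.reactions:
            for s in r.educts + r.products + r.modifiers:
                if s not in self.index:
                    raise ConfigurationError(
                        f"{r.scheme}: unknown species {s!r}")
        self._compile()

    # ------------------------------------------------------------ compile
    def _compile(self) -> None:
        """Expand reversible schemes into elementary steps and build the
        stoichiometry matrix / propensity index arrays."""
        steps = []  # (rate value, educt idx list, modifier idx list, stoich)
        n = len(self.species)
        for r in self.reactions:
            k = getattr(self.params, r.rate_symbol, None)
            if k is None:
                raise ConfigurationError(
                    f"missing parameter {r.rate_symbol!r} for {r.scheme}")
            fwd = np.zeros(n)
            for e in r.educts:
                fwd[self.index[e]] -= 1
            for p in r.products:
                fwd[self.index[p]] += 1
            steps.append((k, [self.index[e] for e in r.educts],
                          [self.index[m] for m in r.modifiers], fwd, r.scheme))
            if r.reversible:
                krev = getattr(self.params, r.reverse_rate_symbol, None)
                if krev is None:
                    raise ConfigurationError(
                        f"missing parameter {r.reverse_rate_symbol!r} "
                        f"for {r.scheme}")
                steps.append((krev, [self.index[p] for p in r.products],
                              [], -fwd, r.scheme + "_rev"))
        self._step_schemes = [s[4] for s in steps]
        self._rates = np.array([s[0] for s in steps])
        self._educt_idx = [np.array(s[1], dtype=int) for s in steps]
        self._mod_idx = [np.array(s[2], dtype=int) for s in steps]
        self._stoich = np.column_stack([s[3] for s in steps])  # n x m

    @property
    def n_schemes(self) -> int:
        return len({r.scheme for r in self.reactions})

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species], dtype=float)

    def propensities(self, state: np.ndarray,
                     skip_schemes: tuple = ()) -> np.ndarray:
        """Mass-action propensity of every elementary step at ``state``."""
        props = self._rates.copy()
        for j, (ei, mi) in enumerate(zip(self._educt_idx, self._mod_idx)):
            if self._step_schemes[j].split("_rev")[0] in skip_schemes:
                props[j] = 0.0
                continue
            for i in ei:
                props[j] *= state[i]
            for i in mi:
                props[j] *= state[i]
        return props

    def rhs(self, state: np.ndarray, skip_schemes: tuple = ()) -> np.ndarray:
        """Stoichiometry-weighted sum of propensities (no sign checks; the
        public :func:`ode_rhs` validates the state first)."""
        return self._stoich @ self.propensities(state, skip_schemes)


# ------------------------------------------------------------------ builders
def build_full_network(params: ParameterSet) -> ReactionNetwork:
    """The 17-scheme full SAC network (activation + silencing modules)."""
    p = params
    init = {
        "Kin_U": float(p.n_kinetochores), "Kin_A": 0.0,
        "APC/C": p.APC, "Cdc20": p.Cdc20, "APC/C:Cdc20": 0.0,
        "Securin": p.Securin, "CyclinB": p.CyclinB,
        "O-Mad2": p.OMad2, "C-Mad2": p.CMad2, "C-Mad2:Cdc20": 0.0,
        "BubR1:Bub3": p.BubR1Bub3, "MCC": 0.0, "BCC": 0.0,
        "APC/C:MCC": 0.0, "APC/C:Cdc20:C-Mad2": 0.0, "APC/C:BCC": 0.0,
        "APC/C:Cdc20:MCC": 0.0,
    }
    species = [Species(n, _ROLES[n], init[n]) for n in FULL_SPECIES]

    mad2_decay = [("R13", ("O-Mad2",), (), "k_attach")]
    if p.mad2_decay_pools == "both":
        mad2_decay.append(("R13", ("C-Mad2",), (), "k_attach"))

    R = Reaction
    reactions = [
        R("R1", ("Kin_U",), ("Kin_A",), "k_attach"),
        R("R2", ("APC/C", "Cdc20"), ("APC/C:Cdc20",), "k1",
          reverse_rate_symbol="k_m1"),
        R("R3", ("APC/C:Cdc20", "Securin"), ("APC/C:Cdc20",), "kD"),
        R("R4", ("APC/C:Cdc20", "CyclinB"), ("APC/C:Cdc20",), "kD"),
        R("R5", ("APC/C", "MCC"), ("APC/C:MCC",), "k2",
          reverse_rate_symbol="k_m2"),
        R("R6", ("O-Mad2",), ("C-Mad2",), "k3", modifiers=("Kin_U",),
          reverse_rate_symbol="k_m3"),
        R("R7", ("Cdc20", "C-Mad2"), ("C-Mad2:Cdc20",), "k4"),
        R("R8", ("C-Mad2:Cdc20", "BubR1:Bub3"), ("MCC",), "k5",
          reverse_rate_symbol="k_m5"),
        R("R11", ("O-Mad2", "Cdc20"), ("C-Mad2:Cdc20",), "k6",
          reverse_rate_symbol="k_m6"),
        R("R12", ("Cdc20", "BubR1:Bub3"), ("BCC",), "k7",
          reverse_rate_symbol="k_m7"),
        *[R(sch, e, pr, k) for sch, e, pr, k in mad2_decay],
        R("R14", ("APC/C:Cdc20", "C-Mad2"), ("APC/C:Cdc20:C-Mad2",), "k4",
          reverse_rate_symbol="k_m4"),
        R("R15", ("APC/C:Cdc20:C-Mad2", "BubR1:Bub3"), ("APC/C:MCC",), "k5",
          reverse_rate_symbol="k_m5"),
        R("R16", ("APC/C:Cdc20", "MCC"), ("APC/C:Cdc20:MCC",), "k2",
          reverse_rate_symbol="k_m2"),
        R("R17", ("APC/C:MCC",), ("APC/C:BCC", "O-Mad2"), "k8",
          modifiers=("Kin_A",)),
        # The stripped complex releases its MCC-borne Cdc20, conserving
        # total Cdc20 exactly.
        R("R18", ("APC/C:Cdc20:MCC",), ("APC/C:BCC", "O-Mad2", "Cdc20"),
          "k9", modifiers=("Kin_A",)),
        R("R19", ("APC/C:BCC",), ("APC/C:Cdc20", "BubR1:Bub3"), "k10"),
    ]
    net = ReactionNetwork("full", species, reactions, params)
    return net


def build_reduced_network(params: ParameterSet, *,
                          include_kina_in_feedback: bool = True,
                          degrading_species: str = "APC/C"
                          ) -> ReactionNetwork:
    """The 5-scheme coarse-grained network with the autocatalytic feedback.

    The disassembly of APC/C:MCC is catalysed by free APC/C (the feedback) and,
    by default, additionally proportional to the attached-kinetochore count —
    the variant consistent with the total-MCC balance used by the switch
    analysis.  ``degrading_species`` names the species that degrades Securin
    (free APC/C by default; the coarse-grained reactions never form an
    APC/C:Cdc20 complex).
    """
    p = params
    if degrading_species not in REDUCED_SPECIES:
        raise ConfigurationError(
            f"degrading_species {degrading_species!r} not in reduced model")
    init = {
        "Kin_U": float(p.n_kinetochores), "Kin_A": 0.0,
        "Mad2": p.Mad2_reduced, "MCC": p.MCC_reduced,
        "APC/C": p.APC, "APC/C:MCC": 0.0, "Securin": p.Securin,
    }
    roles = dict(_ROLES)
    roles["APC/C:MCC"] = "inhibitor"
    species = [Species(n, roles.get(n, "neutral"), init[n])
               for n in REDUCED_SPECIES]
    feedback_mods = ("APC/C", "Kin_A") if include_kina_in_feedback \
        else ("APC/C",)
    R = Reaction
    reactions = [
        R("M1", ("Kin_U",), ("Kin_A",), "k_attach"),
        R("M2", ("Mad2",), ("MCC",), "kM1", modifiers=("Kin_U",)),
        R("M3", ("MCC", "APC/C"), ("APC/C:MCC",), "kM2",
          reverse_rate_symbol="k_mM2"),
        R("M4", ("APC/C:MCC",), ("APC/C", "Mad2"), "kM3",
          modifiers=feedback_mods),
        R("M5", (degrading_species, "Securin"), (degrading_species,), "kD"),
    ]
    return ReactionNetwork("reduced", species, reactions, params)


# ------------------------------------------------------------------ analysis
def ode_rhs(network: ReactionNetwork, state: np.ndarray) -> np.ndarray:
    """Time derivative of every species under mass-action kinetics.

    Raises ``ValueError`` for negative state entries.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (len(network.species),):
        raise ValueError(
            f"state length {state.shape} does not match species count "
            f"{len(network.species)}")
    if np.any(state < 0):
        bad = network.species_names[int(np.argmin(state))]
        raise ValueError(f"negative concentration for {bad}")
    return network.rhs(state)


def conservation_totals(network: ReactionNetwork, state: np.ndarray) -> dict:
    """Totals of the conserved cores at ``state``.

    Full model: total APC/C, Cdc20, BubR1:Bub3 and (non-increasing) Mad2 over
    all complexes, plus Kin_U + Kin_A.  Reduced model: APCT, MadT, MCCT and
    the kinetochore count.
    """
    state = np.asarray(state, dtype=float)
    g = lambda n: state[network.index[n]]
    if network.name == "full":
        totals = {"kinetochores": g("Kin_U") + g("Kin_A")}
        for core, label in (("apc", "APC/C"), ("cdc20", "Cdc20"),
                            ("bub", "BubR1:Bub3"), ("mad2", "Mad2")):
            totals[label] = float(sum(
                _COMPOSITION[n].get(core, 0) * g(n)
                for n in network.species_names))
        return totals
    return {
        "kinetochores": g("Kin_U") + g("Kin_A"),
        "APC/C": float(g("APC/C") + g("APC/C:MCC")),
        "Mad2": float(g("Mad2") + g("MCC") + g("APC/C:MCC")),
        "MCC": float(g("MCC") + g("APC/C:MCC")),
    }
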