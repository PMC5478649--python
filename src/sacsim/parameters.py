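"""Rate constants and initial concentrations for the SAC models.

Every rate symbol used anywhere in the package lives in :class:`ParameterSet`.
Units: first-order rates in 1/s, second-order rates in 1/(uM*s), concentrations
in uM.  Kinetochore counts are dimensionless multipliers, so a rate such as
``k3`` ("per unattached kinetochore") keeps units of 1/s.

The bundled reference set (:func:`reference_parameters`) encodes the study
conditions: initial concentrations from the human-SAC modelling literature
(Cdc20 the most abundant species), the kinetochore-mediated O-Mad2 -> C-Mad2
turnover at its 0.016/s ceiling, Mad2 stripping below its 0.015/s ceiling, and
the remaining rates calibrated once so that the unperturbed run shows the
canonical sequence: fast MCC burst, steady decline during attachment, full
APC/C:Cdc20 activation shortly after the last kinetochore attaches.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

__all__ = [
    "ParameterSet",
    "ConfigurationError",
    "reference_parameters",
    "K3_CEILING",
    "STRIP_CEILING",
]

#: Maximal kinetochore-mediated O-Mad2 turnover rate per kinetochore (1/s).
K3_CEILING = 0.016
#: Maximal Mad2-stripping rate per attached kinetochore (1/s).
STRIP_CEILING = 0.015


class ConfigurationError(ValueError):
    """A parameter/configuration problem, naming the offending symbol."""


# Rates are grouped by the reaction they drive; "m" prefixes mark reverse
# (minus) rate constants, e.g. ``k_m2`` is the dissociation partner of ``k2``.
_RATE_FIELDS = (
    "k_attach",
    "k1", "k_m1", "kD",
    "k2", "k_m2",
    "k3", "k_m3",
    "k4", "k_m4",
    "k5", "k_m5",
    "k6", "k_m6",
    "k7", "k_m7",
    "k8", "k9", "k10",
    "kM1", "kM2", "k_mM2", "kM3",
)

_CONC_FIELDS = (
    "APC", "Cdc20", "Securin", "CyclinB",
    "OMad2", "CMad2", "BubR1Bub3",
    "Mad2_reduced", "MCC_reduced",
)


@dataclass(frozen=True)
class ParameterSet:
    """The single home of every rate symbol and initial concentration.

    Attributes
    ----------
    k_attach : float
        Kinetochore attachment rate per unattached kinetochore (1/s); also the
        literal rate of the spontaneous free-Mad2 decay reaction.
    k1, k_m1 : float
        APC/C + Cdc20 binding / dissociation.
    kD : float
        Securin / CyclinB degradation by APC/C:Cdc20 (1/(uM*s)).
    k2, k_m2 : float
        MCC binding to APC/C and to APC/C:Cdc20.
    k3, k_m3 : float
        O-Mad2 <-> C-Mad2 turnover; forward rate is per unattached kinetochore.
    k4, k_m4 : float
        C-Mad2 capture of Cdc20 (irreversible on free Cdc20) and the reversible
        C-Mad2 capture on APC/C:Cdc20.
    k5, k_m5 : float
        BubR1:Bub3 recruitment completing (APC/C-bound) MCC.
    k6, k_m6 : float
        Direct, slow O-Mad2 + Cdc20 association.
    k7, k_m7 : float
        Direct BCC formation (Cdc20 + BubR1:Bub3).
    k8, k9 : float
        Mad2 stripping from APC/C:MCC resp. APC/C:Cdc20:MCC, per attached
        kinetochore (the implicit p31comet/UbcH10 channel).
    k10 : float
        APC/C:BCC decay into active APC/C:Cdc20.
    kM1, kM2, k_mM2, kM3 : float
        Coarse-grained model: kinetochore-mediated MCC formation (per
        unattached kinetochore), MCC/APC/C binding, and the autocatalytic
        APC/C-mediated disassembly of APC/C:MCC (1/(uM*s)).
    APC ... BubR1Bub3 : float
        Initial concentrations of the basic species (uM); complexes start at 0.
    Mad2_reduced, MCC_reduced : float
        Initial free Mad2 and MCC of the coarse-grained model.
    n_kinetochores : int
        92 for a human mitotic cell.
    mad2_decay_pools : str
        Which free Mad2 pools the spontaneous decay acts on: "both" or "open".
    """

    k_attach: float = 0.0058
    k1: float = 0.047
    k_m1: float = 3.2e-4
    kD: float = 0.1
    k2: float = 24.0
    k_m2: float = 3.8e-4
    k3: float = 0.016
    k_m3: float = 0.0027
    k4: float = 0.28
    k_m4: float = 0.014
    k5: float = 8.5
    k_m5: float = 0.001
    k6: float = 0.0035
    k_m6: float = 0.019
    k7: float = 0.094
    k_m7: float = 0.0127
    k8: float = 1.5e-4
    k9: float = 3.0e-4
    k10: float = 0.0068
    kM1: float = 0.016
    kM2: float = 24.0
    k_mM2: float = 5.0e-4
    kM3: float = 0.02

    APC: float = 0.09
    Cdc20: float = 0.22
    Securin: float = 0.2
    CyclinB: float = 0.2
    OMad2: float = 0.15
    CMad2: float = 0.0
    BubR1Bub3: float = 0.13
    Mad2_reduced: float = 0.15
    MCC_reduced: float = 0.0

    n_kinetochores: int = 92
    mad2_decay_pools: str = "open"

    # ------------------------------------------------------------------ API
    @property
    def km(self) -> float:
        """Effective Michaelis-like constant of the coarse-grained binding,
        (k_mM2 + kM3) / kM2 in uM (the linearised removal of the closed form)."""
        return (self.k_mM2 + self.kM3) / self.kM2

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the named symbols changed."""
        for key in changes:
            if key not in {f.name for f in fields(self)}:
                raise ConfigurationError(f"unknown parameter symbol: {key!r}")
        return dataclasses.replace(self, **changes)

    def validate(self, allow_out_of_range: bool = False) -> "ParameterSet":
        """Check sign constraints and the in-text rate ceilings.

        Raises :class:`ConfigurationError` naming the first offending symbol.
        With ``allow_out_of_range`` the ceilings (k3 <= 0.016/s, k8/k9 <=
        0.015/s) and the stability ordering are skipped, for parameter sweeps
        that deliberately cross them.
        """
        for f in _RATE_FIELDS:
            if getattr(self, f) < 0:
                raise ConfigurationError(f"rate {f} must be >= 0")
        for f in _CONC_FIELDS:
            if getattr(self, f) < 0:
                raise ConfigurationError(f"concentration {f} must be >= 0")
        if self.n_kinetochores < 0:
            raise ConfigurationError("n_kinetochores must be >= 0")
        if self.mad2_decay_pools not in ("both", "open"):
            raise ConfigurationError(
                "mad2_decay_pools must be 'both' or 'open'")
        if not allow_out_of_range:
            if self.k3 > K3_CEILING:
                raise ConfigurationError(
                    f"k3 = {self.k3} exceeds the {K3_CEILING}/s per-kinetochore "
                    "ceiling (pass allow_out_of_range to override)")
            if self.k8 > STRIP_CEILING or self.k9 > STRIP_CEILING:
                raise ConfigurationError(
                    f"k8/k9 must not exceed {STRIP_CEILING}/s "
                    "(pass allow_out_of_range to override)")
            # MCC-containing complexes must outlive BCC-containing ones.
            if not (self.k_m5 < self.k_m7 and self.k_m2 < self.k10):
                raise ConfigurationError(
                    "stability ordering violated: need k_m5 < k_m7 and "
                    "k_m2 < k10 (MCC more stable than BCC)")
            basics = {f: getattr(self, f)
                      for f in ("APC", "Securin", "CyclinB", "OMad2",
                                "CMad2", "BubR1Bub3")}
            worst = max(basics, key=basics.get)
            if self.Cdc20 < basics[worst]:
                raise ConfigurationError(
                    f"Cdc20 must be the most abundant basic species "
                    f"(Cdc20 = {self.Cdc20} < {worst} = {basics[worst]})")
        return self

    # -------------------------------------------------------------- IO
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict, *, allow_out_of_range: bool = False,
                  base: "ParameterSet | None" = None) -> "ParameterSet":
        """Build from a (possibly partial) mapping of symbol -> value.

        Unknown keys raise :class:`ConfigurationError`.  ``base`` supplies the
        defaults (the reference fixture if omitted).
        """
        base = base if base is not None else cls()
        ps = base.replace(**d)
        return ps.validate(allow_out_of_range=allow_out_of_range)

    def hash(self) -> str:
        """Stable hexadecimal digest of the full parameter set (provenance)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def reference_parameters() -> ParameterSet:
    """The bundled, versioned reference parameter set (see module docstring)."""
    return ParameterSet().validate()
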