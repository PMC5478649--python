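"""Coarse Brownian-dynamics particle simulation of the full SAC network.

The engine tests whether spatial structure matters for checkpoint behaviour:
all molecular species are spheres of homogeneous density (radius from
molecular mass, diffusion coefficient from the Stokes-Einstein 1/radius
form) moving by free Brownian motion in a spherical reaction volume, with
the 92 kinetochores as fixed spheres on a central metaphase plate.

Reactions follow the Doi model: a bimolecular rule fires with propensity
``lam`` while the pair is closer than the sum of the interaction radii; the
per-contact propensity is obtained by inverting the Erban-Chapman relation

    k = 4*pi*D*R * (1 - tanh(q)/q),    q = R*sqrt(lam/D)

so that the well-mixed limit reproduces the requested mass-action rate
constant even when the pair is partially diffusion-limited.  Unimolecular
reactions fire spontaneously.  Kinetochores act through space alone: any
O-Mad2 particle entering an unattached kinetochore region converts to
C-Mad2 with probability one, and attached kinetochores apply the two
Mad2-stripping rules inside an enlarged interaction radius.

Scale: the default configuration holds physiological concentrations in a
reaction volume about 100-fold smaller than the kinetochore-proximal region
of a mitotic cell, i.e. 1/100 of the physiological copy numbers.  Because
concentrations (not rates) are preserved, the matched mean-field model is
the ordinary ODE system itself, with the kinetochore-mediated rates
replaced by their geometry-determined effective values (see
:func:`calibrate_kinetochore_rates` / :func:`matched_parameters`).
Interaction radii are deliberately inflated relative to physical protein
sizes; this, not a rescaled time axis, is what makes desk-scale run times
possible, and it is calibrated out by the rate inversion above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .network import FULL_SPECIES, ReactionNetwork, build_full_network
from .parameters import ConfigurationError, ParameterSet
from .simulate import TimeCourse, attachment_schedule

__all__ = [
    "ParticleSpecies",
    "SpatialConfig",
    "init_particles",
    "step",
    "run_spatial",
    "calibrate_kinetochore_rates",
    "matched_parameters",
    "matched_mean_field",
    "spatial_reference_parameters",
    "doi_rate_inversion",
    "UM_PER_COUNT",
]

#: copies per (uM * nm^3): 1 uM = 6.02214e-7 / nm^3
_COPIES_PER_UM_NM3 = 6.02214e-7
#: uM s^-1 rate constant in nm^3 s^-1
_NM3_PER_UM = 1.0 / _COPIES_PER_UM_NM3

# approximate molecular masses in kDa (complex = sum of parts)
MASSES = {
    "APC/C": 1220.0, "Cdc20": 55.0, "APC/C:Cdc20": 1275.0,
    "Securin": 22.0, "CyclinB": 48.0,
    "O-Mad2": 24.0, "C-Mad2": 24.0, "C-Mad2:Cdc20": 79.0,
    "BubR1:Bub3": 160.0, "MCC": 239.0, "BCC": 215.0,
    "APC/C:MCC": 1459.0, "APC/C:Cdc20:C-Mad2": 1299.0,
    "APC/C:BCC": 1435.0, "APC/C:Cdc20:MCC": 1514.0,
}

MOLECULAR_SPECIES = tuple(n for n in FULL_SPECIES
                          if n not in ("Kin_U", "Kin_A"))


@dataclass(frozen=True)
class ParticleSpecies:
    """A diffusing species: homogeneous-density sphere of the given mass."""

    name: str
    molecular_mass: float       # kDa
    radius: float               # nm, r_ref * (m / m_ref)^(1/3)
    diffusion_coefficient: float  # nm^2/s, D_ref * r_ref / r
    copy_number: int

    def __post_init__(self):
        if self.copy_number < 0:
            raise ConfigurationError("copy_number must be >= 0")


def _plate_positions(n: int, ring_radius: float, z_offset: float
                     ) -> np.ndarray:
    """Two back-to-back rings of n/2 kinetochores on the metaphase plate."""
    half = n // 2
    ang = 2 * np.pi * np.arange(half) / half
    ring = np.stack([ring_radius * np.cos(ang),
                     ring_radius * np.sin(ang)], axis=1)
    top = np.column_stack([ring, np.full(half, z_offset)])
    bottom = np.column_stack([ring, np.full(n - half, -z_offset)])
    # stagger the second ring by half a spacing
    rot = np.pi / half
    c, s = np.cos(rot), np.sin(rot)
    bottom[:, :2] = bottom[:, :2] @ np.array([[c, -s], [s, c]]).T
    return np.vstack([top, bottom])


@dataclass
class SpatialConfig:
    """Geometry, particle scaling and stepping of the particle engine.

    Defaults emulate the kinetochore-proximal region of a mitotic cell at
    1/100 copy-number scale; they are plausible placeholders, not measured
    values, and everything is overridable.
    """

    volume_radius: float = 570.0          # nm (sphere, ~0.78e9 nm^3)
    kinetochore_radius: float = 25.0      # nm (conversion region, unattached)
    attached_interaction_radius: float = 150.0  # nm (silencing region)
    ring_radius: float = 420.0            # nm, metaphase-plate ring
    plate_offset: float = 60.0            # nm, half-distance between rings
    timestep: float = 0.1                 # s
    r_ref: float = 40.0                   # nm at mass_ref (inflated, see doc)
    mass_ref: float = 100.0               # kDa
    d_ref: float = 2.5e3                  # nm^2/s at r_ref
    copy_scale: float = 1.0               # reduction factor on copy numbers
    output_every: int = 25                # steps between recorded frames
    kinetochore_positions: np.ndarray | None = None

    def __post_init__(self):
        if self.attached_interaction_radius < self.kinetochore_radius:
            raise ConfigurationError(
                "attached_interaction_radius must be >= kinetochore_radius")
        if self.kinetochore_positions is None:
            self.kinetochore_positions = _plate_positions(
                92, self.ring_radius, self.plate_offset)
        kp = np.asarray(self.kinetochore_positions, dtype=float)
        if np.any(np.linalg.norm(kp, axis=1)
                  > self.volume_radius - self.kinetochore_radius):
            raise ConfigurationError("kinetochores must lie inside the volume")
        d = np.linalg.norm(kp[:, None] - kp[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 2 * self.kinetochore_radius:
            raise ConfigurationError("kinetochores overlap")
        self.kinetochore_positions = kp

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.volume_radius ** 3

    def species_table(self, params: ParameterSet) -> dict:
        """name -> ParticleSpecies with copy numbers from the concentrations."""
        init = {
            "APC/C": params.APC, "Cdc20": params.Cdc20,
            "Securin": params.Securin, "CyclinB": params.CyclinB,
            "O-Mad2": params.OMad2, "C-Mad2": params.CMad2,
            "BubR1:Bub3": params.BubR1Bub3,
        }
        out = {}
        for name in MOLECULAR_SPECIES:
            m = MASSES[name]
            r = self.r_ref * (m / self.mass_ref) ** (1.0 / 3.0)
            d = self.d_ref * self.r_ref / r
            conc = init.get(name, 0.0)
            copies = int(round(conc * self.volume * _COPIES_PER_UM_NM3
                               * self.copy_scale))
            out[name] = ParticleSpecies(name, m, r, d, copies)
        return out


def doi_rate_inversion(k_um: float, R: float, D_rel: float) -> float:
    """Per-contact propensity lam (1/s) whose Doi-model steady state
    reproduces the mass-action rate ``k_um`` (1/(uM*s)).

    Inverts k = 4*pi*D*R*(1 - tanh(q)/q) with q = R*sqrt(lam/D); raises if
    ``k_um`` exceeds the diffusion-limited ceiling 4*pi*D*R.
    """
    if k_um < 0:
        raise ConfigurationError("rate constant must be >= 0")
    if k_um == 0:
        return 0.0
    k = k_um * _NM3_PER_UM
    k_smol = 4.0 * np.pi * D_rel * R
    if k >= 0.98 * k_smol:
        raise ConfigurationError(
            f"rate {k_um} 1/(uM*s) is diffusion-limited for R={R:.0f} nm, "
            f"D={D_rel:.0f} nm^2/s (ceiling {0.98 * k_smol / _NM3_PER_UM:.2f})")

    def f(log_lam):
        lam = math.exp(log_lam)
        q = R * math.sqrt(lam / D_rel)
        return 4.0 * np.pi * D_rel * R * (1.0 - math.tanh(q) / q) - k

    lo, hi = -20.0, 20.0
    while f(hi) < 0 and hi < 60:
        hi += 10
    return math.exp(brentq(f, lo, hi, xtol=1e-12))


class _Engine:
    """Compiled particle system for one (config, params) pair."""

    def __init__(self, config: SpatialConfig, params: ParameterSet):
        self.config = config
        self.params = params
        self.species = config.species_table(params)
        self.names = list(MOLECULAR_SPECIES)
        self.sindex = {n: i for i, n in enumerate(self.names)}
        self.radii = np.array([self.species[n].radius for n in self.names])
        self.D = np.array([self.species[n].diffusion_coefficient
                           for n in self.names])
        self._compile_rules()
        dt = config.timestep
        # tunnelling guard: a particle's RMS step must stay below the
        # smallest bimolecular interaction radius
        rms = np.sqrt(6.0 * self.D.max() * dt)
        if self.pair_R.size and rms >= self.pair_R.min():
            raise ConfigurationError(
                f"timestep {dt} s gives RMS displacement {rms:.0f} nm, not "
                f"below the smallest interaction radius "
                f"{self.pair_R.min():.0f} nm")

    # ------------------------------------------------------------- rules
    def _compile_rules(self):
        net = build_full_network(self.params.replace())
        self.uni = {}      # species idx -> list of (rate, product idx tuple)
        pair_rules = {}    # (i,j) sorted -> (lam, products)
        for r in net.reactions:
            if "Kin" in "".join(r.educts):
                continue
            steps = [(r.rate_symbol, r.educts, r.products, bool(r.modifiers))]
            if r.reversible:
                steps.append((r.reverse_rate_symbol, r.products, r.educts,
                              False))
            for sym, educts, products, modified in steps:
                k = getattr(self.params, sym)
                if modified:         # kinetochore-mediated: handled spatially
                    continue
                prods = tuple(self.sindex[p] for p in products)
                if len(educts) == 1:
                    self.uni.setdefault(self.sindex[educts[0]], []).append(
                        (k, prods))
                else:
                    i, j = sorted(self.sindex[e] for e in educts)
                    R = self.radii[i] + self.radii[j]
                    lam = doi_rate_inversion(k, R, self.D[i] + self.D[j])
                    pair_rules[(i, j)] = (lam, R, prods)
        self.pair_rules = pair_rules
        self.pair_R = np.array([v[1] for v in pair_rules.values()]) \
            if pair_rules else np.array([])
        # dense lookup tables for the vectorised pair stage
        S = len(self.names)
        self.rule_id = np.full(S * S, -1, np.int32)
        self.rule_lam = np.zeros(len(pair_rules))
        self.rule_R2 = np.zeros(len(pair_rules))
        self.rule_prods = []
        for rid, ((i, j), (lam, R, prods)) in enumerate(pair_rules.items()):
            self.rule_id[i * S + j] = rid
            self.rule_id[j * S + i] = rid
            self.rule_lam[rid] = lam
            self.rule_R2[rid] = R * R
            self.rule_prods.append(prods)
        # kinetochore-mediated channels
        V = self.config.volume
        Ra = self.config.attached_interaction_radius
        vol_a = 4.0 / 3.0 * np.pi * Ra ** 3
        # reaction 17/18 rates are "per attached kinetochore" first-order
        # constants; the in-region propensity that reproduces k8 in the
        # well-mixed limit is k8 * V / v_region
        self.lam_strip = {
            self.sindex["APC/C:MCC"]:
                (self.params.k8 * V / vol_a,
                 (self.sindex["APC/C:BCC"], self.sindex["O-Mad2"])),
            self.sindex["APC/C:Cdc20:MCC"]:
                (self.params.k9 * V / vol_a,
                 (self.sindex["APC/C:BCC"], self.sindex["O-Mad2"],
                  self.sindex["Cdc20"])),
        }

    # ------------------------------------------------------------- state
    def init_state(self, rng) -> dict:
        cfg = self.config
        counts = [self.species[n].copy_number for n in self.names]
        total = sum(counts)
        if total == 0:
            raise ConfigurationError("no particles to place")
        # rough packing feasibility check with a quarter-radius hard core
        core = self.radii / 4.0
        if np.sum(4 / 3 * np.pi * (core ** 3)[np.repeat(
                np.arange(len(counts)), counts)]) > 0.3 * cfg.volume:
            raise ConfigurationError("volume too small for the population")
        sp = np.repeat(np.arange(len(counts)), counts)
        pos = np.empty((total, 3))
        placed = 0
        tree_pts = []
        while placed < total:
            cand = rng.normal(size=3)
            cand = cand / np.linalg.norm(cand) \
                * cfg.volume_radius * rng.random() ** (1 / 3)
            ok = True
            if tree_pts:
                d = np.linalg.norm(np.array(tree_pts[-200:]) - cand, axis=1)
                if np.any(d < core[sp[placed]]):
                    ok = False
            if ok:
                pos[placed] = cand
                tree_pts.append(cand)
                placed += 1
        return {"pos": pos, "sp": sp.astype(np.int32),
                "alive": np.ones(total, bool)}


def init_particles(config: SpatialConfig, params: ParameterSet,
                   seed: int) -> dict:
    """Seeded uniform non-overlapping placement of the scaled population.

    Returns a state dict with positions (nm), species indices, and the alive
    mask, plus the engine that owns the compiled rules.
    """
    eng = _Engine(config, params)
    rng = np.random.default_rng(seed)
    state = eng.init_state(rng)
    state["engine"] = eng
    state["attached"] = np.zeros(len(config.kinetochore_positions), bool)
    return state


def _spawn(state, idx, products, eng, jitter, rng, scatter=False):
    """Replace particle idx by the product list (first reuses the slot).

    With ``scatter`` the extra products are placed uniformly in the volume
    instead of at the parent position; the stripping channel uses this to
    emulate the rapid poleward streaming of Mad2 ejected at attached
    kinetochores (stripped material does not linger at the plate).
    """
    pos = state["pos"][idx]
    state["sp"][idx] = products[0]
    extra = products[1:]
    if extra:
        if scatter:
            R = state["engine"].config.volume_radius
            npos = rng.normal(size=(len(extra), 3))
            npos *= (R * rng.random(len(extra)) ** (1 / 3)
                     / np.linalg.norm(npos, axis=1))[:, None]
        else:
            # place each co-product just outside the binding radius of any
            # rule it shares with the first product, so that dissociation is
            # not immediately undone by geminate rebinding
            npos = np.empty((len(extra), 3))
            S = len(eng.names)
            for n, prod in enumerate(extra):
                rid = eng.rule_id[products[0] * S + prod]
                dist = 1.1 * math.sqrt(eng.rule_R2[rid]) if rid >= 0 \
                    else jitter
                u = rng.normal(size=3)
                npos[n] = pos + u * (dist / np.linalg.norm(u))
        state["pos"] = np.vstack([state["pos"], npos])
        state["sp"] = np.concatenate([state["sp"], np.array(extra,
                                                            np.int32)])
        state["alive"] = np.concatenate([state["alive"],
                                         np.ones(len(extra), bool)])


def step(state: dict, config: SpatialConfig, rng) -> dict:
    """Advance one timestep: Brownian displacement with boundary reflection,
    spontaneous unimolecular events, kinetochore conversion/stripping, and
    Doi-model bimolecular reactions (one reaction per particle per step)."""
    eng: _Engine = state["engine"]
    dt = config.timestep
    alive = state["alive"]
    idx_alive = np.flatnonzero(alive)
    pos = state["pos"]
    sp = state["sp"]

    # 1. diffusion + radial reflection at the sphere boundary
    sigma = np.sqrt(2.0 * eng.D[sp[idx_alive]] * dt)
    pos[idx_alive] += rng.normal(size=(idx_alive.size, 3)) * sigma[:, None]
    rad = np.linalg.norm(pos[idx_alive], axis=1)
    out = rad > config.volume_radius
    if out.any():
        ii = idx_alive[out]
        r = rad[out]
        pos[ii] *= ((2 * config.volume_radius - r) / r)[:, None]

    used = np.zeros(len(sp), bool)
    used[~alive] = True

    # 2. unimolecular events
    for sidx, channels in eng.uni.items():
        cand = np.flatnonzero((sp == sidx) & alive & ~used)
        if cand.size == 0:
            continue
        ktot = sum(k for k, _ in channels)
        fire = cand[rng.random(cand.size) < -np.expm1(-ktot * dt) * 1.0]
        for i in fire:
            u = rng.random() * ktot
            acc = 0.0
            for k, prods in channels:
                acc += k
                if u <= acc:
                    if prods:
                        _spawn(state, i, prods, eng, 2.0, rng)
                    else:
                        state["alive"][i] = False
                    used = np.resize(used, len(state["sp"]))
                    used[i] = True
                    break
        sp = state["sp"]
        alive = state["alive"]
        pos = state["pos"]
        used = np.resize(used, len(sp))

    # 3. kinetochore channels
    kt = config.kinetochore_positions
    att = state["attached"]
    ktree = cKDTree(kt)
    # O-Mad2 -> C-Mad2 at unattached kinetochores, probability 1 on contact
    o_idx = np.flatnonzero((sp == eng.sindex["O-Mad2"]) & alive & ~used)
    if o_idx.size:
        R_conv = config.kinetochore_radius + eng.radii[eng.sindex["O-Mad2"]]
        near = ktree.query_ball_point(pos[o_idx], R_conv)
        for i, ks in zip(o_idx, near):
            if any(not att[k] for k in ks):
                sp[i] = eng.sindex["C-Mad2"]
                used[i] = True
    # Mad2 stripping inside the enlarged radius of attached kinetochores
    if att.any():
        for sidx, (lam, prods) in eng.lam_strip.items():
            c_idx = np.flatnonzero((sp == sidx) & alive & ~used)
            if c_idx.size == 0:
                continue
            R_str = config.attached_interaction_radius
            near = ktree.query_ball_point(pos[c_idx], R_str)
            p = -np.expm1(-lam * dt)
            for i, ks in zip(c_idx, near):
                n_att = sum(1 for k in ks if att[k])
                if n_att and rng.random() < 1 - (1 - p) ** n_att:
                    _spawn(state, i, prods, eng, 2.0, rng, scatter=True)
                    used = np.resize(used, len(state["sp"]))
                    used[i] = True
            sp = state["sp"]
            alive = state["alive"]
            pos = state["pos"]
            used = np.resize(used, len(sp))

    # 4. bimolecular Doi reactions (vectorised pair filter, then conflict
    # resolution over the few accepted events)
    if eng.pair_rules:
        live = np.flatnonzero(alive)
        tree = cKDTree(pos[live])
        pairs = tree.query_pairs(float(eng.pair_R.max()),
                                 output_type="ndarray")
        if pairs.size:
            S = len(eng.names)
            gi, gj = live[pairs[:, 0]], live[pairs[:, 1]]
            rid = eng.rule_id[sp[gi] * S + sp[gj]]
            mask = rid >= 0
            if mask.any():
                gi, gj, rid = gi[mask], gj[mask], rid[mask]
                d2 = np.sum((pos[gi] - pos[gj]) ** 2, axis=1)
                mask = d2 <= eng.rule_R2[rid]
                gi, gj, rid = gi[mask], gj[mask], rid[mask]
                acc = rng.random(gi.size) < -np.expm1(-eng.rule_lam[rid] * dt)
                gi, gj, rid = gi[acc], gj[acc], rid[acc]
                order = rng.permutation(gi.size)
                for a in order:
                    i, j, r = gi[a], gj[a], rid[a]
                    if used[i] or used[j]:
                        continue
                    mid = 0.5 * (pos[i] + pos[j])
                    state["pos"][i] = mid
                    _spawn(state, i, eng.rule_prods[r], eng, 2.0, rng)
                    state["alive"][j] = False
                    used = np.resize(used, len(state["sp"]))
                    used[i] = True
                    used[j] = True
    return state


def run_spatial(config: SpatialConfig, params: ParameterSet, t_end: float,
                seed: int) -> TimeCourse:
    """Particle trajectory of the full network; counts per frame converted
    to concentrations (uM) on the scaled volume."""
    state = init_particles(config, params, seed)
    eng: _Engine = state["engine"]
    rng = np.random.default_rng(seed + 1)
    events = attachment_schedule(92, params.k_attach, "hybrid", seed + 2,
                                 t_end)
    dt = config.timestep
    n_steps = int(np.ceil(t_end / dt))
    frames, times = [], []
    conv = 1.0 / (config.volume * _COPIES_PER_UM_NM3 * config.copy_scale)
    ev_ptr = 0
    for s in range(n_steps + 1):
        t = s * dt
        while ev_ptr < len(events) and events[ev_ptr][0] <= t:
            state["attached"][events[ev_ptr][1]] = True
            ev_ptr += 1
        if s % config.output_every == 0 or s == n_steps:
            sp, alive = state["sp"], state["alive"]
            counts = np.bincount(sp[alive], minlength=len(eng.names))
            row = np.empty(len(FULL_SPECIES))
            n_att = int(state["attached"].sum())
            for k, name in enumerate(FULL_SPECIES):
                if name == "Kin_U":
                    row[k] = 92 - n_att
                elif name == "Kin_A":
                    row[k] = n_att
                else:
                    row[k] = counts[eng.sindex[name]] * conv
            frames.append(row)
            times.append(t)
        if s < n_steps:
            step(state, config, rng)
    t_last = events[-1][0] if len(events) == 92 else np.inf
    return TimeCourse(times=np.array(times), values=np.array(frames),
                      species=list(FULL_SPECIES), attachment_events=events,
                      t_last_attach=t_last, seed=seed,
                      meta={"mode": "spatial",
                            "params_hash": params.hash()})


def calibrate_kinetochore_rates(config: SpatialConfig, params: ParameterSet,
                                n_tracers: int = 80, t_cal: float = 400.0,
                                seed: int = 0) -> dict:
    """Measured effective kinetochore-mediated rates of this geometry.

    Tracer particles diffuse with only the kinetochore channel active; each
    reacting tracer is counted and re-injected uniformly, so the measurement
    runs at the steady state of a spatially uniform source — the regime the
    full run operates in, where the reacting pools are replenished from
    uniformly distributed precursors.  Returns per-kinetochore first-order
    constants ``k3_eff`` (O-Mad2 conversion at unattached kinetochores) and
    ``k8_eff`` (stripping inside the attached interaction radius).
    """
    out = {}
    zero = {k: 0.0 for k in ("k1", "k_m1", "kD", "k2", "k_m2", "k_m3",
                             "k4", "k_m4", "k5", "k_m5", "k6", "k_m6",
                             "k7", "k_m7", "k10", "k_attach")}
    p0 = params.replace(**zero)
    for which in ("k3", "k3_crowded", "k8"):
        state = init_particles(config, p0, seed + 17)
        eng = state["engine"]
        rng = np.random.default_rng(seed + 18)
        if which == "k3":
            # a few well-separated unattached kinetochores: near-isolated
            # per-kinetochore conversion rate (late-attachment regime)
            tracer = eng.sindex["O-Mad2"]
            state["attached"][:] = True
            n_kt = len(config.kinetochore_positions)
            sparse = np.linspace(0, n_kt, 6, endpoint=False).astype(int)
            state["attached"][sparse] = False
        elif which == "k3_crowded":
            # all kinetochores unattached: the regions compete for tracers,
            # giving the depressed per-kinetochore rate of early prometaphase
            tracer = eng.sindex["O-Mad2"]
            state["attached"][:] = False
        else:
            tracer = eng.sindex["APC/C:MCC"]
            state["attached"][:] = True
        state["sp"][:] = tracer
        keep = min(n_tracers, len(state["sp"]))
        state["alive"][keep:] = False
        dt = config.timestep
        n_steps = int(t_cal / dt)
        burn_in = n_steps // 5
        events = 0
        R = config.volume_radius
        for s_i in range(n_steps):
            step(state, config, rng)
            reacted = np.flatnonzero(state["alive"]
                                     & (state["sp"] != tracer))
            if s_i >= burn_in:
                events += reacted.size
            # uniform re-injection keeps the source spatially flat
            if reacted.size:
                state["sp"] = state["sp"][:len(state["alive"])]
                state["sp"][reacted] = tracer
                npos = rng.normal(size=(reacted.size, 3))
                npos *= (R * rng.random(reacted.size) ** (1 / 3)
                         / np.linalg.norm(npos, axis=1))[:, None]
                state["pos"][reacted] = npos
                # drop any spawned by-products of the counted events
                state["alive"][keep:] = False
        t_meas = (n_steps - burn_in) * dt
        n_active = int((~state["attached"]).sum()) if which != "k8" \
            else len(config.kinetochore_positions)
        out[which + "_eff"] = events / (keep * t_meas * n_active)
    # competition-saturation fit k3(n) = k3_1 / (1 + c*(n-1)) through the
    # sparse (n=6) and crowded (n=92) measurements
    n_kt = len(config.kinetochore_positions)
    n_sparse = 6
    r = out["k3_eff"] / max(out["k3_crowded_eff"], 1e-30)
    denom = (n_kt - 1) - (n_sparse - 1) * r
    c = max((r - 1.0) / denom, 0.0) if denom > 0 else 0.0
    out["k3_iso"] = out["k3_eff"] * (1.0 + c * (n_sparse - 1))
    out["competition_c"] = c
    return out


def matched_parameters(config: SpatialConfig, params: ParameterSet,
                       calibration: dict | None = None,
                       seed: int = 0) -> ParameterSet:
    """ParameterSet whose ODE solution is the mean-field limit of the
    particle engine: kinetochore-mediated rates replaced by the calibrated
    effective rates of the configured geometry, initial concentrations
    quantised to the integer copy numbers actually placed."""
    cal = calibration or calibrate_kinetochore_rates(config, params,
                                                     seed=seed)
    table = config.species_table(params)
    conv = 1.0 / (config.volume * _COPIES_PER_UM_NM3 * config.copy_scale)
    k8_eff = cal["k8_eff"]
    k9_eff = k8_eff * (params.k9 / params.k8 if params.k8 > 0 else 1.0)
    return params.replace(
        k3=cal["k3_eff"], k8=k8_eff, k9=k9_eff,
        APC=table["APC/C"].copy_number * conv,
        Cdc20=table["Cdc20"].copy_number * conv,
        Securin=table["Securin"].copy_number * conv,
        CyclinB=table["CyclinB"].copy_number * conv,
        OMad2=table["O-Mad2"].copy_number * conv,
        CMad2=table["C-Mad2"].copy_number * conv,
        BubR1Bub3=table["BubR1:Bub3"].copy_number * conv,
    )


def matched_mean_field(config: SpatialConfig, params: ParameterSet,
                       t_end: float, times: np.ndarray,
                       calibration: dict | None = None,
                       seed: int = 0) -> TimeCourse:
    """Mean-field limit of the particle engine on the given output grid.

    Integrates the full-network ODE with the kinetochore-mediated O-Mad2
    conversion following the calibrated competition-saturation law
    k3(Kin_U) = k3_iso / (1 + c*(Kin_U - 1)) — the measured per-kinetochore
    rate interpolating between the crowded early-prometaphase regime and the
    isolated late regime — and stripping at the calibrated effective rate.
    Attachment is deterministic (continuous Kin_U), matching the ensemble
    mean of the stochastic attachment process.
    """
    from scipy.integrate import solve_ivp

    cal = calibration or calibrate_kinetochore_rates(config, params,
                                                     seed=seed)
    mp = matched_parameters(config, params, calibration=cal)
    net = build_full_network(mp.replace(k3=cal["k3_iso"]))
    iO, iC, iU = (net.index["O-Mad2"], net.index["C-Mad2"],
                  net.index["Kin_U"])
    c = cal["competition_c"]

    def rhs(t, y):
        yc = np.maximum(y, 0.0)
        dy = net.rhs(yc)
        # replace the k3_iso*KinU conversion flux by the saturating law
        kin_u = yc[iU]
        flux_iso = cal["k3_iso"] * kin_u * yc[iO]
        flux_sat = flux_iso / (1.0 + c * max(kin_u - 1.0, 0.0))
        dy[iO] += flux_iso - flux_sat
        dy[iC] -= flux_iso - flux_sat
        return dy

    sol = solve_ivp(rhs, (0.0, t_end), net.initial_state(), method="LSODA",
                    t_eval=times, rtol=1e-8, atol=1e-10)
    values = np.clip(sol.y.T, 0.0, None)
    from .simulate import _t_last_deterministic
    return TimeCourse(times=np.asarray(times), values=values,
                      species=list(net.species_names), attachment_events=[],
                      t_last_attach=_t_last_deterministic(
                          net.n_kinetochores, mp.k_attach),
                      meta={"mode": "matched-mean-field"})


def spatial_reference_parameters() -> ParameterSet:
    """Study conditions of the desk-scale particle runs.

    The reference kinetics with the two strongest binding steps (MCC-APC/C
    capture and BubR1:Bub3 recruitment) slowed to 2 /(uM*s) so that no rule
    exceeds the diffusion-limited ceiling of the coarse particle geometry;
    dissociation constants are preserved.  The matched mean-field model for
    these runs comes from :func:`matched_parameters`.
    """
    p = ParameterSet()
    return p.replace(k2=2.0, k_m2=p.k_m2 * 2.0 / p.k2,
                     k5=2.0, k_m5=p.k_m5 * 2.0 / p.k5)


#: conversion helper exposed for tests: uM per single copy in a config volume
def UM_PER_COUNT(config: SpatialConfig) -> float:
    return 1.0 / (config.volume * _COPIES_PER_UM_NM3 * config.copy_scale)
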