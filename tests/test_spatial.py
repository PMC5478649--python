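"""Particle engine: geometry, rate inversion, Brownian statistics,
kinetochore channels, conservation."""

import numpy as np
import pytest

from sacsim.parameters import ConfigurationError
from sacsim.spatial import (SpatialConfig, UM_PER_COUNT, doi_rate_inversion,
                            init_particles, run_spatial,
                            spatial_reference_parameters, step)

_COPIES_PER_UM_NM3 = 6.02214e-7


@pytest.fixture(scope="module")
def sp_params():
    return spatial_reference_parameters()


@pytest.fixture(scope="module")
def cfg():
    return SpatialConfig()


class TestGeometryAndScaling:
    def test_radius_and_diffusion_laws(self, cfg, sp_params):
        table = cfg.species_table(sp_params)
        a, b = table["APC/C"], table["Cdc20"]
        # homogeneous-density spheres: r ~ m^(1/3)
        assert a.radius / b.radius == pytest.approx(
            (a.molecular_mass / b.molecular_mass) ** (1 / 3))
        # Stokes-Einstein: D ~ 1/r
        assert a.diffusion_coefficient * a.radius == pytest.approx(
            b.diffusion_coefficient * b.radius)

    def test_copy_number_is_avogadro_conversion(self, cfg, sp_params):
        """At reduction factor 1: copies = conc * V * (6.022e-7 / uM nm^3),
        checked by hand for Cdc20."""
        table = cfg.species_table(sp_params)
        by_hand = round(sp_params.Cdc20 * (4 / 3) * np.pi * 570.0 ** 3
                        * _COPIES_PER_UM_NM3)
        assert table["Cdc20"].copy_number == by_hand

    def test_zero_concentration_zero_particles(self, cfg, sp_params):
        table = cfg.species_table(sp_params)
        assert table["MCC"].copy_number == 0

    def test_placement_inside_volume_and_reproducible(self, cfg, sp_params):
        s1 = init_particles(cfg, sp_params, seed=11)
        s2 = init_particles(cfg, sp_params, seed=11)
        assert np.array_equal(s1["pos"], s2["pos"])
        assert int(s1["alive"].sum()) == sum(
            v.copy_number for v in cfg.species_table(sp_params).values())
        assert np.all(np.linalg.norm(s1["pos"], axis=1)
                      <= cfg.volume_radius + 1e-9)

    def test_overlapping_kinetochores_rejected(self):
        kp = np.zeros((2, 3))
        with pytest.raises(ConfigurationError, match="overlap"):
            SpatialConfig(kinetochore_positions=kp)

    def test_oversized_timestep_rejected(self, sp_params):
        cfg = SpatialConfig(timestep=50.0)
        with pytest.raises(ConfigurationError, match="timestep"):
            init_particles(cfg, sp_params, seed=0)


class TestDoiInversion:
    @pytest.mark.parametrize("k_um", [0.01, 0.3, 1.8])
    def test_roundtrip_reproduces_rate(self, k_um):
        R, D = 120.0, 4000.0
        lam = doi_rate_inversion(k_um, R, D)
        q = R * np.sqrt(lam / D)
        k_back = 4 * np.pi * D * R * (1 - np.tanh(q) / q) * 6.02214e-7
        assert k_back == pytest.approx(k_um, rel=1e-9)

    def test_diffusion_limited_rate_rejected(self):
        with pytest.raises(ConfigurationError, match="diffusion-limited"):
            doi_rate_inversion(100.0, 100.0, 3000.0)

    def test_zero_rate(self):
        assert doi_rate_inversion(0.0, 100.0, 3000.0) == 0.0


class TestStep:
    def test_frozen_engine_is_static(self, sp_params):
        p = sp_params.replace(**{k: 0.0 for k in
                                 ("k1", "k_m1", "kD", "k2", "k_m2", "k3",
                                  "k_m3", "k4", "k_m4", "k5", "k_m5", "k6",
                                  "k_m6", "k7", "k_m7", "k8", "k9", "k10",
                                  "k_attach")})
        cfg = SpatialConfig(d_ref=0.0)
        state = init_particles(cfg, p, seed=2)
        pos0 = state["pos"].copy()
        rng = np.random.default_rng(3)
        for _ in range(5):
            step(state, cfg, rng)
        # no diffusion, no unimolecular rates, no pair rules firing
        assert np.array_equal(state["pos"], pos0)
        assert state["alive"].all()

    def test_free_diffusion_msd(self, sp_params):
        """Mean squared displacement of free Brownian particles grows as
        6 D t (checked before boundary reflections bite)."""
        p = sp_params.replace(**{k: 0.0 for k in
                                 ("k1", "k_m1", "kD", "k2", "k_m2", "k3",
                                  "k_m3", "k4", "k_m4", "k5", "k_m5", "k6",
                                  "k_m6", "k7", "k_m7", "k8", "k9", "k10",
                                  "k_attach")},
                             Cdc20=0.22, OMad2=0.0, BubR1Bub3=0.0, APC=0.0,
                             Securin=0.0, CyclinB=0.0)
        cfg = SpatialConfig()
        state = init_particles(cfg, p, seed=4)
        eng = state["engine"]
        D = eng.D[eng.sindex["Cdc20"]]
        rng = np.random.default_rng(5)
        pos0 = state["pos"].copy()
        n_steps = 10
        for _ in range(n_steps):
            step(state, cfg, rng)
        msd = np.mean(np.sum((state["pos"] - pos0) ** 2, axis=1))
        expected = 6 * D * n_steps * cfg.timestep
        assert msd == pytest.approx(expected, rel=0.25)

    def test_omad2_converts_at_unattached_kinetochore(self, sp_params):
        # freeze diffusion (and all chemistry) so that particles placed on
        # kinetochores are guaranteed to still be inside the region when
        # the contact test runs: conversion is probability 1 on contact
        p = sp_params.replace(**{k: 0.0 for k in
                                 ("k1", "k_m1", "kD", "k2", "k_m2", "k_m3",
                                  "k4", "k_m4", "k5", "k_m5", "k6", "k_m6",
                                  "k7", "k_m7", "k8", "k9", "k10",
                                  "k_attach")})
        cfg = SpatialConfig(d_ref=0.0)
        state = init_particles(cfg, p, seed=6)
        eng = state["engine"]
        o_idx = np.flatnonzero(state["sp"] == eng.sindex["O-Mad2"])[:5]
        state["pos"][o_idx] = cfg.kinetochore_positions[:5]
        state["attached"][:] = False
        rng = np.random.default_rng(7)
        step(state, cfg, rng)
        assert np.all(state["sp"][o_idx] == eng.sindex["C-Mad2"])

    def test_no_conversion_at_attached_kinetochore(self, cfg, sp_params):
        p = sp_params.replace(k_m3=0.0, k4=0.0, k6=0.0, k_attach=0.0)
        state = init_particles(cfg, p, seed=6)
        eng = state["engine"]
        o_idx = np.flatnonzero(state["sp"] == eng.sindex["O-Mad2"])
        state["attached"][:] = True
        rng = np.random.default_rng(7)
        step(state, cfg, rng)
        assert np.all(state["sp"][o_idx] == eng.sindex["O-Mad2"])


class TestRunSpatial:
    def test_rates_zero_counts_constant(self, cfg, sp_params):
        p = sp_params.replace(**{k: 0.0 for k in
                                 ("k1", "k_m1", "kD", "k2", "k_m2", "k3",
                                  "k_m3", "k4", "k_m4", "k5", "k_m5", "k6",
                                  "k_m6", "k7", "k_m7", "k8", "k9", "k10",
                                  "k_attach")})
        # kinetochore conversion is geometric (probability 1 on contact),
        # so exclude it by emptying the O-Mad2 pool
        p = p.replace(OMad2=0.0)
        tc = run_spatial(cfg, p, t_end=20.0, seed=8)
        for name in ("Cdc20", "APC/C", "BubR1:Bub3", "Securin"):
            assert np.allclose(tc[name], tc[name][0])

    def test_conservation_of_cores(self, cfg, sp_params):
        """Particle counts obey the same composition bookkeeping as the
        ODE: APC/C, Cdc20, BubR1:Bub3 cores constant, Mad2 non-increasing."""
        from sacsim.network import _COMPOSITION
        tc = run_spatial(cfg, sp_params, t_end=120.0, seed=9)
        um = UM_PER_COUNT(cfg)

        def total(core, i):
            return sum(_COMPOSITION[n].get(core, 0) * tc[n][i]
                       for n in tc.species if n in _COMPOSITION)

        for core in ("apc", "cdc20", "bub"):
            t0, t1 = total(core, 0), total(core, -1)
            assert t1 == pytest.approx(t0, abs=0.6 * um)
        mad = [total("mad2", i) for i in range(len(tc.times))]
        assert mad[-1] <= mad[0] + 0.6 * um
        assert np.all(tc["Kin_U"] + tc["Kin_A"] == 92)
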