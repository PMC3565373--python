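"""Lattice Monte Carlo: energies, enumeration oracle, sampler behavior."""

import math

import numpy as np
import pytest

from memphase.ising_exact import spontaneous_order
from memphase.lattice_mc import LatticeSpec, MCParams, energy, enumerate_exact, metropolis_run


class TestLatticeSpec:
    def test_site_counts_and_area_fraction(self):
        spec = LatticeSpec(L=4, c=1)
        seg = spec.segment_of_sites()
        assert (seg == 0).sum() == 4 and (seg == 1).sum() == 12
        assert spec.q1 == 0.25

    def test_partition_validation(self):
        with pytest.raises(ValueError):
            LatticeSpec(L=4, c=5)
        with pytest.raises(ValueError):
            LatticeSpec(L=1, c=0)

    def test_bond_count_on_torus(self):
        bi, bj = LatticeSpec(L=4, c=2).bond_list()
        assert len(bi) == 2 * 16  # 2N bonds on a periodic square lattice

    def test_excluding_boundary_bonds(self):
        spec = LatticeSpec(L=4, c=2, include_boundary_couplings=False)
        bi, bj = spec.bond_list()
        # two column interfaces x 4 rows = 8 bonds dropped
        assert len(bi) == 2 * 16 - 8
        seg = spec.segment_of_sites()
        assert (seg[bi] == seg[bj]).all()


class TestEnergy:
    def test_all_b_configuration_counts_bb_bonds(self):
        spec = LatticeSpec(L=3, c=0)
        params = MCParams(t_bar=2.0, uaa=-0.5, uab=0.5, ubb=-0.5)
        e = energy(np.zeros(9), spec, params)
        assert e == pytest.approx(18 * -0.5, rel=1e-12)  # 2N bonds, all bb

    def test_single_flip_energy_difference(self):
        """One a-site in the b-background changes 4 bonds bb -> ab and adds
        the field term (dU[m] - dmu)."""
        spec = LatticeSpec(L=4, c=2)
        params = MCParams(t_bar=2.0, dmu=0.3, du1=0.1, du2=-0.7)
        uaa, uab, ubb = params.couplings()
        base = np.zeros(16)
        for site, seg_field in [(0, 0.1 - 0.3), (3, -0.7 - 0.3)]:
            cfg = base.copy()
            cfg[site] = 1
            de = energy(cfg, spec, params) - energy(base, spec, params)
            assert de == pytest.approx(4 * (uab - ubb) + seg_field, rel=1e-12)

    def test_translation_invariance_on_uniform_lattice(self, rng):
        spec = LatticeSpec(L=4, c=0)
        params = MCParams(t_bar=1.7, dmu=0.2)
        cfg = rng.integers(0, 2, 16)
        grid = cfg.reshape(4, 4)
        e0 = energy(cfg, spec, params)
        assert energy(np.roll(grid, 1, 0).ravel(), spec, params) == pytest.approx(e0)
        assert energy(np.roll(grid, 2, 1).ravel(), spec, params) == pytest.approx(e0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            energy(np.zeros(8), LatticeSpec(L=3, c=0), MCParams(t_bar=2.0))


class TestEnumeration:
    def test_entropy_dominated_limit(self):
        res = enumerate_exact(LatticeSpec(L=2, c=1), MCParams(t_bar=1e6))
        assert res["mean_n"] == pytest.approx(0.5, abs=1e-5)

    def test_field_dominated_limit(self):
        res = enumerate_exact(LatticeSpec(L=2, c=1), MCParams(t_bar=2.0, dmu=50.0))
        assert res["mean_n"] == pytest.approx(1.0, abs=1e-6)

    def test_segment_affinity_enriches_a_molecules(self):
        """Negative dU2 (a-molecules sticky in segment 2) raises the
        segment-2 occupation above segment 1 at the transition field."""
        res = enumerate_exact(LatticeSpec(L=3, c=1),
                              MCParams(t_bar=2.0, dmu=0.0, du1=0.0, du2=-2.0))
        n1, n2 = res["mean_n_seg"]
        assert n2 > n1

    def test_particle_hole_duality(self):
        """Mapping dmu -> -dmu, dU -> -dU sends <n> to 1 - <n> exactly."""
        spec = LatticeSpec(L=3, c=2)
        a = enumerate_exact(spec, MCParams(t_bar=2.0, dmu=0.4, du1=0.3, du2=-0.8))
        b = enumerate_exact(spec, MCParams(t_bar=2.0, dmu=-0.4, du1=-0.3, du2=0.8))
        assert a["mean_n"] == pytest.approx(1.0 - b["mean_n"], abs=1e-12)
        for x, y in zip(a["mean_n_seg"], b["mean_n_seg"]):
            assert x == pytest.approx(1.0 - y, abs=1e-12)

    def test_transition_field_is_symmetry_point(self):
        """On a uniform lattice with affinity dU, the order parameter
        vanishes exactly at dmu = mu_alphabeta + dU (= dU here)."""
        spec = LatticeSpec(L=4, c=4)
        du1 = 0.6
        at = enumerate_exact(spec, MCParams(t_bar=2.0, dmu=du1, du1=du1))
        assert at["mean_n"] == pytest.approx(0.5, abs=1e-12)
        below = enumerate_exact(spec, MCParams(t_bar=2.0, dmu=du1 - 0.2, du1=du1))
        above = enumerate_exact(spec, MCParams(t_bar=2.0, dmu=du1 + 0.2, du1=du1))
        assert below["mean_n"] < 0.5 < above["mean_n"]

    def test_site_limit(self):
        with pytest.raises(ValueError):
            enumerate_exact(LatticeSpec(L=5, c=2), MCParams(t_bar=2.0))


class TestMetropolis:
    def test_seeded_runs_identical(self):
        spec = LatticeSpec(L=4, c=2)
        params = MCParams(t_bar=2.0, dmu=0.1, du2=-0.5, sweeps=200, burnin=50, seed=99)
        a = metropolis_run(spec, params)
        b = metropolis_run(spec, params)
        assert a == b

    def test_different_seed_different_trajectory(self):
        spec = LatticeSpec(L=4, c=2)
        a = metropolis_run(spec, MCParams(t_bar=2.0, sweeps=200, burnin=50, seed=1))
        b = metropolis_run(spec, MCParams(t_bar=2.0, sweeps=200, burnin=50, seed=2))
        assert a.mean_n != b.mean_n

    def test_high_temperature_half_occupation(self):
        res = metropolis_run(LatticeSpec(L=8, c=4),
                             MCParams(t_bar=100.0, sweeps=4000, burnin=500, seed=5))
        assert abs(res.mean_n - 0.5) < 3 * res.se_n
        assert 0.4 < res.acceptance_rate <= 1.0

    def test_matches_enumeration_on_tiny_lattice(self):
        spec = LatticeSpec(L=3, c=1)
        params = MCParams(t_bar=2.0, dmu=0.3, du2=-1.0, sweeps=30000, burnin=2000,
                          stride=3, seed=17)
        mc = metropolis_run(spec, params)
        ex = enumerate_exact(spec, params)
        for m, (e, se) in zip(ex["mean_n_seg"], zip(mc.mean_n_seg, mc.se_n_seg)):
            assert abs(e - m) < 3 * se

    def test_ordered_branch_at_weak_field(self):
        """At T_bar = 2 with a +0.01 ordering field the magnetization sits on
        the positive spontaneous branch.  The tolerance allows for the
        linear-response shift chi*H_bar ~ 0.01 of the finite field."""
        spec = LatticeSpec(L=32, c=0)
        params = MCParams(t_bar=2.0, dmu=0.02, sweeps=2000, burnin=500, seed=11)
        res = metropolis_run(spec, params, initial=np.ones(spec.n_sites))
        assert res.magnetization == pytest.approx(spontaneous_order(2.0), abs=0.025)

    def test_validation(self):
        with pytest.raises(ValueError):
            MCParams(t_bar=2.0, sweeps=0)
        with pytest.raises(ValueError):
            MCParams(t_bar=2.0, uaa=-1.0)  # partial raw couplings
        with pytest.raises(ValueError):
            metropolis_run(LatticeSpec(L=3, c=0),
                           MCParams(t_bar=2.0, sweeps=5, stride=5))
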