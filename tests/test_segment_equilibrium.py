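"""Spectator fractions and segment-state classification."""

import numpy as np
import pytest

from memphase.ising_exact import exact_binodals
from memphase.meanfield import mf_binodals
from memphase.segment_equilibrium import (
    COEX_SEGMENT_1,
    COEX_SEGMENT_2,
    ONE_PHASE,
    solve_state,
    spectator_fraction,
)

TBAR = 2.0


class TestSpectatorFraction:
    def test_sign_branches_meanfield(self, mf_eos):
        pair = mf_binodals(TBAR)
        # segment 1 separating, positive contrast: spectator below x_beta
        xs2 = spectator_fraction(1, TBAR, 1.0, mf_eos)
        assert 0.0 < xs2 < pair.x_beta
        # negative contrast: spectator above x_alpha
        xs2n = spectator_fraction(1, TBAR, -1.0, mf_eos)
        assert pair.x_alpha < xs2n < 1.0
        # segment 2 separating flips the sign rule
        xs1 = spectator_fraction(2, TBAR, 1.0, mf_eos)
        assert pair.x_alpha < xs1 < 1.0
        xs1n = spectator_fraction(2, TBAR, -1.0, mf_eos)
        assert 0.0 < xs1n < pair.x_beta

    def test_root_residual_meanfield(self, mf_eos):
        """The returned composition satisfies dG(x) = -dU21 to 1e-10."""
        x = spectator_fraction(2, TBAR, -1.0, mf_eos)
        assert abs(mf_eos.delta_g(x, TBAR, flatten=False) + 1.0) < 1e-10
        x = spectator_fraction(1, TBAR, 2.5, mf_eos)
        assert abs(mf_eos.delta_g(x, TBAR, flatten=False) + 2.5) < 1e-10

    def test_exact_limit_regimes(self, exact_eos):
        pair = exact_binodals(TBAR)
        assert spectator_fraction(1, TBAR, 5.0, exact_eos, regime="large") == 0.0
        assert spectator_fraction(1, TBAR, 5.0, exact_eos, regime="small") == pair.x_beta
        assert spectator_fraction(1, TBAR, -5.0, exact_eos, regime="large") == 1.0
        assert spectator_fraction(1, TBAR, -5.0, exact_eos, regime="small") == pair.x_alpha
        assert spectator_fraction(2, TBAR, -5.0, exact_eos, regime="large") == 0.0
        assert spectator_fraction(2, TBAR, 5.0, exact_eos, regime="large") == 1.0

    def test_monotone_decreasing_in_contrast(self, mf_eos):
        """Spectator composition decreases with contrast on each sign branch."""
        for contrasts in (np.linspace(0.05, 4.0, 12), np.linspace(-4.0, -0.05, 12)):
            xs = [spectator_fraction(1, TBAR, du, mf_eos) for du in contrasts]
            assert np.all(np.diff(xs) < 0)

    def test_jump_across_zero_contrast(self, mf_eos):
        """The spectator composition jumps across the miscibility gap at
        zero contrast: the one-sided limits are the two binodals."""
        pair = mf_binodals(TBAR)
        assert spectator_fraction(1, TBAR, +1e-6, mf_eos) == pytest.approx(pair.x_beta, abs=1e-3)
        assert spectator_fraction(1, TBAR, -1e-6, mf_eos) == pytest.approx(pair.x_alpha, abs=1e-3)

    def test_large_contrast_saturates(self, mf_eos):
        assert spectator_fraction(1, TBAR, 50.0, mf_eos) == pytest.approx(0.0, abs=1e-6)
        assert spectator_fraction(1, TBAR, -50.0, mf_eos) == pytest.approx(1.0, abs=1e-6)

    def test_preconditions(self, mf_eos, exact_eos):
        with pytest.raises(ValueError, match="degenerate|whole-membrane"):
            spectator_fraction(1, TBAR, 0.0, mf_eos)
        with pytest.raises(ValueError, match="Tc"):
            spectator_fraction(1, 5.0, 1.0, mf_eos)
        with pytest.raises(ValueError, match="regime"):
            spectator_fraction(1, TBAR, 1.0, exact_eos)


class TestSolveState:
    def test_zero_contrast_whole_membrane(self, exact_eos):
        st = solve_state(0.5, TBAR, 0.7, 0.0, exact_eos)
        assert st.Xa1 == st.Xa2 == 0.5
        assert st.phase == COEX_SEGMENT_1 and st.whole_membrane

    def test_zero_contrast_one_phase_outside_binodals(self, exact_eos):
        st = solve_state(0.02, TBAR, 0.7, 0.0, exact_eos)
        assert st.phase == ONE_PHASE and not st.whole_membrane

    def test_exact_limit_lever_window(self, exact_eos):
        """Large positive contrast: segment-1 window is the lever-projected
        binodal interval with an empty (Xa2 = 0) bound segment."""
        st = solve_state(0.3, TBAR, 0.7, 5.0, exact_eos, regime="large")
        assert st.phase == COEX_SEGMENT_1
        assert st.Xa2 == 0.0
        assert st.Xa1 == pytest.approx(0.3 / 0.7, rel=1e-12)
        # window endpoints in overall composition (frozen lever arithmetic)
        pair = exact_binodals(TBAR)
        assert 0.7 * pair.x_beta == pytest.approx(0.031038, abs=5e-6)
        assert 0.7 * pair.x_alpha == pytest.approx(0.668962, abs=5e-6)

    def test_partitioning_residual_all_phases(self, mf_eos):
        for xa in (0.05, 0.2, 0.5, 0.69, 0.8, 0.97):
            for du in (-2.0, -0.3, 0.4, 3.0):
                st = solve_state(xa, TBAR, 0.6, du, mf_eos)
                assert abs(st.partitioning_residual) < 1e-10

    def test_one_phase_chemical_equilibrium_residual(self, mf_eos):
        # 0.695 sits in the intermediate one-phase gap between the two
        # segment windows at these parameters
        st = solve_state(0.695, TBAR, 0.7, 1.0, mf_eos)
        assert st.phase == ONE_PHASE
        res = mf_eos.delta_g(st.Xa1, TBAR) - mf_eos.delta_g(st.Xa2, TBAR) - 1.0
        assert abs(res) < 1e-10

    def test_coexistence_interval_membership(self, mf_eos):
        pair = mf_binodals(TBAR)
        st = solve_state(0.3, TBAR, 0.7, 1.0, mf_eos)
        assert st.phase == COEX_SEGMENT_1
        assert pair.x_beta <= st.Xa1 <= pair.x_alpha
        assert st.spectator_segment == 2 and st.Xa2 == st.spectator_x

    def test_spectator_constant_across_window(self, mf_eos):
        """Within the segment-1 window the spectator composition is pinned."""
        specs = [solve_state(xa, TBAR, 0.7, 1.0, mf_eos).Xa2 for xa in (0.1, 0.3, 0.5)]
        assert max(specs) - min(specs) < 1e-12

    def test_mirror_symmetry_under_species_relabel(self, mf_eos):
        """(dU21, Xa) -> (-dU21, 1-Xa) maps states by X -> 1-X."""
        for xa, du in [(0.3, 1.0), (0.72, 1.0), (0.5, -0.5), (0.95, 2.0)]:
            a = solve_state(xa, TBAR, 0.7, du, mf_eos)
            b = solve_state(1.0 - xa, TBAR, 0.7, -du, mf_eos)
            assert a.Xa1 == pytest.approx(1.0 - b.Xa1, abs=1e-9)
            assert a.Xa2 == pytest.approx(1.0 - b.Xa2, abs=1e-9)
            assert (a.phase == ONE_PHASE) == (b.phase == ONE_PHASE)

    def test_no_simultaneous_coexistence(self, mf_eos):
        """For nonzero contrast no overall composition puts both segments
        inside their binodal interval at once."""
        pair = mf_binodals(TBAR)
        for xa in np.linspace(0.01, 0.99, 49):
            st = solve_state(xa, TBAR, 0.55, 0.8, mf_eos)
            in1 = pair.x_beta <= st.Xa1 <= pair.x_alpha
            in2 = pair.x_beta <= st.Xa2 <= pair.x_alpha
            if st.phase == ONE_PHASE:
                assert not (in1 and in2)
            else:
                assert (st.phase == COEX_SEGMENT_1) == in1
                assert (st.phase == COEX_SEGMENT_2) == in2

    def test_degenerate_area_fractions(self, exact_eos):
        st0 = solve_state(0.5, TBAR, 0.0, 3.0, exact_eos, regime="large")
        assert st0.phase == COEX_SEGMENT_2
        st1 = solve_state(0.5, TBAR, 1.0, 3.0, exact_eos, regime="large")
        assert st1.phase == COEX_SEGMENT_1

    def test_supercritical_is_one_phase(self, mf_eos):
        st = solve_state(0.5, 4.5, 0.7, 1.0, mf_eos)
        assert st.phase == ONE_PHASE
        assert abs(st.partitioning_residual) < 1e-10

    def test_input_validation(self, mf_eos):
        with pytest.raises(ValueError):
            solve_state(1.5, TBAR, 0.7, 1.0, mf_eos)
        with pytest.raises(ValueError):
            solve_state(0.5, TBAR, -0.1, 1.0, mf_eos)
        with pytest.raises(ValueError):
            solve_state(float("nan"), TBAR, 0.7, 1.0, mf_eos)
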