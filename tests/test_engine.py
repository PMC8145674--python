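import math

import numpy as np
import pytest

from adhesim import _kernel as K
from adhesim.energetics import total_energy
from adhesim.engine import (
    Simulation,
    make_initial_state,
    mc_step,
    metropolis_accept,
    run_trajectory,
)
from adhesim.lattice import MembraneState, bonds
from adhesim.params import ModelParameters
from conftest import random_state


class TestMetropolis:
    @pytest.mark.parametrize(
        "delta_e, u, expected",
        [
            (-3.0, 0.99, True),
            (0.0, 0.999, True),
            (2.0, 0.13, True),  # exp(-2) = 0.1353 > 0.13
            (2.0, 0.14, False),
            (50.0, 1e-12, False),
        ],
    )
    def test_acceptance_rule(self, delta_e, u, expected):
        assert metropolis_accept(delta_e, u) is expected

    def test_u_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 1.5)


class TestInitialState:
    def test_degenerate_interval_gives_flat_field(self, small_params, rng):
        state = make_initial_state(small_params, (40.0, 40.0), rng)
        assert np.all(state.l == 40.0)

    def test_uniform_interval_and_single_occupancy(self, rng):
        params = ModelParameters(
            lattice_nx=10, lattice_ny=10, n_tcr=20, n_lfa=20,
            n_self_pmhc=20, n_foreign_pmhc=5, n_icam=20,
        )
        state = make_initial_state(params, (14.5, 40.5), rng)
        assert state.l.min() >= 14.5 and state.l.max() <= 40.5
        counts = state.species_counts()
        assert counts == {"TCR": 20, "LFA1": 20, "SMHC": 20, "FMHC": 5, "ICAM1": 20}

    def test_overfull_membrane_rejected(self, rng):
        with pytest.raises(ValueError):
            ModelParameters(lattice_nx=3, lattice_ny=3, n_tcr=10, n_lfa=0,
                            n_self_pmhc=0, n_icam=0)

    def test_run_rejects_mismatched_counts(self, small_params, rng):
        state = make_initial_state(small_params, (14.5, 40.5), rng)
        state.occ1[tuple(np.argwhere(state.occ1 == K.M1_TCR)[0])] = 0  # lose a TCR
        with pytest.raises(ValueError, match="species counts"):
            Simulation(small_params, state)


class TestMoveOutcomes:
    def _clamp_sim(self, l0=15.0, u_self=5.9):
        """One TCR/self-pMHC pair apposed at the centre of a flat 8x8 field."""
        params = ModelParameters(
            lattice_nx=8, lattice_ny=8, u_self=u_self, n_tcr=1, n_lfa=0,
            n_self_pmhc=1, n_foreign_pmhc=0, n_icam=0, dwell_start_step=0,
        )
        l = np.full((8, 8), l0)
        occ1 = np.zeros((8, 8), np.int8)
        occ2 = np.zeros((8, 8), np.int8)
        occ1[4, 4] = K.M1_TCR
        occ2[4, 4] = K.M2_SMHC
        return Simulation(params, MembraneState(l, occ1, occ2), dwell_window=(0, 2**62))

    def test_separation_shift_breaks_bond_uphill(self):
        sim = self._clamp_sim()
        out = sim.attempt_separation_move(patch=(4, 4), delta=0.51, u=0.0)
        assert out.accepted and out.bonds_broken == [((4, 4), K.KIND_TCR_SELF)]
        # breaking the bond costs +U plus the bending of the new bump
        assert out.delta_e > 5.9

    def test_negative_separation_proposal_rejected(self):
        sim = self._clamp_sim(l0=0.2)
        out = sim.attempt_separation_move(patch=(0, 0), delta=-0.4, u=0.0)
        assert not out.accepted and sim.state.l[0, 0] == 0.2

    def test_free_protein_hop_is_free(self):
        sim = self._clamp_sim(l0=40.0)  # pair apposed but far outside the window
        out = sim.attempt_protein_move(protein=0, direction=1, u=0.999999)
        assert out.accepted and out.delta_e == 0.0 and not out.excluded

    def test_bound_hop_into_new_complex_is_excluded(self):
        sim = self._clamp_sim()
        # put a second free pMHC next to the bound TCR's patch
        sim2 = self._clamp_sim()
        state = sim2.state
        state.occ2[3, 4] = K.M2_SMHC
        params = sim2.params.replace(n_self_pmhc=2)
        sim2 = Simulation(params, state, dwell_window=(0, 2**62))
        # TCR (protein index 0) hops "up" onto the patch apposing the free pMHC
        out = sim2.attempt_protein_move(protein=0, direction=0, u=0.0)
        assert out.excluded and not out.accepted
        assert state.occ1[4, 4] == K.M1_TCR  # unchanged

    def test_unbound_hop_into_binding_position_is_downhill(self):
        sim = self._clamp_sim()
        state = sim.state
        # move the TCR off the pMHC first (breaks the bond, u=0 forces accept)
        out = sim.attempt_protein_move(protein=0, direction=0, u=0.0)
        assert out.accepted and out.bonds_broken
        # hopping back re-forms the bond with dE = -U < 0
        back = sim.attempt_protein_move(protein=0, direction=1, u=0.999999)
        assert back.accepted and back.delta_e == pytest.approx(-5.9)
        assert back.bonds_formed == [((4, 4), K.KIND_TCR_SELF)]

    def test_pair_move_preserves_bond_between_in_window_patches(self):
        sim = self._clamp_sim()
        out = sim.attempt_pair_move(pair=(4, 4), direction=3, u=0.999999)
        assert out.accepted and out.delta_e == 0.0 and out.bond_moved
        assert not out.bonds_formed and not out.bonds_broken
        assert bonds(sim.state, sim.params).patches == [(4, 5)]

    def test_pair_move_to_out_of_window_target_costs_u(self):
        sim = self._clamp_sim()
        sim.state.l[4, 5] = 25.0
        out = sim.attempt_pair_move(pair=(4, 4), direction=3, u=0.0)
        assert out.accepted and out.delta_e == pytest.approx(5.9)
        assert out.bonds_broken == [((4, 4), K.KIND_TCR_SELF)]

    def test_pair_move_onto_occupied_target_rejected(self):
        sim = self._clamp_sim()
        sim2_state = sim.state
        sim2_state.occ1[4, 5] = K.M1_TCR  # blocker on membrane 1
        params = sim.params.replace(n_tcr=2)
        sim = Simulation(params, sim2_state, dwell_window=(0, 2**62))
        out = sim.attempt_pair_move(pair=(4, 4), direction=3, u=0.0)
        assert not out.accepted


class TestIncrementalEnergyOracle:
    """Reported move dE must equal the brute-force total-energy difference."""

    @pytest.mark.parametrize("move_type", ["separation", "protein", "pair"])
    def test_thousand_random_moves(self, move_type, small_params, rng):
        state = random_state(small_params, rng, l_range=(13.0, 42.0))
        sim = Simulation(small_params, state, dwell_window=(0, 2**62))
        checked = 0
        while checked < 1000:
            if move_type == "pair" and sim.n_pairs == 0:
                sim.attempt_protein_move(rng, u=0.0)  # reshuffle until pairs exist
                continue
            e_before = total_energy(state, small_params).e_total
            if move_type == "separation":
                out = sim.attempt_separation_move(rng, u=0.0)
            elif move_type == "protein":
                out = sim.attempt_protein_move(rng, u=0.0)
            else:
                out = sim.attempt_pair_move(rng, u=0.0)
            e_after = total_energy(state, small_params).e_total
            if out.accepted:
                assert e_after - e_before == pytest.approx(out.delta_e, abs=1e-9)
            else:
                assert e_after == e_before  # rejected/excluded moves change nothing
            checked += 1
        sim.check_consistency()


class TestMoveStorms:
    def test_species_conservation_and_occupancy(self, small_params, rng):
        state = random_state(small_params, rng)
        before = state.species_counts()
        for _ in range(15):
            mc_step(state, small_params, rng)
        assert state.species_counts() == before
        # single occupancy is structural (one code per patch) -- cross-check the
        # protein registry against the occupancy grids
        sim = state._sim
        sim.check_consistency()
        occupied1 = {(int(i), int(j)) for i, j in zip(*np.nonzero(state.occ1))}
        reg1 = {
            (int(sim.pi[p]), int(sim.pj[p]))
            for p in range(sim.n_proteins) if sim.pm[p] == 1
        }
        assert occupied1 == reg1
        assert state.step_counter == 15

    def test_bond_cache_matches_recomputation_after_kernel_run(self, small_params, rng):
        state = make_initial_state(small_params, (14.0, 41.0), rng)
        sim = Simulation(small_params, state)
        sim.run(n_steps=300, sampling_interval=50)
        sim.check_consistency()
        view = bonds(sim.state, small_params)
        assert np.array_equal(sim.nbond, view.counts_by_kind())
        assert state.species_counts()["TCR"] == small_params.n_tcr


class TestStepAccounting:
    def test_attempts_per_step(self, rng):
        params = ModelParameters(
            lattice_nx=6, lattice_ny=6, n_tcr=2, n_lfa=2, n_self_pmhc=0,
            n_foreign_pmhc=0, n_icam=0, dwell_start_step=0,
        )
        state = make_initial_state(params, (40.0, 40.0), rng)
        sim = Simulation(params, state)
        assert sim.n_pairs == 0  # no cognate partners present at all
        sim.step(rng)
        s = sim.stats
        # 36 separation attempts + 4 protein attempts + 0 pair attempts
        assert s[0] == 36 and s[3] == 4 and s[6] == 0

    def test_empty_membranes_only_separation_attempts(self, rng):
        params = ModelParameters(
            lattice_nx=5, lattice_ny=5, n_tcr=0, n_lfa=0, n_self_pmhc=0,
            n_foreign_pmhc=0, n_icam=0,
        )
        sim = Simulation(params, make_initial_state(params, (30.0, 30.0), rng))
        sim.step(rng)
        assert sim.stats[0] == 25 and sim.stats[3] == 0 and sim.stats[6] == 0


class TestDwellTracking:
    def test_scripted_bind_unbind_sequence(self):
        """A bond formed at step 10 and broken at step 250 dwells 240 t0."""
        params = ModelParameters(
            lattice_nx=8, lattice_ny=8, u_self=5.9, n_tcr=1, n_lfa=0,
            n_self_pmhc=1, n_foreign_pmhc=0, n_icam=0, dwell_start_step=0,
        )
        l = np.full((8, 8), 16.0)  # apposed but unbound
        occ1 = np.zeros((8, 8), np.int8)
        occ2 = np.zeros((8, 8), np.int8)
        occ1[4, 4] = K.M1_TCR
        occ2[4, 4] = K.M2_SMHC
        sim = Simulation(params, MembraneState(l, occ1, occ2), dwell_window=(0, 2**62))
        sim.state.step_counter = 10
        formed = sim.attempt_separation_move(patch=(4, 4), delta=-0.6, u=0.0)
        assert formed.bonds_formed
        sim.state.step_counter = 250
        broken = sim.attempt_separation_move(patch=(4, 4), delta=0.4, u=0.0)
        assert broken.bonds_broken
        record = sim.dwell_record()
        assert list(record.lifetimes[K.KIND_TCR_SELF]) == [240]
        assert record.bind_counts[0] == 1 and record.unbind_counts[0] == 1

    def test_surviving_bond_is_censored_not_counted(self):
        params = ModelParameters(
            lattice_nx=8, lattice_ny=8, u_self=5.9, n_tcr=1, n_lfa=0,
            n_self_pmhc=1, n_foreign_pmhc=0, n_icam=0, dwell_start_step=0,
        )
        l = np.full((8, 8), 15.0)
        occ1 = np.zeros((8, 8), np.int8)
        occ2 = np.zeros((8, 8), np.int8)
        occ1[4, 4] = K.M1_TCR
        occ2[4, 4] = K.M2_SMHC
        sim = Simulation(params, MembraneState(l, occ1, occ2), dwell_window=(0, 2**62))
        record = sim.dwell_record()
        assert record.censored[K.KIND_TCR_SELF] == 1
        assert record.lifetimes[K.KIND_TCR_SELF].size == 0


class TestReproducibility:
    def test_same_seed_bitwise_identical_series(self, rng):
        params = ModelParameters(
            lattice_nx=10, lattice_ny=10, u_self=6.5, n_tcr=3, n_lfa=3,
            n_self_pmhc=3, n_foreign_pmhc=0, n_icam=3, n_steps=400,
            equilibration_steps=100, sampling_interval=20, dwell_start_step=0,
            rng_seed=99,
        )
        init = make_initial_state(params, (14.5, 40.5), np.random.default_rng(5))
        r1 = run_trajectory(params, init.copy())
        r2 = run_trajectory(params, init.copy())
        assert r1.series.data.equals(r2.series.data)
        assert np.array_equal(r1.final_state.l, r2.final_state.l)
        r3 = run_trajectory(params.replace(rng_seed=100), init.copy())
        assert not r3.series.data.equals(r1.series.data)


class TestClampedPatchStatistics:
    def test_stationary_variance_of_single_free_patch(self):
        """One free patch on a clamped flat background has energy
        10*kappa*(l-l0)^2/a^2, hence Gaussian stationary statistics with
        variance a^2/(20*kappa) = 0.5625 nm^2 at the default parameters."""
        params = ModelParameters(
            lattice_nx=5, lattice_ny=5, n_tcr=0, n_lfa=0, n_self_pmhc=0,
            n_foreign_pmhc=0, n_icam=0,
        )
        state = make_initial_state(params, (40.0, 40.0), np.random.default_rng(0))
        sim = Simulation(params, state)
        rng = np.random.default_rng(31415)
        samples = np.empty(150_000)
        for t in range(samples.size):
            sim.attempt_separation_move(rng, patch=(2, 2))
            samples[t] = state.l[2, 2]
        var = samples[2000:].var()
        assert var == pytest.approx(params.patch_size**2 / (20 * params.kappa), rel=0.05)
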