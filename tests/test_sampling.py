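"""Monte Carlo engine: DOF accounting, determinism, exchange bookkeeping."""

import numpy as np
import pytest

import foldswitch as fs
from foldswitch.sampling import (
    Conformation,
    HybridModel,
    count_dof,
    mc_cycle,
    random_conformation,
    run_constant_T,
    temperature_ladder,
)
from foldswitch.sequences import GA98, GB98
from foldswitch.transferable import TERM_NAMES


class TestCountDof:
    def test_glycine_tripeptide(self):
        # phi and psi free on every residue, no sidechain rotors
        assert count_dof("GGG") == 6

    def test_fold_switch_pair(self):
        assert count_dof(GA98) == 283
        assert count_dof(GB98) == 282

    @pytest.mark.parametrize("base", ["GGG", "LAKE", GA98])
    def test_appending_glycine_adds_two(self, base):
        assert count_dof(base + "G") == count_dof(base) + 2

    def test_proline_phi_frozen(self):
        assert count_dof("GPG") == count_dof("GGG") - 1

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            count_dof("AXA")


class _CountingModel:
    def __init__(self):
        self.calls = 0

    def evaluate(self, coords):
        self.calls += 1
        return {t: 0.0 for t in TERM_NAMES}


class TestMcCycle:
    def test_updates_per_cycle_equals_dof(self, empty_map):
        seq = "LAK"
        counter = _CountingModel()
        model = HybridModel(empty_map, empty_map, fs.SbmParams(), counter)
        conf = random_conformation(seq, np.random.default_rng(0))
        mc_cycle(conf, 1.0, model, np.random.default_rng(1), current_energy=0.0)
        assert counter.calls == count_dof(seq)

    def test_flat_potential_accepts_every_move(self, empty_map):
        model = HybridModel(empty_map, empty_map, fs.SbmParams(), "none")
        conf = random_conformation("LAK", np.random.default_rng(0))
        _, _, accepted = mc_cycle(conf, 1.0, model, np.random.default_rng(1),
                                  current_energy=0.0)
        assert accepted == count_dof("LAK")

    def test_infinite_temperature_accepts_everything(self, map_A, map_B,
                                                     fixture_seq):
        model = HybridModel(map_A, map_B, fs.SbmParams(eps_B=-1.0), "standin")
        conf = random_conformation(fixture_seq, np.random.default_rng(2))
        n_acc = 0
        rng = np.random.default_rng(3)
        e = model.energy(conf)
        for _ in range(3):
            conf, e, acc = mc_cycle(conf, 1e12, model, rng, current_energy=e)
            n_acc += acc
        assert n_acc == 3 * count_dof(fixture_seq)

    def test_proline_phi_stays_frozen_under_moves(self, empty_map):
        model = HybridModel(empty_map, empty_map, fs.SbmParams(), "none")
        conf = random_conformation("APA", np.random.default_rng(4))
        frozen = conf.phi[1]
        rng = np.random.default_rng(5)
        for _ in range(20):
            conf, _, _ = mc_cycle(conf, 2.0, model, rng, current_energy=0.0)
        assert conf.phi[1] == frozen


class TestRunConstantT:
    def test_deterministic_for_fixed_seed(self, map_A, map_B, fixture_seq):
        params = fs.SbmParams(eps_B=-1.0, eps_ratio=1.0)
        kwargs = dict(T=0.5, n_cycles=15, seed=42, record_stride=3)
        t1 = run_constant_T(fixture_seq, (map_A, map_B), params, **kwargs)
        t2 = run_constant_T(fixture_seq, (map_A, map_B), params, **kwargs)
        assert t1.E_total == t2.E_total
        assert t1.Q_A == t2.Q_A

    def test_zero_cycles_records_initial_state_only(self, map_A, map_B,
                                                    fixture_seq):
        traj = run_constant_T(fixture_seq, (map_A, map_B), fs.SbmParams(),
                              T=1.0, n_cycles=0, seed=0)
        assert len(traj) == 1
        assert traj.cycles == [0]

    def test_cycles_strictly_increasing(self, map_A, map_B, fixture_seq):
        traj = run_constant_T(fixture_seq, (map_A, map_B), fs.SbmParams(),
                              T=1.0, n_cycles=12, seed=1, record_stride=4)
        assert all(b > a for a, b in zip(traj.cycles, traj.cycles[1:]))

    def test_low_T_sbm_run_reaches_helix_basin(self, map_A, fixture_seq):
        # single-basin potential: the helix map minimum is reachable
        params = fs.SbmParams(eps_B=-1.0, eps_ratio=1.0)
        traj = run_constant_T(fixture_seq, (map_A, _empty_like(map_A)), params,
                              T=0.25, n_cycles=250, seed=7, record_stride=10)
        assert max(traj.Q_A) > 0.8


def _empty_like(cmap):
    from foldswitch.contacts import ConsensusMap
    return ConsensusMap(fold_label="empty", contacts=[], n_conformers=1,
                        length=cmap.length)


class TestReplicaExchange:
    def test_equal_temperatures_always_swap(self, map_A, map_B, fixture_seq):
        rs = fs.parallel_tempering(fixture_seq, (map_A, map_B), fs.SbmParams(),
                                   [1.0, 1.0], n_cycles=12,
                                   exchange_interval=2, seed=0)
        assert rs.exchange_attempted > 0
        assert rs.acceptance_rate == 1.0

    def test_unsorted_ladder_rejected(self, map_A, map_B, fixture_seq):
        with pytest.raises(ValueError, match="sorted"):
            fs.parallel_tempering(fixture_seq, (map_A, map_B), fs.SbmParams(),
                                  [2.0, 1.0], n_cycles=2, seed=0)

    def test_replica_identities_remain_a_permutation(self, map_A, map_B,
                                                     fixture_seq):
        rs = fs.parallel_tempering(fixture_seq, (map_A, map_B),
                                   fs.SbmParams(eps_B=-1.0),
                                   [0.4, 0.7, 1.2], n_cycles=20,
                                   exchange_interval=2, seed=3)
        assert sorted(rs.replica_at_rung) == [0, 1, 2]

    def test_exchange_log_only_at_interval_multiples(self, map_A, map_B,
                                                     fixture_seq):
        rs = fs.parallel_tempering(fixture_seq, (map_A, map_B), fs.SbmParams(),
                                   [0.5, 1.0], n_cycles=10,
                                   exchange_interval=3, seed=2)
        assert [c for c, _, _ in rs.exchange_log] == [3, 6, 9]
        assert sum(a for _, a, _ in rs.exchange_log) == rs.exchange_attempted
        assert sum(a for _, _, a in rs.exchange_log) == rs.exchange_accepted

    def test_one_trajectory_per_rung(self, map_A, map_B, fixture_seq):
        ladder = temperature_ladder(0.5, 2.0, 3)
        rs = fs.parallel_tempering(fixture_seq, (map_A, map_B), fs.SbmParams(),
                                   ladder, n_cycles=6, exchange_interval=3,
                                   seed=1)
        assert len(rs.trajectories) == 3
        assert [t.T for t in rs.trajectories] == ladder

    def test_identical_hamiltonians_always_accept(self, map_A, map_B,
                                                  fixture_seq):
        rs = fs.hamiltonian_replica_exchange(
            fixture_seq, (map_A, map_B), [-0.37, -0.37], T=1.0, n_cycles=12,
            exchange_interval=2, seed=0)
        assert rs.exchange_attempted > 0
        assert rs.acceptance_rate == 1.0

    def test_hamiltonian_rungs_store_eps(self, map_A, map_B, fixture_seq):
        rs = fs.hamiltonian_replica_exchange(
            fixture_seq, (map_A, map_B), [-0.5, -0.3], T=1.0, n_cycles=4,
            exchange_interval=2, seed=0)
        assert [t.eps_B for t in rs.trajectories] == [-0.5, -0.3]

    def test_seed_reproducibility(self, map_A, map_B, fixture_seq):
        kwargs = dict(n_cycles=10, exchange_interval=3, seed=9)
        a = fs.parallel_tempering(fixture_seq, (map_A, map_B), fs.SbmParams(),
                                  [0.5, 1.0], **kwargs)
        b = fs.parallel_tempering(fixture_seq, (map_A, map_B), fs.SbmParams(),
                                  [0.5, 1.0], **kwargs)
        for ta, tb in zip(a.trajectories, b.trajectories):
            assert ta.E_total == tb.E_total


class TestConformation:
    def test_coordinates_deterministic_function_of_torsions(self):
        c1 = Conformation("LAKE", [-60, -70, -80, -90], [140, -40, 150, 60])
        c2 = Conformation("LAKE", [-60, -70, -80, -90], [140, -40, 150, 60])
        assert np.array_equal(c1.coords.ca, c2.coords.ca)

    def test_copy_is_independent(self):
        c1 = Conformation("LAKE", [-60] * 4, [140] * 4)
        c2 = c1.copy()
        c2.phi[0] = 77.0
        c2.invalidate()
        assert c1.phi[0] == -60
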