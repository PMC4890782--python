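"""Transferable-energy contract, stand-in terms and the pi-pi override."""

import numpy as np
import pytest

import foldswitch as fs
from foldswitch.geometry import build_chain
from foldswitch.pipi import GRID_SHAPE, PiPiPotential
from foldswitch.transferable import (
    NullModel,
    StandinModel,
    apply_pipi_override,
    evaluate_transferable,
    total_energy,
)

TERMS = ("E_local", "E_EV", "E_HB", "E_SC", "E_HP")


def _extended(seq):
    L = len(seq)
    return build_chain(seq, np.full(L, -135.0), np.full(L, 135.0))


def _coords_with_sc(seq, sc_positions):
    """ChainCoords with atoms spread far apart except prescribed SC centroids."""
    from foldswitch.geometry import ChainCoords
    L = len(seq)
    far = np.column_stack([(np.arange(L) + 5) * 100.0, np.zeros(L), np.zeros(L)])
    sc = far.copy()
    for i, pos in sc_positions.items():
        sc[i] = pos
    normals = np.full((L, 3), np.nan)
    for i, aa in enumerate(seq):
        if aa in "FY":
            normals[i] = (0.0, 0.0, 1.0)
    return ChainCoords(seq, far + (0, 1, 0), far, far + (0, 0, 1),
                       far + (0, 0, 2), far + (0, 2, 0), sc, normals)


class TestStandinTerms:
    def test_fully_extended_chain_has_no_nonbonded_terms(self):
        coords = _extended("KELKELKEL")
        model = StandinModel(k_local=0.0)
        terms = model.evaluate(coords)
        assert terms["E_EV"] == pytest.approx(0.0, abs=1e-6)
        assert terms["E_HB"] == pytest.approx(0.0, abs=1e-3)
        assert terms["E_HP"] == 0.0

    def test_overlap_gives_large_positive_excluded_volume(self):
        # force two nonbonded sidechain centroids into near-overlap
        coords = _coords_with_sc("AAAAA", {0: (0, 0, 0), 3: (1.4, 0, 0)})
        assert StandinModel().e_ev(coords) > 100.0

    def test_hydrophobic_term_counts_contacting_nonpolar_pairs(self):
        # three nonpolar centroids in mutual contact, one polar bystander
        coords = _coords_with_sc("LSLAL", {0: (0, 0, 0), 2: (4.0, 0, 0),
                                           4: (2.0, 3.0, 0)})
        model = StandinModel(k_hp=1.0, k_ev=0.0)
        # pairs within 4.5 A: (0,2)=4.0, (0,4)=3.6, (2,4)=3.6 -> count 3
        assert model.e_hp(coords) == pytest.approx(-3.0)
        # a polar partner (Ser) never counts even when close to a nonpolar one
        coords2 = _coords_with_sc("LSLAL", {1: (0, 0, 0), 3: (1.0, 0, 0)})
        assert model.e_hp(coords2) == 0.0

    def test_charge_term_sign(self):
        attract = StandinModel().e_sc(_extended("KAAEAAKAAE"))
        repel = StandinModel().e_sc(_extended("KAAKAAKAAK"))
        assert attract < 0 < repel

    def test_all_terms_finite_for_random_chains(self, rng):
        model = StandinModel()
        for _ in range(5):
            L = 10
            coords = build_chain("LAKEVSTIFD", rng.uniform(-160, -50, L),
                                 rng.uniform(-70, 170, L))
            assert all(np.isfinite(v) for v in model.evaluate(coords).values())


class TestContract:
    def test_null_model_returns_five_zero_terms(self):
        terms = NullModel().evaluate(_extended("AAAA"))
        assert set(terms) == set(TERMS)
        assert all(v == 0.0 for v in terms.values())

    def test_any_object_with_evaluate_satisfies_contract(self, map_A, map_B):
        class Constant:
            def evaluate(self, coords):
                return {t: 1.0 for t in TERMS}

        coords = _extended("A" * map_A.length)
        bd = total_energy(coords, None, map_A, map_B, fs.SbmParams(), Constant())
        assert bd.E_trans == pytest.approx(5.0)

    def test_sequence_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sequence"):
            evaluate_transferable(_extended("AAAA"), "AAAL", NullModel())

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="unknown residue"):
            build_chain("AXZA", np.zeros(4), np.zeros(4))


class TestTotalEnergy:
    def test_additivity_is_exact(self, map_A, map_B, rng):
        coords = build_chain("LAKEVSTIFDNQ", rng.uniform(-160, -50, 12),
                             rng.uniform(-70, 170, 12))
        bd = total_energy(coords, None, map_A, map_B, fs.SbmParams(), "standin")
        assert bd.E_SBM == bd.E_A + bd.E_B
        assert bd.E_total == pytest.approx(
            bd.E_A + bd.E_B + bd.E_local + bd.E_EV + bd.E_HB + bd.E_SC + bd.E_HP)

    def test_zero_sbm_and_null_model_gives_zero_total(self, map_A, map_B):
        coords = _extended("A" * map_A.length)
        bd = total_energy(coords, None, map_A, map_B,
                          fs.SbmParams(eps_B=0.0), "none")
        assert bd.E_total == 0.0

    def test_model_none_reduces_to_pure_sbm(self, helix_conformers, map_A, map_B):
        coords = _extended("A" * map_A.length)
        bd = total_energy(coords, None, map_A, map_B, fs.SbmParams(), "none")
        assert bd.E_total == bd.E_SBM


class TestNoFoldingWithoutNativeBias:
    def test_standin_alone_does_not_reach_either_basin(self, map_A, map_B,
                                                       fixture_seq):
        # SBM off: the stand-in potential alone should not discover the
        # specific native distance patterns of either consensus map
        from foldswitch.sampling import run_constant_T
        from foldswitch.sbm import progress
        traj = run_constant_T(fixture_seq, (map_A, map_B),
                              fs.SbmParams(eps_B=0.0), T=0.45, n_cycles=200,
                              seed=13, transferable="standin",
                              record_stride=5, record_snapshots=True)
        ref = fs.SbmParams(eps_B=-1.0, eps_ratio=1.0)
        q = np.array([[progress(c.coords.ca, map_A, map_B, ref).Q_A,
                       progress(c.coords.ca, map_A, map_B, ref).Q_B]
                      for c in traj.snapshots])
        in_a = np.mean((q[:, 0] >= 0.6) & (q[:, 1] < 0.6))
        in_b = np.mean((q[:, 1] >= 0.6) & (q[:, 0] < 0.6))
        assert in_a < 0.05
        assert in_b < 0.05


class TestPipiOverride:
    @pytest.fixture
    def uniform_potential(self):
        energy = np.full(GRID_SHAPE, -0.8)
        return PiPiPotential(energy=energy, eps_pipi=1.5, pair_class="F-F")

    def test_no_aromatics_means_no_change(self, uniform_potential, rng):
        seq = "LAKEVLAKEV"
        coords = build_chain(seq, rng.uniform(-160, -50, 10),
                             rng.uniform(-70, 170, 10))
        base = StandinModel()
        wrapped = apply_pipi_override(base, uniform_potential)
        assert wrapped.evaluate(coords) == base.evaluate(coords)

    def test_aromatic_pair_energy_replaced(self):
        # one Phe pair in contact, parallel pseudo-normals
        seq = "AFAAFAAA"
        coords = _coords_with_sc(seq, {1: (0, 0, 0), 4: (4.0, 0, 0)})
        base = StandinModel(k_ev=0.0)
        f_pairs = [(i, j) for i, j, _ in base.hp_pair_matrix(coords)
                   if seq[i] == "F" and seq[j] == "F"]
        assert f_pairs == [(1, 4)]
        energy = np.full(GRID_SHAPE, -0.8)
        wrapped = apply_pipi_override(
            base, PiPiPotential(energy=energy, eps_pipi=1.5, pair_class="F-F"))
        delta = wrapped.evaluate(coords)["E_HP"] - base.evaluate(coords)["E_HP"]
        # the pair trades the -k_hp hydrophobic unit for E_pipi = -0.8
        assert delta == pytest.approx(1.0 - 0.8)

    def test_empty_table_rejected(self):
        empty = PiPiPotential(energy=np.zeros(GRID_SHAPE), eps_pipi=1.5,
                              pair_class="F-F")
        with pytest.raises(ValueError, match="empty"):
            apply_pipi_override(StandinModel(), empty)

    def test_model_without_pair_terms_rejected(self, uniform_potential):
        with pytest.raises(TypeError):
            apply_pipi_override(NullModel(), uniform_potential)
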