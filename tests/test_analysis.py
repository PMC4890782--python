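"""Superposition vectors, RMSD_sm, clustering, regions, flux, contact shifts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import foldswitch as fs
from foldswitch.analysis import (
    centroid_graph,
    cluster_conformations,
    contact_shift,
    macrostate_3,
    rmsd_sm,
    select_region,
    sequence_bias,
    superposition_vector,
    transition_flux,
)
from foldswitch.geometry import kabsch
from foldswitch.thermo import REGION_PRESETS


class TestSuperpositionVector:
    def test_conformation_equal_to_reference_gives_zero_blocks(
            self, helix_conformers, hairpin_conformers):
        ref_a, ref_b = helix_conformers[0], hairpin_conformers[0]
        v = superposition_vector(ref_a, ref_a, ref_b)
        L = len(ref_a)
        assert len(v) == 4 * L
        assert np.allclose(v[:L], 0.0, atol=1e-9)          # CA block vs A
        assert np.allclose(v[2 * L:3 * L], 0.0, atol=1e-9)  # CB block vs A
        assert v[L:2 * L].max() > 1.0                       # vs B: nonzero

    def test_invariant_under_rigid_motion_of_conformation(
            self, helix_conformers, hairpin_conformers):
        from foldswitch.structures import Structure, Residue
        ref_a, ref_b = helix_conformers[0], hairpin_conformers[1]
        conf = helix_conformers[1]
        rot = Rotation.random(random_state=5).as_matrix()
        shift = np.array([3.0, -8.0, 12.0])
        moved = Structure(id="m", model_index=1, residues=[
            Residue(index=r.index, name=r.name, ca=r.ca @ rot.T + shift,
                    cb=None if r.cb is None else r.cb @ rot.T + shift,
                    sidechain_heavy=[s @ rot.T + shift
                                     for s in r.sidechain_heavy])
            for r in conf.residues])
        v0 = superposition_vector(conf, ref_a, ref_b)
        v1 = superposition_vector(moved, ref_a, ref_b)
        assert np.allclose(v0, v1, atol=1e-6)

    def test_three_point_kabsch_oracle(self):
        # hand-placed triangle: superposition is an exact rigid match
        tri = np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 4, 0]])
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        moved = tri @ rot.T + np.array([5.0, 6, 7])
        _, _, fitted = kabsch(tri, moved)
        assert np.allclose(fitted, moved, atol=1e-9)

    def test_length_mismatch_rejected(self, helix_conformers):
        short = fs.generate_fixture_set(fs.FixtureSpec(
            length=8, topology="helix-bundle", n_conformers=1, seed=0))[0]
        with pytest.raises(ValueError):
            superposition_vector(helix_conformers[0], short, short)


class TestRmsdSm:
    def test_identical_vectors_zero(self, rng):
        v = rng.random(48)
        assert rmsd_sm(v, v) == 0.0

    def test_uniform_offset_equals_offset(self, rng):
        v = rng.random(48)
        assert rmsd_sm(v, v + 2.5) == pytest.approx(2.5)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_metric_axioms(self, seed):
        r = np.random.default_rng(seed)
        a, b, c = r.normal(size=(3, 24))
        assert rmsd_sm(a, b) >= 0
        assert rmsd_sm(a, b) == pytest.approx(rmsd_sm(b, a))
        assert rmsd_sm(a, c) <= rmsd_sm(a, b) + rmsd_sm(b, c) + 1e-12

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd_sm(np.zeros(4), np.zeros(8))


class TestClustering:
    def _blobs(self, rng, n_per=30, spread=0.1):
        centers = np.array([[0.0] * 8, [10.0] * 8, [-10.0] * 8])
        pts = np.concatenate([
            c + rng.normal(scale=spread, size=(n_per, 8)) for c in centers])
        labels = np.repeat([0, 1, 2], n_per)
        return pts, labels

    def test_planted_partition_recovered(self, rng):
        pts, labels = self._blobs(rng)
        cl = cluster_conformations(pts, k=3, seed=0)
        # same planted blob <-> same cluster id
        for blob in range(3):
            ids = cl.assignments[labels == blob]
            assert len(set(ids)) == 1
        assert len(set(cl.assignments)) == 3

    def test_deterministic_for_fixed_seed(self, rng):
        pts, _ = self._blobs(rng)
        a = cluster_conformations(pts, k=3, seed=5)
        b = cluster_conformations(pts, k=3, seed=5)
        assert np.array_equal(a.assignments, b.assignments)
        assert np.array_equal(a.centroid_ids, b.centroid_ids)

    def test_centroids_are_members_of_their_clusters(self, rng):
        pts, _ = self._blobs(rng, spread=3.0)
        cl = cluster_conformations(pts, k=5, seed=2)
        for c, cid in enumerate(cl.centroid_ids):
            assert cl.assignments[cid] == c

    def test_k_equal_to_points_gives_singletons(self, rng):
        pts = rng.normal(size=(6, 4)) * 10
        cl = cluster_conformations(pts, k=6, seed=0)
        assert sorted(cl.assignments) == list(range(6))

    def test_too_few_vectors_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_conformations(rng.normal(size=(4, 8)), k=5)


class TestCentroidGraph:
    def test_threshold_zero_connects_only_duplicates(self, rng):
        pts = np.concatenate([rng.normal(size=(5, 6)) * 20,
                              np.zeros((2, 6))])
        cl = cluster_conformations(pts, k=6, seed=1)
        edges = centroid_graph(cl, threshold=0.0)
        for a, b, d in edges:
            assert d == 0.0

    def test_infinite_threshold_gives_complete_graph(self, rng):
        pts = rng.normal(size=(12, 6)) * 10
        cl = cluster_conformations(pts, k=4, seed=3)
        edges = centroid_graph(cl, threshold=np.inf)
        assert len(edges) == 4 * 3 // 2

    def test_edges_annotated_with_rmsd_sm(self, rng):
        pts = rng.normal(size=(10, 6))
        cl = cluster_conformations(pts, k=3, seed=0)
        cent = pts[cl.centroid_ids]
        for a, b, d in centroid_graph(cl, threshold=np.inf):
            assert d == pytest.approx(rmsd_sm(cent[a], cent[b]))


class TestSelectRegion:
    def test_open_interval_excludes_boundary(self):
        box = ((0.66, 0.74), (0.12, 0.22))
        q_a = np.array([0.66, 0.70, 0.74])
        q_b = np.array([0.15, 0.15, 0.15])
        assert list(select_region(q_a, q_b, box)) == [1]

    def test_full_box_selects_everything(self, rng):
        q_a, q_b = rng.random(100), rng.random(100)
        idx = select_region(q_a, q_b, ((-0.01, 1.01), (-0.01, 1.01)))
        assert len(idx) == 100

    def test_counts_match_linear_scan(self, rng):
        q_a, q_b = rng.random(500), rng.random(500)
        box = REGION_PRESETS["TS1-GB"]
        idx = select_region(q_a, q_b, box)
        (a0, a1), (b0, b1) = box
        brute = [i for i in range(500)
                 if a0 < q_a[i] < a1 and b0 < q_b[i] < b1]
        assert list(idx) == brute

    def test_empty_box_rejected(self):
        with pytest.raises(ValueError):
            select_region(np.zeros(3), np.zeros(3), ((0.5, 0.5), (0.1, 0.2)))


class TestSequenceBias:
    def _clustering(self, labels, assignments, k):
        from foldswitch.analysis import Clustering
        n = len(labels)
        assignments = np.asarray(assignments)
        vectors = np.zeros((n, 4))
        centroid_ids = np.array([np.nonzero(assignments == c)[0][0]
                                 for c in range(k)])
        return Clustering(k=k, assignments=assignments,
                          centroid_ids=centroid_ids, vectors=vectors,
                          source_labels=np.asarray(labels))

    def test_equal_counts_give_zero_bias(self):
        cl = self._clustering([0, 1, 0, 1], [0, 0, 1, 1], 2)
        table = sequence_bias(cl, np.full(4, 0.5), np.full(4, 0.5))
        assert table["bias"].tolist() == [0.0, 0.0]
        assert table["fold_bias"].tolist() == [0.0, 0.0]

    def test_count_ratio_30_vs_10(self):
        labels = [0] * 10 + [1] * 30 + [0] * 30 + [1] * 10
        assignments = [0] * 40 + [1] * 40
        cl = self._clustering(labels, assignments, 2)
        table = sequence_bias(cl, np.full(80, 0.4), np.full(80, 0.4))
        assert table["bias"][0] == pytest.approx(np.log(3.0))
        assert table["bias"][1] == pytest.approx(-np.log(3.0))

    def test_one_sided_cluster_flagged(self):
        cl = self._clustering([0, 0, 1, 1], [0, 0, 1, 1], 2)
        table = sequence_bias(cl, np.full(4, 0.5), np.full(4, 0.5))
        assert table["bias"][0] == -np.inf
        assert bool(table["degenerate"][0])

    def test_unequal_source_counts_rejected(self):
        cl = self._clustering([0, 0, 0, 1], [0, 0, 1, 1], 2)
        with pytest.raises(ValueError, match="equal"):
            sequence_bias(cl, np.full(4, 0.5), np.full(4, 0.5))


class TestTransitionFlux:
    def test_static_trajectory_has_no_flux(self):
        fm = transition_flux(np.full(20, 0.9), np.full(20, 0.1))
        off_diag = fm.counts.sum() - np.trace(fm.counts)
        assert off_diag == 0

    def test_alternating_u_a_counting(self):
        # records U, A, U, A -> 3 transitions, all U <-> G_A
        q_a = np.array([0.2, 0.9, 0.2, 0.9])
        q_b = np.zeros(4)
        fm = transition_flux(q_a, q_b)
        assert fm.counts.sum() == 3
        assert fm.two_way("G_A", "U") == 1.0
        assert fm.two_way("G_B", "U") == 0.0

    def test_markov_chain_fluxes_match_generator(self, rng):
        # two-state Markov chain over U and G_A with known switch rates
        p_switch = 0.3
        states = [0]
        for _ in range(6000):
            states.append(states[-1] ^ 1 if rng.random() < p_switch
                          else states[-1])
        q_a = np.where(np.array(states) == 1, 0.9, 0.2)
        fm = transition_flux(q_a, np.zeros(len(q_a)))
        observed = fm.counts.sum() - np.trace(fm.counts)
        assert observed / 6000 == pytest.approx(p_switch, abs=0.03)

    def test_undefined_q_rejected(self):
        with pytest.raises(ValueError):
            transition_flux(np.array([0.1, np.nan]), np.zeros(2))

    def test_three_state_partition_covers_plane(self, rng):
        for q_a, q_b in rng.random((100, 2)) * 1.05:
            assert macrostate_3(q_a, q_b) in ("U", "G_A", "G_B")


class TestContactShift:
    def test_identical_ensembles_have_zero_shift(self, helix_conformers,
                                                 map_A, map_B):
        ens = list(helix_conformers)
        table = contact_shift(ens, ens, map_A, map_B)
        assert len(table) > 0
        assert np.allclose(table["shift"], 0.0)

    def test_contact_order_formula(self, helix_conformers, map_A, map_B):
        ens = list(helix_conformers)
        table = contact_shift(ens, ens, map_A, map_B)
        assert np.array_equal(table["contact_order"],
                              np.abs(table["i"] - table["j"]) + 1)
        assert table["contact_order"].min() >= 4

    def test_planted_frequencies(self, helix_conformers, hairpin_conformers,
                                 map_A, map_B):
        # ensemble A: 2 helix + 2 hairpin; ensemble B: 4 hairpin
        ens_a = [helix_conformers[0], helix_conformers[0],
                 hairpin_conformers[0], hairpin_conformers[0]]
        ens_b = [hairpin_conformers[0]] * 4
        table = contact_shift(ens_a, ens_b, map_A, map_B)
        helix_only = fs.build_contact_map(helix_conformers[0]).contacts \
            - fs.build_contact_map(hairpin_conformers[0]).contacts
        for (i, j) in helix_only:
            row = table[(table["i"] == i) & (table["j"] == j)].iloc[0]
            assert row["P_A"] == pytest.approx(0.5)
            assert row["P_B"] == pytest.approx(0.0)

    def test_native_classification(self, helix_conformers, map_A, map_B):
        ens = list(helix_conformers)
        table = contact_shift(ens, ens, map_A, map_B)
        native_a_pairs = {(c.i, c.j) for c in map_A.contacts}
        for _, row in table.iterrows():
            if (row["i"], row["j"]) in native_a_pairs:
                assert row["class"] in ("native-G_A", "native-both")

    def test_empty_ensemble_rejected(self, map_A, map_B):
        with pytest.raises(ValueError):
            contact_shift([], [], map_A, map_B)
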