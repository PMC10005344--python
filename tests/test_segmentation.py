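"""Orientation descriptors, time averaging and crystallite clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from quasicryst.model_io import TrajectoryWindow
from quasicryst.segmentation import (axis_angles, chain_vectors,
                                     cluster_orientations, slopes,
                                     time_average_descriptors, segment)
from quasicryst.synthetic import CrystalliteSpec, generate_polycrystal_frame
from quasicryst.model_io import SimulationBox

from conftest import make_pair_frame

vec3 = st.tuples(*[st.floats(-100, 100, allow_nan=False)] * 3).map(np.array)
nonzero_vec3 = vec3.filter(lambda v: np.linalg.norm(v) > 1e-6)


class TestSlopes:
    def test_generic_vector(self):
        b = slopes(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(
            b, [np.arctan(2.0), np.arctan(1.5), np.arctan(1.0 / 3.0)],
            atol=1e-12)

    def test_axis_aligned_conventions(self):
        # x-aligned: Bxy = 0, Byz = 0 (0/0 convention), Bzx = pi/2
        np.testing.assert_allclose(slopes(np.array([1.0, 0.0, 0.0])),
                                   [0.0, 0.0, np.pi / 2], atol=1e-15)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            slopes(np.zeros(3))

    @settings(deadline=None, derandomize=True)
    @given(nonzero_vec3)
    def test_head_tail_invariance_exact(self, v):
        np.testing.assert_array_equal(slopes(v), slopes(-v))

    @settings(deadline=None, derandomize=True)
    @given(nonzero_vec3, st.floats(1e-3, 1e3))
    def test_positive_scaling_invariance(self, v, s):
        np.testing.assert_allclose(slopes(v), slopes(s * v), atol=1e-9)


class TestAxisAngles:
    def test_unit_axis(self):
        np.testing.assert_allclose(axis_angles(np.array([0.0, 0.0, 1.0])),
                                   [np.pi / 2, np.pi / 2, 0.0], atol=1e-15)

    def test_generic_vector(self):
        a = axis_angles(np.array([1.0, 2.0, 3.0]))
        r = np.sqrt(14.0)
        np.testing.assert_allclose(
            a, [np.arccos(1 / r), np.arccos(2 / r), np.arccos(3 / r)],
            atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(nonzero_vec3)
    def test_antisymmetry_and_direction_cosines(self, v):
        a = axis_angles(v)
        np.testing.assert_allclose(axis_angles(-v), np.pi - a, atol=1e-9)
        assert abs(np.sum(np.cos(a) ** 2) - 1.0) < 1e-9


class TestChainVectors:
    def test_subtraction(self, pair_topology):
        frame, table = make_pair_frame([[1.0, 2.0, 3.0]],
                                       origins=[[1.0, 1.0, 0.0]])
        np.testing.assert_allclose(
            chain_vectors(frame, table, pair_topology.anchor_orient),
            [[1.0, 2.0, 3.0]])

    def test_coincident_anchors_raise(self, pair_topology):
        frame, table = make_pair_frame([[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="degenerate"):
            chain_vectors(frame, table, pair_topology.anchor_orient)


class TestTimeAveraging:
    def _window(self, vecs_per_frame):
        frames = []
        for t, vecs in enumerate(vecs_per_frame):
            f, table = make_pair_frame(vecs)
            f.time = float(t)
            frames.append(f)
        return TrajectoryWindow(frames, 0.0, float(len(vecs_per_frame) - 1)), table

    def test_static_molecule_equals_single_frame(self, pair_topology):
        v = [[1.0, 2.0, 3.0]]
        win, table = self._window([v] * 10)
        df = time_average_descriptors(win, table, pair_topology)
        np.testing.assert_allclose(df[["Bxy", "Byz", "Bzx"]].to_numpy()[0],
                                   slopes(np.array(v[0])), atol=1e-12)
        assert df["n_frames"].iloc[0] == 10

    def test_mean_vector_mode_cancels_symmetric_wobble(self, pair_topology):
        eps = 1e-3
        win, table = self._window([[[1.0, 0.0, eps]], [[1.0, 0.0, -eps]]])
        df = time_average_descriptors(win, table, pair_topology)
        assert df["Bzx"].iloc[0] == pytest.approx(np.pi / 2)  # dz == 0 exactly

    def test_literal_mode_wrap_artifact(self, pair_topology):
        # slopes +89 deg and -89 deg average to 0 in literal mode
        v1 = [1.0, np.tan(np.deg2rad(89.0)), 0.0]
        v2 = [1.0, np.tan(np.deg2rad(-89.0)), 0.0]
        win, table = self._window([[v1], [v2]])
        lit = time_average_descriptors(win, table, pair_topology,
                                       averaging="literal")
        assert lit["Bxy"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        # mean-vector mode stays at the wrap: |Bxy| ~ 90 deg
        mv = time_average_descriptors(win, table, pair_topology)
        assert abs(np.degrees(mv["Bxy"].iloc[0])) > 85.0

    def test_empty_window_raises(self, pair_topology):
        win, table = self._window([[[1.0, 0.0, 0.0]]])
        win.frames = []
        with pytest.raises(ValueError):
            time_average_descriptors(win, table, pair_topology)


def _descriptor_frame(angles, mode="slopes"):
    cols = (["Bxy", "Byz", "Bzx"] if mode == "slopes"
            else ["alpha_x", "alpha_y", "alpha_z"])
    df = pd.DataFrame(np.asarray(angles), columns=cols)
    df.insert(0, "molecule_id", np.arange(len(df)))
    df["n_frames"] = 1
    df.attrs["mode"] = mode
    return df


class TestClustering:
    def test_two_groups_plus_random(self, rng):
        g1 = rng.normal(0.2, np.deg2rad(1.0), (50, 3))
        g2 = g1 + np.deg2rad(30.0)
        noise = rng.uniform(-np.pi / 2, np.pi / 2, (10, 3))
        df = _descriptor_frame(np.vstack([g1, g2, noise]))
        crys = cluster_orientations(df, eps_deg=5.0, min_cluster_size=5)
        ordered = [c for c in crys if not c.is_disordered_pool]
        pool = [c for c in crys if c.is_disordered_pool][0]
        assert len(ordered) == 2
        assert set(ordered[0].member_molecule_ids) | set(
            ordered[1].member_molecule_ids) >= set(range(100))
        assert sum(m >= 100 for m in pool.member_molecule_ids) >= 8

        # brute-force separability oracle: every in-group pairwise
        # distance is below eps, every cross-group one above
        def wrapdist(a, b):
            d = np.abs(a - b)
            d = np.minimum(d, np.pi - d)
            return np.sqrt((d ** 2).sum())

        within = max(wrapdist(a, b) for a in g1[:10] for b in g1[:10])
        across = min(wrapdist(a, b) for a in g1[:10] for b in g2[:10])
        assert within < np.deg2rad(5.0) < across

    def test_single_orientation_single_cluster(self):
        df = _descriptor_frame(np.tile([0.3, -0.2, 0.9], (20, 1)))
        crys = cluster_orientations(df, eps_deg=5.0, min_cluster_size=5)
        ordered = [c for c in crys if not c.is_disordered_pool]
        assert len(ordered) == 1 and ordered[0].size == 20

    def test_well_ordered_single_crystal_is_a_small_compact_cluster(self, rng):
        angles = rng.normal([0.5, -0.1, 0.8], np.deg2rad(0.2), (8, 3))
        crys = cluster_orientations(_descriptor_frame(angles), eps_deg=5.0,
                                    min_cluster_size=5)
        ordered = [c for c in crys if not c.is_disordered_pool]
        assert len(ordered) == 1 and ordered[0].size == 8

    def test_permutation_invariance_of_memberships(self, rng):
        g1 = rng.normal(0.2, np.deg2rad(1.0), (30, 3))
        g2 = g1 + np.deg2rad(40.0)
        angles = np.vstack([g1, g2])
        perm = rng.permutation(len(angles))
        def memberships(a, ids):
            df = _descriptor_frame(a)
            df["molecule_id"] = ids
            crys = cluster_orientations(df, eps_deg=5.0, min_cluster_size=5)
            return {frozenset(c.member_molecule_ids.tolist())
                    for c in crys if not c.is_disordered_pool}
        assert (memberships(angles, np.arange(60))
                == memberships(angles[perm], perm))

    def test_parameter_validation(self):
        df = _descriptor_frame(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            cluster_orientations(df, eps_deg=0.0)
        with pytest.raises(ValueError):
            cluster_orientations(df, min_cluster_size=1)


ROTATIONS = [(20, 35, 10), (0, 75, 40), (90, 30, 60), (150, 110, 20),
             (45, 150, 80)]


@pytest.mark.parametrize("n_crystallites", [1, 2, 3, 5])
def test_polycrystal_recovery_is_exact(n_crystallites):
    """K well-separated crystallites + disordered melt: exact recovery."""
    box = SimulationBox(12, 12, 12)
    specs = [CrystalliteSpec(n_a=5, n_b=5, angular_noise_deg=1.0, seed=s,
                             rotation=ROTATIONS[s], translation=(6, 6, 6))
             for s in range(n_crystallites)]
    n_dis = max(1, (25 * n_crystallites) // 10)
    frame, table, truth = generate_polycrystal_frame(specs, box,
                                                     n_disordered=n_dis)
    window = TrajectoryWindow([frame], 0.0, 0.0)
    crystallites, _ = segment(window, table, eps_deg=5.0, min_cluster_size=5)
    ordered = [c for c in crystallites if not c.is_disordered_pool]
    assert len(ordered) == n_crystallites
    label = np.full(table.n_molecules, -1)
    for c in ordered:
        label[c.member_molecule_ids] = c.crystallite_id
    found = set()
    for k in range(n_crystallites):
        ids = set(label[truth.labels == k])
        assert len(ids) == 1 and -1 not in ids  # perfect, unsplit membership
        found |= ids
    assert len(found) == n_crystallites  # no two merged
    assert (label[truth.labels < 0] == -1).mean() >= 0.8
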