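"""Contact function: pose geometry, contract properties, estimation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from omegamap.contactfn import (ANY, ContactParameterTable, EstimationError,
                                EstimationSettings, PairContactParams,
                                RelativePose, contact_value,
                                estimate_pair_params, estimate_parameters,
                                pair_contact, pose_distance, quat_angle,
                                range_class, relative_pose)
from omegamap.fixtures import HELIX_PHI_PSI, build_chain


def _params(d_lo=5.0, d_hi=8.0, theta_max=1.0, alpha_max=1.5, quat=None):
    if quat is None:
        quat = np.array([0.0, 0.0, 0.0, 1.0])
    return PairContactParams(d_lo=d_lo, d_hi=d_hi, preferred_rotation=quat,
                             theta_max=theta_max, alpha_max=alpha_max)


class TestRangeClass:
    @pytest.mark.parametrize("sep,expected",
                             [(1, 1), (2, 2), (4, 4), (5, "long"), (40, "long")])
    def test_binning(self, sep, expected):
        assert range_class(sep) == expected

    def test_zero_separation_rejected(self):
        with pytest.raises(ValueError):
            range_class(0)


class TestRelativePose:
    def test_identity_and_half_turn(self):
        p = _params()
        R = np.eye(3)
        assert relative_pose(R, R, 6.0, p).theta == pytest.approx(0.0)
        half = Rotation.from_euler("x", np.pi).as_matrix()
        pose = relative_pose(half, np.eye(3), 6.0, p)
        assert pose.theta == pytest.approx(np.pi, abs=1e-9)

    def test_trace_formula_matches_quaternion_angle(self, rng):
        """The rotation-matrix geodesic angle equals the quaternion angle
        2*arccos(|<q_ij, q*>|) on random rotations."""
        for _ in range(50):
            Ri, Rj = Rotation.random(2, rng=rng)
            q_star = Rotation.random(rng=rng)
            p = _params(quat=q_star.as_quat())
            pose = relative_pose(Ri.as_matrix(), Rj.as_matrix(), 6.0, p)
            q_ij = Rotation.from_matrix(Ri.as_matrix() @ Rj.as_matrix().T)
            expected = quat_angle(q_ij.as_quat(), q_star.as_quat())
            assert pose.theta == pytest.approx(expected, abs=1e-9)


class TestPoseDistance:
    def test_long_range_identity(self, rng):
        p = PairContactParams(d_lo=5.0, d_hi=8.0)
        for d in rng.uniform(0.1, 20, 20):
            assert pose_distance(RelativePose(d=d), p, "long") == d
            assert pose_distance(RelativePose(d=d), p, 1) == d

    def test_full_orientation_bonus(self):
        p = _params()
        d = 6.0  # inside the interval -> full fade
        assert pose_distance(RelativePose(d, theta=0.0), p, 3) == \
            pytest.approx(d - p.alpha_max)

    def test_monotone_in_theta(self):
        p = _params()
        thetas = np.linspace(0, p.theta_max * 0.99, 25)
        dps = [pose_distance(RelativePose(6.5, t), p, 4) for t in thetas]
        assert np.all(np.diff(dps) > 0)

    def test_bounds_and_cutoffs(self, rng):
        p = _params()
        for _ in range(200):
            d = rng.uniform(0.1, 15)
            theta = rng.uniform(0, np.pi)
            dp = pose_distance(RelativePose(d, theta), p, 2)
            assert d - p.alpha_max - 1e-12 <= dp <= d + 1e-12
            if theta >= p.theta_max or d >= p.d_hi + 2.0:
                assert dp == d


class TestContactValue:
    def test_edges_and_midpoint(self):
        p = _params()
        assert contact_value(p.d_lo, p) == pytest.approx(1.0)
        assert contact_value(p.d_hi, p) == pytest.approx(0.0)
        assert contact_value(0.5 * (p.d_lo + p.d_hi), p) == pytest.approx(0.5)
        assert contact_value(0.0, p) == 1.0
        assert contact_value(50.0, p) == 0.0

    def test_orientation_breaks_distance_tie(self):
        """Two pairs at the same 7.4 A separation: the one whose relative
        rotation is nearer the preferred one scores strictly higher."""
        q_star = Rotation.from_euler("z", 0.3)
        p = _params(d_lo=5.0, d_hi=9.0, quat=q_star.as_quat())
        d = 7.4
        near = relative_pose(q_star.as_matrix(), np.eye(3), d, p)   # theta ~ 0
        far = relative_pose(Rotation.from_euler("y", 0.9).as_matrix(),
                            np.eye(3), d, p)
        assert near.theta < far.theta < np.pi
        w_near = contact_value(pose_distance(near, p, 4), p)
        w_far = contact_value(pose_distance(far, p, 4), p)
        assert w_near > w_far


class TestTable:
    def test_swap_symmetry(self):
        q = Rotation.from_euler("xyz", [0.4, -0.2, 0.9]).as_quat()
        table = ContactParameterTable()
        table.entries[("A", "G", 3)] = _params(quat=q)
        ag = table.lookup("A", "G", 3)
        ga = table.lookup("G", "A", 3)
        assert ag.d_lo == ga.d_lo and ag.d_hi == ga.d_hi
        q_ab = Rotation.from_quat(ag.preferred_rotation)
        q_ba = Rotation.from_quat(ga.preferred_rotation)
        np.testing.assert_allclose((q_ab * q_ba).magnitude(), 0.0, atol=1e-12)

    def test_backoff_to_pooled(self, table):
        specific = {k for k in table.entries if k[0] != ANY}
        assert ("W", "W", "long") not in specific
        p = table.lookup("W", "W", "long")
        assert p is table.entries[(ANY, ANY, "long")]

    def test_missing_backoff_raises(self):
        with pytest.raises(KeyError):
            ContactParameterTable().lookup("A", "A", 2)

    def test_serialization_preserves_contact_values(self, table, tmp_path, rng):
        """A table serialized and re-read yields identical omega on random
        (d, theta, pair, range) evaluations."""
        path = tmp_path / "table.json"
        table.to_json(path)
        table2 = ContactParameterTable.from_json(path)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(2000):
            a, b = rng.choice(list(aas), 2)
            rng_cls = [1, 2, 3, 4, "long"][rng.integers(5)]
            p1 = table.lookup(a, b, rng_cls)
            p2 = table2.lookup(a, b, rng_cls)
            d = float(rng.uniform(0, 14))
            theta = float(rng.uniform(0, np.pi)) if p1.theta_max else None
            w1 = contact_value(pose_distance(RelativePose(d, theta), p1, rng_cls), p1)
            w2 = contact_value(pose_distance(RelativePose(d, theta), p2, rng_cls), p2)
            assert w1 == w2


class TestPairContact:
    def test_deterministic_and_in_unit_interval(self, table, helix15):
        vals = [pair_contact(helix15, i, j, table)
                for i in range(1, 8) for j in range(i + 1, 15)]
        assert all(0.0 <= v <= 1.0 for v in vals)
        again = [pair_contact(helix15, i, j, table)
                 for i in range(1, 8) for j in range(i + 1, 15)]
        assert vals == again

    def test_long_range_depends_on_distance_only(self, table, helix15, rng):
        """Rotating residue frames at fixed site positions cannot change a
        long-range contact value."""
        conf = build_chain([(-70, 130)] * 12)
        w0 = pair_contact(conf, 1, 9, table)
        # re-orient residue 1's N and C about its CA: frames change, CB kept
        c = conf.coords.copy()
        R = Rotation.from_euler("z", 1.1).as_matrix()
        ca = c[0, 1]
        for slot in (0, 2, 3):
            c[0, slot] = (c[0, slot] - ca) @ R.T + ca
        rotated = type(conf)(conf.sequence, c)
        assert pair_contact(rotated, 1, 9, table) == w0

    def test_range_classes_use_distinct_intervals(self, table, helix15):
        """Same geometry, different sequence separation: contact values
        differ whenever the range-class intervals differ."""
        p3 = table.lookup("A", "A", 3)
        p4 = table.lookup("A", "A", 4)
        assert (p3.d_lo, p3.d_hi) != (p4.d_lo, p4.d_hi)

    def test_requires_ordered_pair(self, table, helix15):
        with pytest.raises(IndexError):
            pair_contact(helix15, 9, 3, table)


class TestEstimation:
    def test_helical_reference_gives_tight_short_range_params(self, rng):
        """Ideal alpha-helices concentrate ranges 3-4 below 9 A with a
        dominant relative orientation (theta_max < pi/2), verified against
        a brute-force distance scan over the generated helices."""
        helices = [build_chain(
            [(HELIX_PHI_PSI[0] + rng.normal(0, 4),
              HELIX_PHI_PSI[1] + rng.normal(0, 4)) for _ in range(25)])
            for _ in range(40)]
        table = estimate_parameters(helices)
        for rng_cls in (3, 4):
            p = table.lookup("A", "A", rng_cls)
            assert 0 < p.d_lo < p.d_hi < 9.0
            assert p.theta_max < np.pi / 2
            # oracle: every range-rng_cls distance in the data
            dists = []
            for h in helices:
                sites = h.interaction_sites
                for i in range(25 - rng_cls):
                    dists.append(np.linalg.norm(sites[i] - sites[i + rng_cls]))
            assert np.quantile(dists, 0.2) >= p.d_lo - 1.0
            assert np.quantile(dists, 0.8) <= p.d_hi + 1.0

    def test_single_structure_min_support_one(self):
        conf = build_chain([HELIX_PHI_PSI] * 10)
        table = estimate_parameters(
            [conf], EstimationSettings(min_support=1))
        sites = conf.interaction_sites
        d = np.linalg.norm(sites[0] - sites[3])
        p = table.lookup("A", "A", 3)
        assert p.d_lo - 1.0 < d < p.d_hi + 1.0

    def test_empty_reference_raises(self):
        with pytest.raises(EstimationError):
            estimate_parameters([])

    def test_no_short_maximum_raises(self):
        far = np.random.default_rng(0).uniform(12.5, 13.9, 500)
        with pytest.raises(EstimationError, match="density maximum"):
            estimate_pair_params(far)
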