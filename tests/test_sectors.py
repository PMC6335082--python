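import math

import numpy as np
import pytest

from dendrorient.circstats import circular_distance, wrap_angle
from dendrorient.errors import GeometryError
from dendrorient.io import DIRECTIONS, SegmentCloud
from dendrorient.sectors import assign_sectors, build_partition, signed_angle

from conftest import cloud_from_alphas


class TestSignedAngle:
    def test_parallel(self):
        assert signed_angle((1, 0), (1, 0)) == 0.0

    def test_counterclockwise_positive(self):
        assert signed_angle((1, 0), (0, 1)) == pytest.approx(math.pi / 2)

    def test_antiparallel_maps_to_plus_pi(self):
        assert signed_angle((1, 0), (-1, 0)) == pytest.approx(math.pi)

    def test_zero_vector_rejected(self):
        with pytest.raises(GeometryError):
            signed_angle((1, 0), (0, 0))

    def test_matches_angle_difference_oracle(self, rng):
        """500 random pairs vs wrap(atan2(v) - atan2(a))."""
        for _ in range(500):
            a = rng.normal(size=2)
            v = rng.normal(size=2)
            if np.linalg.norm(a) < 1e-6 or np.linalg.norm(v) < 1e-6:
                continue
            expect = wrap_angle(math.atan2(v[1], v[0]) - math.atan2(a[1], a[0]))
            assert circular_distance(signed_angle(a, v), expect) < 1e-9


class TestBuildPartition:
    def test_symmetric_frame(self, symmetric_partition):
        ps = symmetric_partition.arc_fractions
        assert ps == pytest.approx({j: 0.25 for j in DIRECTIONS})
        assert symmetric_partition.ray_angles["posterior"] == 0.0
        # rays at 90 degree spacing
        for j in DIRECTIONS:
            others = [k for k in DIRECTIONS if k != j]
            gaps = sorted(
                circular_distance(
                    symmetric_partition.ray_angles[j],
                    symmetric_partition.ray_angles[k],
                )
                for k in others
            )
            assert gaps == pytest.approx([math.pi / 2, math.pi / 2, math.pi])

    def test_soma_displaced_toward_anterior(self):
        """Hand-derived bisector geometry for a displaced soma.

        Refs at unit N/E/S/W, soma at (0.5, 0): the dorsal/ventral rays
        rotate toward the posterior ray, so the anterior sector widens to
        (pi - arctan 2) on each side's bisector half and the posterior
        sector shrinks to arctan(2).
        """
        refs = {
            "posterior": (-1.0, 0.0), "anterior": (1.0, 0.0),
            "dorsal": (0.0, 1.0), "ventral": (0.0, -1.0),
        }
        part = build_partition((0.5, 0.0), refs)
        ps = part.arc_fractions
        two_pi = 2 * math.pi
        assert ps["anterior"] == pytest.approx((math.pi - math.atan(2)) / two_pi)
        assert ps["posterior"] == pytest.approx(math.atan(2) / two_pi)
        assert ps["dorsal"] == pytest.approx(0.25)
        assert ps["ventral"] == pytest.approx(0.25)
        assert sum(ps.values()) == pytest.approx(1.0, abs=1e-12)

    def test_reference_point_on_soma_rejected(self, symmetric_refs):
        refs = dict(symmetric_refs, dorsal=(3.0, -4.0))
        with pytest.raises(GeometryError):
            build_partition((3.0, -4.0), refs)

    def test_coincident_rays_rejected(self):
        refs = {
            "posterior": (-1.0, 0.0), "anterior": (1.0, 0.0),
            "dorsal": (2.0, 0.0), "ventral": (0.0, -1.0),
        }
        with pytest.raises(GeometryError):
            build_partition((0.0, 0.0), refs)

    def test_partition_of_unity_random_maps(self, rng):
        for _ in range(300):
            soma = rng.normal(0, 100, size=2)
            refs = {
                j: soma + rng.normal(0, 500, size=2)
                for j in DIRECTIONS
            }
            try:
                part = build_partition(soma, refs)
            except GeometryError:
                continue
            assert sum(part.arc_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_rays_mode_partition(self, symmetric_refs):
        part = build_partition((0.0, 0.0), symmetric_refs, mode="rays")
        assert sum(part.arc_fractions.values()) == pytest.approx(1.0, abs=1e-12)
        # each sector's lower boundary is its own ray (half-open arcs)
        for j in DIRECTIONS:
            assert str(part.sector_of(part.ray_angles[j])[0]) == j


class TestAssignSectors:
    def test_point_due_anterior(self, symmetric_partition):
        cloud = cloud_from_alphas([math.pi], symmetric_partition)
        asg = assign_sectors(cloud, symmetric_partition)
        assert asg.counts["anterior"] == 1

    def test_counts_match_brute_force_arc_membership(self, symmetric_partition, rng):
        """Nearest-ray membership is an independent oracle in bisector mode."""
        alphas = wrap_angle(rng.uniform(-math.pi, math.pi, size=1000))
        cloud = cloud_from_alphas(alphas, symmetric_partition)
        asg = assign_sectors(cloud, symmetric_partition)
        rays = symmetric_partition.ray_angles
        brute = {j: 0 for j in DIRECTIONS}
        for a in alphas:
            brute[min(DIRECTIONS, key=lambda j: circular_distance(a, rays[j]))] += 1
        assert asg.counts == brute
        assert asg.total == 1000

    def test_boundary_belongs_to_counterclockwise_sector(self, symmetric_partition):
        # boundaries at +/-45, +/-135 degrees relative to the posterior ray
        lab_on = str(symmetric_partition.sector_of(-math.pi / 4)[0])
        lab_below = str(symmetric_partition.sector_of(-math.pi / 4 - 1e-9)[0])
        assert lab_on == "posterior"
        assert lab_below != "posterior"

    def test_soma_coincident_point_skipped(self, symmetric_partition):
        pts = np.array([[0.0, 0.0], [10.0, 0.0]])
        cloud = SegmentCloud(points=pts, soma=np.zeros(2), step=0.5)
        asg = assign_sectors(cloud, symmetric_partition)
        assert asg.n_skipped == 1
        assert asg.total == 1

    def test_frame_rotation_equivariance(self, rng):
        """Rotating the whole map changes no PS value and no label."""
        soma = np.array([30.0, -20.0])
        refs = {j: soma + rng.normal(0, 300, size=2) for j in DIRECTIONS}
        pts = soma + rng.normal(0, 60, size=(400, 2))
        part = build_partition(soma, refs)
        cloud = SegmentCloud(points=pts, soma=soma, step=0.5)
        asg = assign_sectors(cloud, part)

        phi = 1.234
        rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        soma_r = rot @ soma
        refs_r = {j: rot @ np.asarray(refs[j]) for j in DIRECTIONS}
        part_r = build_partition(soma_r, refs_r)
        cloud_r = SegmentCloud(points=(rot @ pts.T).T, soma=soma_r, step=0.5)
        asg_r = assign_sectors(cloud_r, part_r)

        for j in DIRECTIONS:
            assert part_r.arc_fractions[j] == pytest.approx(part.arc_fractions[j], abs=1e-9)
        assert list(asg_r.labels) == list(asg.labels)
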