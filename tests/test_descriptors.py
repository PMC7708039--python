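"""DNA geometry descriptors: generator round trips and invariances."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fretscape import DuplexSpec, StructureModel, build_duplex, build_ensemble
from fretscape.descriptors import (
    MissingAtomsError,
    base_extrusion_dihedral,
    basepair_frames,
    bend_angle,
    bend_direction_dihedral,
    block_average,
    block_scan,
    cumulative_twist,
    hydrogen_bonds,
    step_twist,
    twist_series,
    untwist_angle,
)
from fretscape.synthetic import MAJOR_GROOVE, MINOR_GROOVE

SEQ24 = "ACGTACGTACGTACGTACGTACGT"


def wrap(angle):
    return (angle + 180.0) % 360.0 - 180.0


class TestFramesAndTwist:
    def test_frames_are_orthonormal(self, straight_duplex):
        for f in basepair_frames(straight_duplex):
            basis = np.stack([f.x, f.y, f.z])
            assert np.allclose(basis @ basis.T, np.eye(3), atol=1e-6)
            assert np.linalg.det(basis) == pytest.approx(1.0, abs=1e-6)

    def test_ideal_duplex_step_twist(self, straight_duplex):
        frames = basepair_frames(straight_duplex)
        for k in range(1, len(frames)):
            assert step_twist(frames, k) == pytest.approx(36.0, abs=0.1)

    def test_cumulative_twist_additivity(self):
        m = build_duplex(DuplexSpec(SEQ24, twist=30.0))
        frames = basepair_frames(m)
        assert cumulative_twist(frames, 14, 19) == pytest.approx(150.0,
                                                                 abs=0.5)
        # additivity is exact: the cumulative equals the sum of its steps
        total = sum(step_twist(frames, k) for k in range(14, 19))
        assert cumulative_twist(frames, 14, 19) == pytest.approx(total,
                                                                 abs=1e-9)

    def test_injected_untwist_is_recovered_at_its_step(self):
        m = build_duplex(DuplexSpec(SEQ24, untwist_steps=((7, 15.0),)))
        frames = basepair_frames(m)
        assert step_twist(frames, 7) == pytest.approx(21.0, abs=0.5)
        for k in (5, 6, 8, 9):
            assert step_twist(frames, k) == pytest.approx(36.0, abs=0.5)

    def test_traversal_reversal_flips_twist_sign(self, straight_duplex):
        """Walking the same frames 3'->5' negates every signed step twist."""
        fwd = basepair_frames(straight_duplex)
        rev = fwd[::-1]
        n = len(fwd)
        for k in range(1, n):
            assert step_twist(rev, k) == pytest.approx(
                -step_twist(fwd, n - k), abs=1e-6
            )

    def test_missing_c1_atoms_are_reported(self, straight_duplex):
        m = straight_duplex
        keep = ~(
            (m.atoms["chain"] == "W")
            & (m.atoms["resid"] == 16)
            & (m.atoms["name"] == "C1'")
        ).to_numpy()
        broken = StructureModel(
            m.atoms[keep].reset_index(drop=True), m.coords[:, keep],
            m.pairing,
        )
        with pytest.raises(MissingAtomsError, match="W:16:C1'"):
            basepair_frames(broken)


class TestUntwistAngle:
    def test_plain_arithmetic(self):
        series = untwist_angle([165.0], 180.0)
        assert series.values[0] == pytest.approx(15.0)
        assert untwist_angle([180.0], 180.0).values[0] == pytest.approx(0.0)

    def test_reference_subensemble_and_drift_recovery(self):
        # ensemble whose 6-mer untwists by 0.2 deg per model at one step
        drift = [0.2 * m for m in range(20)]
        specs = [
            DuplexSpec(SEQ24, untwist_steps=((16, d),)) for d in drift
        ]
        ens = build_ensemble(specs)
        twists = twist_series(ens, 14, 19)
        ref = twists[:5]  # first-quarter reference
        series = untwist_angle(twists, ref)
        expected = np.array(drift) - np.mean(drift[:5])
        assert np.allclose(series.values, expected, atol=1e-6)

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            untwist_angle([150.0], np.array([]))


class TestBending:
    @pytest.mark.parametrize("bend, tol", [(20.0, 1.0), (40.0, 1.5)])
    def test_injected_bend_is_recovered(self, bend, tol):
        m = build_duplex(DuplexSpec(SEQ24, bends=((12, bend, MINOR_GROOVE),)))
        assert bend_angle(m, 12, 5) == pytest.approx(bend, abs=tol)

    def test_straight_helix_direction_is_undefined(self, straight_duplex):
        assert bend_direction_dihedral(straight_duplex, 12, 5) is None

    def test_minor_groove_bend_is_negative(self):
        m = build_duplex(DuplexSpec(SEQ24, bends=((12, 20.0, MINOR_GROOVE),)))
        d = bend_direction_dihedral(m, 12, 5)
        assert d is not None and d < 0

    def test_major_groove_bend_flips_the_sign(self):
        minor = build_duplex(
            DuplexSpec(SEQ24, bends=((12, 20.0, MINOR_GROOVE),))
        )
        major = build_duplex(
            DuplexSpec(SEQ24, bends=((12, 20.0, MAJOR_GROOVE),))
        )
        d_minor = bend_direction_dihedral(minor, 12, 5)
        d_major = bend_direction_dihedral(major, 12, 5)
        assert d_minor < 0 < d_major
        assert abs(abs(d_minor) - abs(d_major)) < 5.0

    def test_insufficient_arms_error(self, straight_duplex):
        with pytest.raises(ValueError, match="insufficient arm"):
            bend_angle(straight_duplex, 3, 5)


class TestBaseExtrusion:
    def test_baseline_identical_for_interior_sites(self):
        m = build_duplex(DuplexSpec("CCCCCCCCCCCC"))
        values = [base_extrusion_dihedral(m, i) for i in range(3, 10)]
        assert max(values) - min(values) < 0.5

    @pytest.mark.parametrize("rotation", [90.0, -90.0])
    def test_rotation_shifts_dihedral_by_rotation(self, rotation):
        base = build_duplex(DuplexSpec("CCCCCCCCCCCC"))
        theta0 = base_extrusion_dihedral(base, 6)
        rotated = build_duplex(
            DuplexSpec("CCCCCCCCCCCC", base_rotations=((6, rotation),))
        )
        shift = wrap(base_extrusion_dihedral(rotated, 6) - theta0)
        assert abs(abs(shift) - 90.0) < 2.0

    def test_opposite_rotations_are_sign_symmetric(self):
        base = build_duplex(DuplexSpec("CCCCCCCCCCCC"))
        theta0 = base_extrusion_dihedral(base, 6)
        plus = build_duplex(
            DuplexSpec("CCCCCCCCCCCC", base_rotations=((6, 90.0),))
        )
        minus = build_duplex(
            DuplexSpec("CCCCCCCCCCCC", base_rotations=((6, -90.0),))
        )
        s_plus = wrap(base_extrusion_dihedral(plus, 6) - theta0)
        s_minus = wrap(base_extrusion_dihedral(minus, 6) - theta0)
        assert s_plus == pytest.approx(-s_minus, abs=2.0)


class TestHydrogenBonds:
    def test_ideal_gc_pair_has_three_watson_crick_bonds(self):
        m = build_duplex(DuplexSpec("G"))
        bonds = hydrogen_bonds(m)
        found = {(b.donor[2], b.acceptor[2]) for b in bonds}
        assert found == {("N1", "N3"), ("N2", "O2"), ("N4", "O6")}
        assert all(2.5 < b.distance <= 3.5 for b in bonds)

    def test_at_pair_has_two_bonds(self):
        m = build_duplex(DuplexSpec("A"))
        assert len(hydrogen_bonds(m)) == 2

    def test_separated_pair_has_no_bonds(self):
        m = build_duplex(DuplexSpec("G"))
        mask = (m.atoms["chain"] == "Y").to_numpy()
        coords = m.coords.copy()
        coords[:, mask] += np.array([0.0, 2.0, 0.0])
        apart = StructureModel(m.atoms, coords, m.pairing)
        assert hydrogen_bonds(apart) == []

    def test_tight_cutoff_excludes_ideal_geometry(self):
        m = build_duplex(DuplexSpec("G"))
        assert hydrogen_bonds(m, d_max=2.5) == []

    def test_full_duplex_bond_count(self):
        m = build_duplex(DuplexSpec("ACGT"))
        assert len(hydrogen_bonds(m)) == 10  # 2 + 3 + 3 + 2


class TestRigidMotionInvariance:
    def test_descriptors_invariant_under_rigid_transforms(self):
        spec = DuplexSpec(
            SEQ24,
            untwist_steps=((7, 15.0),),
            bends=((12, 20.0, MINOR_GROOVE),),
            base_rotations=((16, 45.0),),
        )
        m = build_duplex(spec)
        frames = basepair_frames(m)
        ref = (
            cumulative_twist(frames, 14, 19),
            bend_angle(m, 12, 5),
            bend_direction_dihedral(m, 12, 5),
            base_extrusion_dihedral(m, 16),
        )
        rng = np.random.default_rng(7)
        for _ in range(3):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.uniform(-50, 50, 3)
            moved = m.transformed(R, t)
            frames_m = basepair_frames(moved)
            got = (
                cumulative_twist(frames_m, 14, 19),
                bend_angle(moved, 12, 5),
                bend_direction_dihedral(moved, 12, 5),
                base_extrusion_dihedral(moved, 16),
            )
            for a, b in zip(ref, got):
                assert a == pytest.approx(b, abs=1e-6)


class TestBlockAverage:
    def test_constant_series_has_zero_sd(self):
        mean, sd = block_average(np.full(100, 3.7), 5)
        assert mean == pytest.approx(3.7)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_iid_noise_matches_sigma_over_sqrt_block_length(self):
        rng = np.random.default_rng(0)
        sigma, n, blocks = 2.0, 10_000, 50
        series = rng.normal(0.0, sigma, n)
        _, sd = block_average(series, blocks)
        expected = sigma / np.sqrt(n // blocks)
        assert sd == pytest.approx(expected, rel=0.20)

    def test_correlated_series_exceeds_iid_prediction(self):
        rng = np.random.default_rng(1)
        phi, n = 0.9, 10_000
        eps = rng.normal(0.0, 1.0, n)
        series = np.empty(n)
        series[0] = eps[0]
        for i in range(1, n):
            series[i] = phi * series[i - 1] + eps[i]
        marginal_sd = series.std()
        _, sd = block_average(series, 50)
        iid_prediction = marginal_sd / np.sqrt(n // 50)
        assert sd > 1.5 * iid_prediction

    def test_remainder_is_discarded(self):
        series = np.arange(103, dtype=float)
        mean, _ = block_average(series, 10)
        assert mean == pytest.approx(np.arange(100).mean())

    def test_length_validation(self):
        with pytest.raises(ValueError):
            block_average([1.0, 2.0], 3)
        with pytest.raises(ValueError):
            block_average(np.arange(10.0), 1)

    def test_block_scan_returns_requested_counts(self):
        scan = block_scan(np.random.default_rng(2).normal(size=1000))
        assert set(scan) == {2, 4, 5, 8, 10}
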