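"""Both recovery schemes, the error ratio, and the comparison metrics."""

import numpy as np
import pytest

from femtfm import (
    ClusterMask,
    GeometryError,
    InputError,
    NonConvergenceError,
    SurfaceDisplacementField,
    TractionField,
    add_displacement_noise,
    cluster_net_force,
    error_ratio,
    forward_surface_displacements,
    make_two_cell_fixture,
    recover_mixed,
    recover_whole_field_iterative,
    rms_difference,
)
from tests.conftest import SMALL, max_force_error


class TestRecoverMixed:
    def test_round_trip_recovers_prescribed_forces(self, small_fixture, small_roundtrip):
        # the computational uniqueness property: displacements generated by
        # a known force field give back that field at solver precision
        tf, rep = small_roundtrip
        peak = np.hypot(small_fixture.fx, small_fixture.fy).max()
        assert max_force_error(tf, small_fixture) < 1e-9 * peak

    def test_traction_free_region_is_exactly_zero(self, small_fixture, small_roundtrip):
        tf, _ = small_roundtrip
        outside = small_fixture.labels == 0
        assert np.abs(tf.fx[outside]).max() == 0.0
        assert np.abs(tf.ty[outside]).max() == 0.0

    def test_zero_displacement_gives_zero_traction(self, small_fixture):
        g = small_fixture.grid
        zero = SurfaceDisplacementField(g, np.zeros(g.shape), np.zeros(g.shape))
        tf, rep = recover_mixed(
            zero, small_fixture.mask(), small_fixture.substrate, min_margin=SMALL["margin"]
        )
        assert np.abs(tf.fx).max() < 1e-12
        assert all(np.isnan(e) for e in rep.error_ratios.values())

    def test_linearity(self, small_fixture, small_disp, small_roundtrip):
        tf, _ = small_roundtrip
        tf2, _ = recover_mixed(
            small_disp.in_plane().scaled(2.0),
            small_fixture.mask(),
            small_fixture.substrate,
            min_margin=SMALL["margin"],
        )
        np.testing.assert_allclose(tf2.fx, 2 * tf.fx, atol=1e-10)
        np.testing.assert_allclose(tf2.ty, 2 * tf.ty, atol=1e-10)

    def test_superposition(self, small_fixture, small_disp):
        # recovery of (A + B) equals recovery(A) + recovery(B)
        rng = np.random.default_rng(2)
        g = small_fixture.grid
        other = SurfaceDisplacementField(
            g, 0.01 * rng.normal(size=g.shape), 0.01 * rng.normal(size=g.shape)
        )
        mask, sub = small_fixture.mask(), small_fixture.substrate
        kw = dict(min_margin=SMALL["margin"])
        tf_a, _ = recover_mixed(small_disp.in_plane(), mask, sub, **kw)
        tf_b, _ = recover_mixed(other, mask, sub, **kw)
        both = SurfaceDisplacementField(
            g, small_disp.ux + other.ux, small_disp.uy + other.uy
        )
        tf_ab, _ = recover_mixed(both, mask, sub, **kw)
        np.testing.assert_allclose(tf_ab.fx, tf_a.fx + tf_b.fx, atol=1e-9)
        np.testing.assert_allclose(tf_ab.fy, tf_a.fy + tf_b.fy, atol=1e-9)

    def test_mask_enlargement_changes_little(self, small_fixture, small_disp):
        # uniqueness in practice: a larger prescription region enclosing
        # the true support leaves the recovered traction nearly unchanged
        from scipy import ndimage

        mask = small_fixture.mask()
        lab = ndimage.grey_dilation(mask.labels, size=(3, 3))
        lab = np.where(mask.labels > 0, mask.labels, lab)
        enlarged = ClusterMask(mask.grid, lab)
        tf_true, _ = recover_mixed(
            small_disp.in_plane(), mask, small_fixture.substrate, min_margin=SMALL["margin"]
        )
        tf_enl, _ = recover_mixed(
            small_disp.in_plane(), enlarged, small_fixture.substrate, min_margin=0.0
        )
        peak = np.hypot(tf_true.tx, tf_true.ty).max()
        sel = mask.labels > 0
        rms = np.sqrt(
            np.mean((tf_true.tx - tf_enl.tx)[sel] ** 2 + (tf_true.ty - tf_enl.ty)[sel] ** 2)
        )
        assert rms <= 0.06 * peak

    def test_invalid_labeled_node_rejected(self, small_fixture, small_disp):
        bad = SurfaceDisplacementField(
            small_disp.grid,
            small_disp.ux.copy(),
            small_disp.uy.copy(),
            valid=small_disp.valid.copy(),
        )
        j, i = np.argwhere(small_fixture.labels > 0)[0]
        bad.valid[j, i] = False
        with pytest.raises(InputError):
            recover_mixed(
                bad, small_fixture.mask(), small_fixture.substrate, min_margin=SMALL["margin"]
            )

    def test_mask_near_wall_rejected(self, small_fixture, small_disp):
        with pytest.raises(GeometryError):
            recover_mixed(small_disp.in_plane(), small_fixture.mask(), small_fixture.substrate)

    def test_low_poisson_needs_uz(self, small_disp):
        f = make_two_cell_fixture(poissons_ratio=0.3, **SMALL)
        d = forward_surface_displacements(f)
        with pytest.raises(InputError):
            recover_mixed(d.in_plane(), f.mask(), f.substrate, min_margin=SMALL["margin"])
        # with full 3D data the recovery runs and is exact
        tf, _ = recover_mixed(d, f.mask(), f.substrate, min_margin=SMALL["margin"])
        assert max_force_error(tf, f) < 1e-9

    def test_smoothing_runs_and_changes_result(self, small_fixture, small_disp):
        noisy = add_displacement_noise(small_disp.in_plane(), 0.005, seed=0)
        kw = dict(min_margin=SMALL["margin"])
        tf_raw, _ = recover_mixed(noisy, small_fixture.mask(), small_fixture.substrate, **kw)
        tf_sm, _ = recover_mixed(
            noisy, small_fixture.mask(), small_fixture.substrate, smooth_sigma=1.0, **kw
        )
        assert np.abs(tf_raw.fx - tf_sm.fx).max() > 0


class TestIterativeWholeField:
    def test_zero_field_converges_immediately(self, small_fixture):
        g = small_fixture.grid
        zero = SurfaceDisplacementField(g, np.zeros(g.shape), np.zeros(g.shape))
        tf, rep = recover_whole_field_iterative(
            zero, small_fixture.mask(), small_fixture.substrate, min_margin=SMALL["margin"]
        )
        assert rep.iterations == 1
        assert np.abs(tf.fx).max() == 0.0

    def test_noiseless_round_trip(self, small_fixture, small_disp):
        tf, rep = recover_whole_field_iterative(
            small_disp, small_fixture.mask(), small_fixture.substrate,
            min_margin=SMALL["margin"],
        )
        peak = np.hypot(small_fixture.fx, small_fixture.fy).max()
        assert max_force_error(tf, small_fixture) <= 0.02 * peak
        assert rep.iterations <= 50
        assert len(rep.residual_history) == rep.iterations - 1 or rep.iterations == 1

    def test_agrees_with_mixed_recovery(self, small_fixture, small_disp, small_roundtrip):
        tf_mixed, _ = small_roundtrip
        tf_iter, _ = recover_whole_field_iterative(
            small_disp, small_fixture.mask(), small_fixture.substrate,
            min_margin=SMALL["margin"],
        )
        _, d_force = rms_difference(tf_mixed, tf_iter, small_fixture.mask())
        peak = tf_mixed.force_magnitude().max()
        assert d_force <= 0.05 * peak

    def test_missing_extracellular_data_rejected(self, small_fixture, small_disp):
        partial = SurfaceDisplacementField(
            small_disp.grid,
            small_disp.ux.copy(),
            small_disp.uy.copy(),
            valid=(small_fixture.labels > 0),
        )
        with pytest.raises(InputError):
            recover_whole_field_iterative(
                partial, small_fixture.mask(), small_fixture.substrate,
                min_margin=SMALL["margin"],
            )

    def test_nonconvergence_carries_history(self, small_fixture, small_disp):
        noisy = add_displacement_noise(small_disp, 0.02, seed=3)
        with pytest.raises(NonConvergenceError) as exc:
            recover_whole_field_iterative(
                noisy, small_fixture.mask(), small_fixture.substrate,
                rms_tol=1e-12, max_iter=3, min_margin=SMALL["margin"],
            )
        assert len(exc.value.history) >= 1


def _tf_from(grid, fx, fy, labels):
    return TractionField.from_nodal_forces(grid, fx, fy, None, labels)


class TestMetrics:
    @pytest.fixture
    def dipole(self, small_fixture):
        g = small_fixture.grid
        fx = np.zeros(g.shape)
        lab = np.zeros(g.shape, dtype=int)
        fx[3, 3], fx[3, 5] = 2.0, -2.0
        lab[3, 3] = lab[3, 5] = 1
        return _tf_from(g, fx, np.zeros(g.shape), lab)

    def test_error_ratio_perfect_dipole(self, dipole):
        assert error_ratio(dipole, 1) == 0.0

    def test_error_ratio_single_force_is_one(self, small_fixture):
        g = small_fixture.grid
        fx = np.zeros(g.shape)
        lab = np.zeros(g.shape, dtype=int)
        fx[2, 2] = 1.5
        lab[2, 2] = 1
        assert error_ratio(_tf_from(g, fx, np.zeros(g.shape), lab), 1) == 1.0

    def test_error_ratio_zero_cluster_flagged(self, small_fixture):
        g = small_fixture.grid
        lab = np.zeros(g.shape, dtype=int)
        lab[2, 2] = 1
        tf = _tf_from(g, np.zeros(g.shape), np.zeros(g.shape), lab)
        assert np.isnan(error_ratio(tf, 1))
        with pytest.raises(InputError):
            error_ratio(tf, 9)

    def test_net_force_bookkeeping(self, small_fixture):
        g = small_fixture.grid
        fx, fy = np.zeros(g.shape), np.zeros(g.shape)
        lab = np.zeros(g.shape, dtype=int)
        fx[2, 2], fy[2, 3] = 1.0, -2.0
        lab[2, 2] = lab[2, 3] = 3
        net = cluster_net_force(_tf_from(g, fx, fy, lab), 3)
        np.testing.assert_allclose(net, [1.0, -2.0, 0.0])

    def test_rms_difference_identities(self, dipole, small_fixture):
        assert rms_difference(dipole, dipole) == (0.0, 0.0)
        doubled = dipole.scaled(2.0)
        region = ClusterMask(dipole.grid, dipole.labels)
        dt, df = rms_difference(dipole, doubled, region)
        # |2a − a| = |a|: the RMS difference equals the RMS magnitude
        assert df == pytest.approx(np.sqrt(np.mean(dipole.force_magnitude()[dipole.labels > 0] ** 2)))
        assert dt > 0

    def test_rms_difference_grid_mismatch(self, dipole):
        from femtfm import AlignmentError, SurfaceGrid

        other = _tf_from(
            SurfaceGrid(4, 4, 1.0, 1.0), np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((4, 4), int)
        )
        with pytest.raises(AlignmentError):
            rms_difference(dipole, other)
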