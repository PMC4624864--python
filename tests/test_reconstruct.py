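"""Image processing and FTTC inversion."""

import numpy as np
import pytest
from scipy import fft as spfft
from scipy import ndimage as ndi

from gctfm import (
    GelSubstrate,
    TractionMap,
    compute_reference_image,
    compute_traction,
    correct_drift,
    forward_displacement,
    make_grid,
    measure_displacements,
    project_stack,
    render_bead_images,
    youngs_modulus_from_storage,
)


class TestYoungsModulus:
    @pytest.mark.parametrize(
        "gprime,nu,expected",
        [(100.0, 0.45, 290.0), (100.0, 0.0, 200.0), (0.0, 0.45, 0.0)],
    )
    def test_formula(self, gprime, nu, expected):
        assert youngs_modulus_from_storage(gprime, nu) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            youngs_modulus_from_storage(-1.0, 0.45)
        with pytest.raises(ValueError):
            youngs_modulus_from_storage(100.0, 0.5)
        with pytest.raises(ValueError):
            GelSubstrate(E=290.0, nu=0.6)

    def test_substrate_from_storage(self):
        gel = GelSubstrate.from_storage_modulus(100.0, 0.45)
        assert gel.E == pytest.approx(290.0)
        assert gel.g_prime == pytest.approx(100.0)


class TestProjectStack:
    def test_flat_single_slice_unchanged(self):
        img = np.full((20, 20), 7.0)
        np.testing.assert_allclose(project_stack(img[None]), img)

    def test_max_projection_keeps_disjoint_spots(self):
        z = np.zeros((2, 21, 21))
        z[0, 5:8, 5:8] = 5.0  # extended spots survive a 3x3 median
        z[1, 14:17, 14:17] = 7.0
        proj = project_stack(z)
        assert proj[6, 6] == 5.0 and proj[15, 15] == 7.0

    def test_median_removes_impulse_noise(self):
        z = np.zeros((1, 20, 20))
        z[0, 10, 10] = 100.0
        assert project_stack(z)[10, 10] == 0.0

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            project_stack(np.zeros((0, 10, 10)))


class TestCorrectDrift:
    def test_rigid_integer_shift_detected(self, rng):
        base = rng.random((100, 100))
        shifted = ndi.shift(base, (2, 3), order=1, mode="nearest")
        corrected, shifts = correct_drift(np.stack([base, shifted]))
        np.testing.assert_allclose(shifts[1], [2, 3], atol=0.1)
        inner = np.s_[10:-10, 10:-10]
        assert np.abs(corrected[1][inner] - base[inner]).max() < 0.05

    def test_identical_frames_zero_shift(self, rng):
        base = rng.random((60, 60))
        _, shifts = correct_drift(np.stack([base, base, base]))
        np.testing.assert_allclose(shifts, 0, atol=1e-3)

    def test_componentwise_median_is_outlier_robust(self):
        # three corners say (2, 2); the median must ignore one outlier corner
        estimates = np.array([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0], [9.0, 0.0]])
        np.testing.assert_allclose(np.median(estimates, axis=0), [2.0, 2.0])

    def test_flat_corner_excluded_with_warning(self, rng):
        base = rng.random((100, 100))
        base[:25, :25] = 0.5  # featureless corner
        shifted = ndi.shift(base, (1, 1), order=1, mode="nearest")
        with pytest.warns(UserWarning):
            _, shifts = correct_drift(np.stack([base, shifted]))
        np.testing.assert_allclose(shifts[1], [1, 1], atol=0.2)

    def test_single_frame_rejected(self, rng):
        with pytest.raises(ValueError):
            correct_drift(rng.random((1, 50, 50)))


class TestReferenceImage:
    def test_constant_series(self, rng):
        img = rng.random((30, 30))
        np.testing.assert_allclose(
            compute_reference_image(np.stack([img] * 5)), img
        )

    def test_pixel_course_median(self):
        series = np.zeros((3, 4, 4))
        series[0, 1, 1], series[1, 1, 1], series[2, 1, 1] = 1.0, 2.0, 9.0
        assert compute_reference_image(series)[1, 1] == 2.0

    def test_transient_excursion_removed(self, rng):
        """A bead displaced in fewer than half the frames leaves the
        temporal median at its rest value."""
        rest = rng.random((40, 40))
        moved = np.roll(rest, 3, axis=0)
        series = np.stack([rest, rest, rest, moved, moved])
        np.testing.assert_allclose(compute_reference_image(series), rest)

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_reference_image(rng.random((2, 20, 20)))


class TestMeasureDisplacements:
    def test_identical_images_zero_field(self):
        from gctfm import DisplacementField

        x, y = make_grid((18.0, 18.0), 0.75)
        z = np.zeros((y.size, x.size))
        frames, ref = render_bead_images(
            [DisplacementField(x=x, y=y, ux=z, uy=z)], noise=0.0, seed=3
        )
        meas = measure_displacements(ref, ref, pixel_size=0.25)
        assert np.abs(meas.ux).max() < 0.02 and np.abs(meas.uy).max() < 0.02

    def test_uniform_translation_recovered(self):
        from gctfm import DisplacementField

        x, y = make_grid((18.0, 18.0), 0.75)
        z = np.zeros((y.size, x.size))
        d0 = DisplacementField(x=x, y=y, ux=z, uy=z)
        d1 = DisplacementField(x=x, y=y, ux=z + 1.0, uy=z - 0.5)
        frames, ref = render_bead_images([d0, d1], noise=0.01, seed=3)
        meas = measure_displacements(frames[1], ref, pixel_size=0.25)
        inner = np.s_[4:-4, 4:-4]
        assert abs(meas.ux[inner].mean() - 1.0) < 0.1
        assert abs(meas.uy[inner].mean() + 0.5) < 0.1

    def test_point_force_deformation_direction(self):
        """Measured field correlates (inner product > 0.9) with the true
        forward-modelled deformation of a localized force."""
        x, y = make_grid((24.0, 24.0), 0.75)
        xx, yy = np.meshgrid(x, y)
        tx = 80 * np.exp(-((xx - 12) ** 2 + (yy - 12) ** 2) / (2 * 1.5 ** 2))
        tm = TractionMap(x=x, y=y, tx=tx, ty=np.zeros_like(tx))
        disp = forward_displacement(tm, 290.0, 0.45)
        frames, ref = render_bead_images([disp], noise=0.01, seed=4)
        meas = measure_displacements(frames[0], ref, pixel_size=0.25)
        inner = np.s_[3:-3, 3:-3]
        t = np.concatenate([disp.ux[inner].ravel(), disp.uy[inner].ravel()])
        m = np.concatenate([meas.ux[inner].ravel(), meas.uy[inner].ravel()])
        cos = t @ m / (np.linalg.norm(t) * np.linalg.norm(m))
        assert cos > 0.9


class TestComputeTraction:
    def _patch(self, n=64, d=0.75):
        x = d * np.arange(n)
        y = d * np.arange(n)
        xx, yy = np.meshgrid(x, y)
        c = d * n / 2
        tx = 100 * np.exp(-((xx - c + 4) ** 2 + (yy - c) ** 2) / (2 * 2 ** 2))
        tx -= 100 * np.exp(-((xx - c - 4) ** 2 + (yy - c) ** 2) / (2 * 2 ** 2))
        ty = 50 * np.exp(-((xx - c) ** 2 + (yy - c - 4) ** 2) / (2 * 2 ** 2))
        ty -= 50 * np.exp(-((xx - c) ** 2 + (yy - c + 4) ** 2) / (2 * 2 ** 2))
        return TractionMap(x=x, y=y, tx=tx, ty=ty)

    def test_zero_displacement_zero_traction(self):
        from gctfm import DisplacementField

        x, y = make_grid((24.0, 24.0), 0.75)
        z = np.zeros((y.size, x.size))
        gel = GelSubstrate(E=290.0)
        tm = compute_traction(DisplacementField(x=x, y=y, ux=z, uy=z), gel)
        assert np.allclose(tm.tx, 0) and np.allclose(tm.ty, 0)

    def test_forward_inverse_round_trip(self):
        tm = self._patch()
        gel = GelSubstrate(E=290.0, nu=0.45)
        disp = forward_displacement(tm, gel.E, gel.nu)
        rec = compute_traction(disp, gel, lam=0.0)
        m = 8  # exclude the boundary ring
        sl = np.s_[m:-m, m:-m]
        err = np.sqrt(np.mean((rec.tx[sl] - tm.tx[sl]) ** 2 + (rec.ty[sl] - tm.ty[sl]) ** 2))
        rms = np.sqrt(np.mean(tm.tx[sl] ** 2 + tm.ty[sl] ** 2))
        assert err / rms < 0.05

    def test_traction_linear_in_E(self):
        tm = self._patch()
        disp = forward_displacement(tm, 290.0, 0.45)
        t1 = compute_traction(disp, GelSubstrate(E=290.0, nu=0.45))
        t2 = compute_traction(disp, GelSubstrate(E=580.0, nu=0.45))
        np.testing.assert_allclose(t2.tx, 2 * t1.tx, rtol=1e-10)

    def test_negative_regularization_rejected(self):
        tm = self._patch()
        disp = forward_displacement(tm, 290.0, 0.45)
        with pytest.raises(ValueError):
            compute_traction(disp, GelSubstrate(E=290.0), lam=-1.0)

    def test_nan_displacement_rejected(self):
        tm = self._patch()
        disp = forward_displacement(tm, 290.0, 0.45)
        disp.ux[3, 3] = np.nan
        with pytest.raises(ValueError):
            compute_traction(disp, GelSubstrate(E=290.0))

    def test_tikhonov_reduces_to_unregularized_at_lambda_zero_limit(self):
        tm = self._patch()
        gel = GelSubstrate(E=290.0, nu=0.45)
        disp = forward_displacement(tm, gel.E, gel.nu)
        t0 = compute_traction(disp, gel, lam=0.0)
        t1 = compute_traction(disp, gel, lam=1e-12)
        np.testing.assert_allclose(t0.tx, t1.tx, atol=1e-6)

    def test_strain_energy_parseval_consistency(self):
        """Total strain energy agrees between the real-space sum and the
        spectral-domain sum (unit bookkeeping of the transform pair)."""
        tm = self._patch()
        gel = GelSubstrate(E=290.0, nu=0.45)
        disp = forward_displacement(tm, gel.E, gel.nu, pad_factor=4)
        a = tm.cell_area
        u_real = 0.5 * np.sum(disp.ux * tm.tx + disp.uy * tm.ty) * a
        n = tm.tx.size
        uxf, uyf = spfft.fft2(disp.ux), spfft.fft2(disp.uy)
        txf, tyf = spfft.fft2(tm.tx), spfft.fft2(tm.ty)
        u_spec = 0.5 * np.real(
            np.sum(uxf * np.conj(txf) + uyf * np.conj(tyf))
        ) * a / n
        assert abs(u_real - u_spec) < 1e-6 * abs(u_real)

    def test_rotation_equivariance_90deg(self):
        """Rotating the displacement field by 90° rotates the traction by
        90° (components transform as vectors)."""
        tm = self._patch()
        gel = GelSubstrate(E=290.0, nu=0.45)
        disp = forward_displacement(tm, gel.E, gel.nu)
        rec = compute_traction(disp, gel)
        # rotate grid by +90°: (x, y) -> (-y, x); components (ux,uy)->(-uy,ux)
        from gctfm import DisplacementField

        ux_r = -np.rot90(disp.uy)
        uy_r = np.rot90(disp.ux)
        disp_r = DisplacementField(x=tm.x, y=tm.y, ux=ux_r, uy=uy_r)
        rec_r = compute_traction(disp_r, gel)
        scale = np.abs(rec.tx).max()
        np.testing.assert_allclose(rec_r.tx, -np.rot90(rec.ty), atol=1e-4 * scale)
        np.testing.assert_allclose(rec_r.ty, np.rot90(rec.tx), atol=1e-4 * scale)

    def test_translation_equivariance(self):
        tm = self._patch()
        gel = GelSubstrate(E=290.0, nu=0.45)
        disp = forward_displacement(tm, gel.E, gel.nu)
        rec = compute_traction(disp, gel)
        from gctfm import DisplacementField

        shift = 5
        disp_s = DisplacementField(
            x=tm.x, y=tm.y,
            ux=np.roll(disp.ux, shift, axis=1),
            uy=np.roll(disp.uy, shift, axis=1),
        )
        rec_s = compute_traction(disp_s, gel)
        m = 12
        np.testing.assert_allclose(
            rec_s.tx[m:-m, m + shift:-m + shift],
            rec.tx[m:-m, m:-m],
            atol=0.05 * np.abs(rec.tx).max(),
        )
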