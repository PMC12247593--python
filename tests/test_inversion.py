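"""Inversion tests: closed form, Fourier, least squares, background."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import qbrm
from qbrm.model import BirefringenceModel


def make_stack(I0, ret, phi, angles):
    """Noiseless stack straight from the sinusoid (ret = |sin(2*pi*delta)|)."""
    I0, ret, phi = np.broadcast_arrays(*(np.atleast_2d(x).astype(float)
                                         for x in (I0, ret, phi)))
    frames = [I0 / 2 * (1 + ret * np.sin(2 * np.deg2rad(a - phi)))
              for a in angles]
    return qbrm.PolStack(np.stack(frames), tuple(angles))


def circ_diff(a, b):
    d = np.abs(np.asarray(a) - np.asarray(b)) % 180.0
    return np.minimum(d, 180.0 - d)


THREE = (0.0, 60.0, 120.0)


class TestThreePoint:
    def test_constant_signal_masked_zero_retardance(self):
        st_ = qbrm.PolStack(np.full((3, 2, 2), 0.7), THREE)
        res = qbrm.invert_three_point(st_)
        assert np.allclose(res.transmittance, 1.4)
        assert np.allclose(res.retardance, 0.0)
        assert not res.valid_mask.any()

    def test_derived_triple_roundtrip(self):
        st_ = qbrm.PolStack(
            np.array([0.5669873, 1.4330127, 1.0]).reshape(3, 1, 1), THREE)
        res = qbrm.invert_three_point(st_)
        assert res.transmittance[0, 0] == pytest.approx(2.0, abs=1e-6)
        assert res.retardance[0, 0] == pytest.approx(0.5, abs=1e-6)
        assert res.orientation_deg[0, 0] == pytest.approx(30.0, abs=1e-4)

    def test_homogeneity_under_intensity_scaling(self):
        st_ = make_stack(2.0, 0.4, 25.0, THREE)
        scaled = qbrm.PolStack(st_.frames * 3.7, THREE)
        a, b = qbrm.invert_three_point(st_), qbrm.invert_three_point(scaled)
        assert np.allclose(b.transmittance, 3.7 * a.transmittance)
        assert np.allclose(b.retardance, a.retardance)
        assert np.allclose(circ_diff(b.orientation_deg, a.orientation_deg), 0)

    def test_wrong_angles_rejected_with_guidance(self):
        st_ = make_stack(1.0, 0.3, 10.0, (0.0, 45.0, 90.0))
        with pytest.raises(ValueError, match="invert_nangle"):
            qbrm.invert_three_point(st_)

    def test_negative_intensities_rejected_for_raw_stacks(self):
        # corrected stacks may be negative (mean-subtracted sinusoid) ...
        qbrm.PolStack(-np.ones((3, 1, 1)), THREE, kind="corrected")
        # ... but raw sample/background acquisitions may not
        for kind in ("sample", "background"):
            with pytest.raises(ValueError):
                qbrm.PolStack(-np.ones((3, 1, 1)), THREE, kind=kind)

    def test_clipped_pixels_counted(self):
        st_ = qbrm.PolStack(
            np.array([1.0, 0.0, 0.0]).reshape(3, 1, 1), THREE)
        res = qbrm.invert_three_point(st_)
        assert res.retardance[0, 0] == 1.0
        assert res.n_clipped == 1

    @given(I0=st.floats(0.01, 4), ret=st.floats(1e-3, 1.0),
           phi=st.floats(0, 179.999))
    def test_roundtrip_identity(self, I0, ret, phi):
        res = qbrm.invert_three_point(make_stack(I0, ret, phi, THREE))
        assert res.transmittance[0, 0] == pytest.approx(I0, rel=1e-10)
        assert res.retardance[0, 0] == pytest.approx(ret, rel=1e-10)
        assert circ_diff(res.orientation_deg[0, 0], phi) < 1e-8

    @given(I0=st.floats(0.01, 4), ret=st.floats(1e-3, 1.0),
           phi=st.floats(0, 179.999))
    def test_forward_reevaluation_reproduces_inputs(self, I0, ret, phi):
        st_ = make_stack(I0, ret, phi, THREE)
        res = qbrm.invert_three_point(st_)
        redone = make_stack(res.transmittance, res.retardance,
                            res.orientation_deg, THREE)
        assert np.allclose(redone.frames, st_.frames, rtol=1e-9, atol=1e-12)

    @given(phi=st.floats(0, 179.999), shift=st.floats(0, 179.999))
    def test_orientation_equivariance(self, phi, shift):
        a = qbrm.invert_three_point(make_stack(1.0, 0.5, phi, THREE))
        b = qbrm.invert_three_point(
            make_stack(1.0, 0.5, (phi + shift) % 180, THREE))
        assert circ_diff(b.orientation_deg[0, 0] - a.orientation_deg[0, 0],
                         shift) < 1e-7

    @given(vals=st.lists(st.floats(0, 10), min_size=3, max_size=3))
    def test_retardance_always_real_and_finite(self, vals):
        """Q = half the sum of squared pairwise differences is >= 0."""
        st_ = qbrm.PolStack(np.array(vals).reshape(3, 1, 1), THREE)
        res = qbrm.invert_three_point(st_)
        assert np.isfinite(res.retardance).all()
        assert 0.0 <= res.retardance[0, 0] <= 1.0


class TestEstimatorEquivalence:
    def test_three_point_equals_fourier_and_fit(self):
        rng = np.random.default_rng(5)
        I0 = rng.uniform(0.5, 3, (16, 16))
        ret = rng.uniform(0.05, 1.0, (16, 16))
        phi = rng.uniform(0, 180, (16, 16))
        st_ = make_stack(I0, ret, phi, THREE)
        tp = qbrm.invert_three_point(st_)
        fo = qbrm.invert_nangle(st_)
        fi = qbrm.fit_sinusoid(st_)
        for other in (fo, fi):
            assert np.allclose(other.transmittance, tp.transmittance,
                               atol=1e-9)
            assert np.allclose(other.retardance, tp.retardance, atol=1e-9)
            assert np.all(circ_diff(other.orientation_deg,
                                    tp.orientation_deg) < 1e-7)

    def test_equivalence_on_noisy_frames(self):
        rng = np.random.default_rng(17)
        frames = rng.uniform(0.1, 2.0, (3, 8, 8))
        st_ = qbrm.PolStack(frames, THREE)
        tp = qbrm.invert_three_point(st_)
        fo = qbrm.invert_nangle(st_)
        fi = qbrm.fit_sinusoid(st_)
        for other in (fo, fi):
            assert np.allclose(other.retardance, tp.retardance, atol=1e-9)

    def test_nangle_18_exact_recovery(self):
        angles = tuple(np.arange(18) * 10.0)
        res = qbrm.invert_nangle(make_stack(1.7, 0.42, 137.0, angles))
        assert res.transmittance[0, 0] == pytest.approx(1.7, abs=1e-10)
        assert res.retardance[0, 0] == pytest.approx(0.42, abs=1e-10)
        assert circ_diff(res.orientation_deg[0, 0], 137.0) < 1e-8

    def test_nangle_rejects_unequal_spacing(self):
        st_ = make_stack(1.0, 0.3, 10.0, (0.0, 50.0, 120.0))
        with pytest.raises(ValueError):
            qbrm.invert_nangle(st_)

    def test_fit_handles_arbitrary_angles(self):
        angles = (5.0, 42.0, 77.0, 130.0, 166.0)
        res = qbrm.fit_sinusoid(make_stack(2.2, 0.3, 64.0, angles))
        assert res.transmittance[0, 0] == pytest.approx(2.2, abs=1e-8)
        assert res.retardance[0, 0] == pytest.approx(0.3, abs=1e-8)
        assert circ_diff(res.orientation_deg[0, 0], 64.0) < 1e-6

    def test_fit_perturbation_matches_projection_bound(self):
        """Scaling one of six frames by 1.01 shifts retardance by no more
        than the perturbation's harmonic projection allows."""
        angles = tuple(np.arange(6) * 30.0)
        base = make_stack(2.0, 0.4, 20.0, angles)
        frames = base.frames.copy()
        frames[2] *= 1.01
        pert = qbrm.PolStack(frames, angles)
        res = qbrm.fit_sinusoid(pert)
        ref = qbrm.invert_nangle(pert)  # independent projection route
        assert np.allclose(res.retardance, ref.retardance, atol=1e-9)
        # the 1% single-frame perturbation moves each quadrature by at most
        # (2/n)*dI and the DC by (1/n)*dI; a generous resulting bound:
        d_frame = float(np.max(np.abs(pert.frames - base.frames)))
        bound = (4.0 / 6) * d_frame + 0.01 * 0.4 + 1e-9
        assert abs(res.retardance[0, 0] - 0.4) <= bound


class TestBackgroundCorrection:
    def test_constant_background_is_noop(self):
        sample = make_stack(1.0, 0.4, 30.0, THREE)
        bg = qbrm.PolStack(np.full((3, 1, 1), 0.3), THREE, kind="background")
        corr = qbrm.background_correct(sample, bg)
        assert np.allclose(corr.frames, sample.frames)
        assert corr.kind == "corrected"

    def test_blank_field_yields_zero_retardance(self):
        train = qbrm.OpticalTrain(analyzer_error_waves=0.02)
        blank = qbrm.SpecimenMap.uniform((4, 4), 1.0, 0.0, 0.0)
        stack = qbrm.simulate_qbrm(blank, train, noiseless=True)
        bg = stack.with_kind("background")
        res = BirefringenceModel(stack, background=bg).fit()
        assert np.allclose(res.retardance, 0.0, atol=1e-12)

    def test_angle_mismatch_rejected(self):
        sample = make_stack(1.0, 0.4, 30.0, THREE)
        bg = qbrm.PolStack(np.ones((3, 1, 1)), (0.0, 45.0, 90.0),
                           kind="background")
        with pytest.raises(ValueError):
            qbrm.background_correct(sample, bg)

    def test_kind_enforced(self):
        sample = make_stack(1.0, 0.4, 30.0, THREE)
        with pytest.raises(ValueError):
            qbrm.background_correct(sample, sample)

    def test_system_birefringence_bias_removed(self):
        """With an imperfect analyzer, correction shrinks the blank-region
        retardance bias by well over an order of magnitude."""
        train = qbrm.OpticalTrain(analyzer_error_waves=0.02)
        blank = qbrm.SpecimenMap.uniform((8, 8), 1.0, 0.0, 0.0)
        stack = qbrm.simulate_qbrm(blank, train, noiseless=True)
        bg = stack.with_kind("background")
        uncorr = BirefringenceModel(stack).fit()
        corr = BirefringenceModel(stack, background=bg).fit()
        bias_u = float(uncorr.retardance.mean())
        bias_c = float(corr.retardance.mean())
        assert bias_u > 0.1  # |sin(2*pi*0.02)| worth of spurious signal
        assert bias_u / max(bias_c, 1e-15) >= 10.0


class TestMaskingAndResults:
    def test_floor_extremes(self):
        st_ = make_stack(1.0, 0.5, 30.0, THREE)
        res = qbrm.invert_three_point(st_)
        assert qbrm.mask_orientation(res, 1.0).valid_mask.sum() == \
            (res.retardance >= 1.0).sum()
        assert qbrm.mask_orientation(res, 0.0).valid_mask.all()

    def test_phantom_floor_matches_ground_truth(self, small_phantom,
                                                ideal_train):
        stack = qbrm.simulate_qbrm(small_phantom.specimen, ideal_train,
                                   noiseless=True)
        res = qbrm.invert_three_point(stack, orientation_floor=0.05)
        gt = small_phantom.ground_truth["retardance"]
        assert np.array_equal(res.valid_mask, gt >= 0.05)

    def test_summary_table(self):
        res = qbrm.invert_three_point(make_stack(1.0, 0.5, 30.0, THREE))
        df = res.summary()
        assert set(df.index) == {"transmittance", "retardance",
                                 "orientation_deg"}
        assert df.loc["retardance", "mean"] == pytest.approx(0.5)
        assert df.attrs["method"] == "three_point"
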