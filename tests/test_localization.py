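"""Emitter fitting, CRLB, blink merging and rendering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from g4smlm.fields import ROI, LocalizationField
from g4smlm.localization import (
    CameraCalibration,
    ImageStack,
    _model_and_jac,
    empty_table,
    fit_emitter_window,
    fit_precision_distribution,
    localize_stack,
    merge_blinking,
    render_image,
)
from g4smlm.synthetic import expected_photoelectrons, make_calibration, simulate_frames


def _record(x, y, frame, var_x, var_y, photons=1000.0, channel=0):
    return {
        "channel": channel, "x_nm": x, "y_nm": y, "frame": frame,
        "photons": photons, "background": 1.0,
        "precision_nm": np.sqrt(0.5 * (var_x + var_y)),
        "crlb_x_nm2": var_x, "crlb_y_nm2": var_y, "multiplicity": 1,
    }


class TestCalibration:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            CameraCalibration(np.zeros((4, 4)), np.ones((4, 4)), np.zeros((5, 5)))

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError, match="gain"):
            CameraCalibration(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((4, 4)))

    def test_empty_stack_rejected(self):
        cal = make_calibration((4, 4), seed=0)
        with pytest.raises(ValueError):
            ImageStack(frames=np.zeros((0, 4, 4)), calibration=cal)


class TestEmitterFit:
    def test_noiseless_symmetric_recovery(self):
        mu = expected_photoelectrons([(3.0, 3.0, 2000.0)], (7, 7), 1.1, 2.0)
        fit = fit_emitter_window(mu, np.zeros((7, 7)), 1.1)
        assert fit["x"] == pytest.approx(3.0, abs=1e-4)
        assert fit["y"] == pytest.approx(3.0, abs=1e-4)
        assert fit["photons"] == pytest.approx(2000.0, rel=1e-3)
        assert fit["background"] == pytest.approx(2.0, rel=1e-2)

    def test_noiseless_offcenter_recovery(self):
        mu = expected_photoelectrons([(3.4, 2.6, 5000.0)], (7, 7), 1.1, 5.0)
        fit = fit_emitter_window(mu, np.zeros((7, 7)), 1.1)
        assert fit["x"] == pytest.approx(3.4, abs=1e-3)
        assert fit["y"] == pytest.approx(2.6, abs=1e-3)

    def test_crlb_matches_numeric_fisher(self):
        """CRLB from the analytic Jacobian must match a finite-difference
        Fisher information computed from the model image alone."""
        theta = (3.2, 2.9, 3000.0, 4.0)
        rows = cols = np.arange(7.0)
        read_var = 2.25
        mu0, dmu_analytic = _model_and_jac(theta, cols, rows, 1.1)
        steps = [1e-5, 1e-5, 1e-2, 1e-5]
        dmu = np.empty_like(dmu_analytic)
        for k, h in enumerate(steps):
            tp = list(theta); tm = list(theta)
            tp[k] += h; tm[k] -= h
            mp, _ = _model_and_jac(tp, cols, rows, 1.1)
            mm, _ = _model_and_jac(tm, cols, rows, 1.1)
            dmu[k] = (mp - mm) / (2 * h)
        mu_eff = mu0 + read_var
        fisher_num = np.einsum("aij,bij->ab", dmu / mu_eff[None], dmu)
        fisher_ana = np.einsum("aij,bij->ab", dmu_analytic / mu_eff[None], dmu_analytic)
        np.testing.assert_allclose(fisher_num, fisher_ana, rtol=1e-5)

    def test_all_background_frames_empty_table(self):
        cal = make_calibration((12, 12), seed=1)
        stack = simulate_frames([], cal, background=10.0, n_frames=5, seed=2)
        table = localize_stack(stack, psf_fwhm_px=2.5)
        assert len(table) == 0


class TestLocalizeStack:
    def test_localization_rmse_tracks_crlb(self):
        """Empirical scatter of repeated fits stays within 15% of the
        mean CRLB-predicted precision (efficiency of the MLE)."""
        cal = make_calibration((15, 15), seed=1)
        truth = (7.3, 6.8)
        stack = simulate_frames([(truth[0], truth[1], 5000.0)], cal,
                                psf_sigma_px=1.1, background=5.0,
                                n_frames=150, seed=2)
        table = localize_stack(stack, psf_fwhm_px=1.1 * 2.355)
        assert len(table) > 100
        rmse = np.sqrt(
            0.5 * (((table.x_nm - truth[0] * 100) ** 2).mean()
                   + ((table.y_nm - truth[1] * 100) ** 2).mean())
        )
        crlb = np.sqrt(0.5 * (table.crlb_x_nm2 + table.crlb_y_nm2)).mean()
        assert abs(rmse - crlb) / crlb < 0.15

    def test_efficiency_bound_across_photon_levels(self):
        """Empirical RMSE is never far below the CRLB (information bound)."""
        cal = make_calibration((15, 15), seed=3)
        for photons, seed in [(500.0, 4), (2000.0, 5), (10000.0, 6)]:
            stack = simulate_frames([(7.2, 7.6, photons)], cal, psf_sigma_px=1.1,
                                    background=5.0, n_frames=60, seed=seed)
            table = localize_stack(stack, psf_fwhm_px=1.1 * 2.355)
            assert len(table) > 30
            rmse = np.sqrt(
                0.5 * (((table.x_nm - 720) ** 2).mean() + ((table.y_nm - 760) ** 2).mean())
            )
            crlb = np.sqrt(0.5 * (table.crlb_x_nm2 + table.crlb_y_nm2)).mean()
            assert rmse > 0.7 * crlb  # cannot beat the bound by much


class TestMergeBlinking:
    def test_inverse_variance_worked_example(self):
        table = pd.DataFrame([
            _record(0.0, 0.0, 0, 100.0, 100.0),
            _record(30.0, 0.0, 1, 400.0, 400.0),
        ])
        merged = merge_blinking(table)
        assert len(merged) == 1
        # (0/100 + 30/400) / (1/100 + 1/400) = 6.0 ; var 1/(0.0125) = 80
        assert merged.x_nm.iloc[0] == pytest.approx(6.0, abs=1e-9)
        assert merged.crlb_x_nm2.iloc[0] == pytest.approx(80.0, abs=1e-9)
        assert merged.multiplicity.iloc[0] == 2
        assert merged.photons.iloc[0] == pytest.approx(2000.0)

    def test_frame_gap_not_merged(self):
        table = pd.DataFrame([
            _record(0.0, 0.0, 0, 100.0, 100.0),
            _record(5.0, 0.0, 2, 100.0, 100.0),
        ])
        assert len(merge_blinking(table)) == 2

    def test_distance_outside_gate_not_merged(self):
        # gate = 2.5 * precision = 2.5 * 10 = 25 nm < 60 nm separation
        table = pd.DataFrame([
            _record(0.0, 0.0, 0, 100.0, 100.0),
            _record(60.0, 0.0, 1, 100.0, 100.0),
        ])
        assert len(merge_blinking(table)) == 2

    def test_single_record_identity(self):
        table = pd.DataFrame([_record(5.0, 7.0, 3, 50.0, 50.0)])
        merged = merge_blinking(table)
        assert len(merged) == 1
        assert merged.multiplicity.iloc[0] == 1
        assert merged.x_nm.iloc[0] == pytest.approx(5.0)

    def test_empty_table(self):
        assert len(merge_blinking(empty_table())) == 0

    def test_channels_not_mixed(self):
        table = pd.DataFrame([
            _record(0.0, 0.0, 0, 100.0, 100.0, channel=1),
            _record(1.0, 0.0, 1, 100.0, 100.0, channel=2),
        ])
        assert len(merge_blinking(table)) == 2

    def test_idempotent_and_multiplicity_conserving(self):
        rng = np.random.default_rng(12)
        rows = []
        for i in range(25):  # well-separated emitters blinking in runs
            ex, ey = rng.uniform(500, 5500, 2)
            frame = int(rng.integers(0, 5))
            for _ in range(int(rng.integers(1, 6))):
                rows.append(_record(ex + rng.normal(0, 8), ey + rng.normal(0, 8),
                                    frame, 64.0, 64.0))
                frame += 1
        table = pd.DataFrame(rows)
        m1 = merge_blinking(table)
        m2 = merge_blinking(m1)
        assert len(m1) <= len(table)
        assert m1.multiplicity.sum() == len(table)
        pd.testing.assert_frame_equal(
            m1.reset_index(drop=True), m2.reset_index(drop=True)
        )


class TestPrecisionDistribution:
    def test_skew_gaussian_recovery(self):
        truth = dict(a=4.0, loc=10.0, scale=3.0)
        vals = stats.skewnorm.rvs(truth["a"], truth["loc"], truth["scale"],
                                  size=5000, random_state=21)
        table = pd.DataFrame({"precision_nm": vals})
        fit = fit_precision_distribution(table)
        assert fit.location == pytest.approx(truth["loc"], rel=0.10)
        assert fit.scale == pytest.approx(truth["scale"], rel=0.10)
        assert fit.shape == pytest.approx(truth["a"], rel=0.35)

    def test_symmetric_input_zero_shape(self):
        vals = stats.norm.rvs(10.0, 2.0, size=5000, random_state=22)
        fit = fit_precision_distribution(pd.DataFrame({"precision_nm": vals}))
        loc_sn = fit.location  # skewnorm loc differs from the mean unless shape ~ 0
        assert abs(fit.shape) < 1.0
        assert loc_sn == pytest.approx(10.0, abs=1.0)

    def test_too_few_records(self):
        with pytest.raises(ValueError, match="at least"):
            fit_precision_distribution(pd.DataFrame({"precision_nm": [1.0] * 10}))

    def test_constant_input_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_precision_distribution(pd.DataFrame({"precision_nm": [5.0] * 100}))


class TestRender:
    def _field(self, xy):
        return LocalizationField(np.asarray(xy, float), ROI.square(1000.0), channel=0)

    def test_single_record_unit_mass(self):
        img = render_image(self._field([[0.0, 0.0]]))
        assert img.sum() == pytest.approx(1.0, abs=1e-6)

    def test_linearity_of_coincident_records(self):
        one = render_image(self._field([[50.0, -30.0]]))
        two = render_image(self._field([[50.0, -30.0], [50.0, -30.0]]))
        np.testing.assert_allclose(two, 2 * one, atol=1e-12)

    def test_corner_truncation(self):
        img = render_image(self._field([[-499.0, -499.0]]))
        assert img.sum() < 1.0

    def test_empty_field_zero_canvas(self):
        img = render_image(self._field(np.empty((0, 2))))
        assert img.shape == (100, 100)
        assert img.sum() == 0.0
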