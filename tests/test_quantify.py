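"""Highest-peak location, AUC integration, and the per-ROI ratio."""

import numpy as np
import pytest

from gm1quant.chem import default_targets
from gm1quant.quantify import (
    PeakNotFoundError,
    find_highest_peak,
    integrate_auc,
    quantify_target,
    records_to_frame,
    roi_ratio,
)
from gm1quant.spectra_io import IMSDataset, MassSpectrum, ROI
from gm1quant.synthetic import RegionParams, SimulationConfig, build_phantom, simulate_study

from conftest import gaussian_peak, make_target, mz_axis

D18, D20 = default_targets()


def one_pixel_dataset(mz, intensity, **meta):
    return IMSDataset(
        coordinates=np.array([[0, 0]]),
        mz=mz,
        intensities=intensity[None, :],
        metadata=meta,
    )


def symmetric_two_peak_spectrum(amp18=10.0, amp20=10.0, sigma=0.15):
    """Two pure Gaussians at the species anchors (no isotope satellites).

    The 0.01 Da axis puts both anchors exactly on the grid, so the two
    integration windows are perfectly congruent."""
    mz = mz_axis(1530.0, 1590.0, bin_width=0.01)
    it = gaussian_peak(mz, D18.predicted_mz, amp18, sigma) + gaussian_peak(
        mz, D20.predicted_mz, amp20, sigma
    )
    return mz, it


ROI_00 = dict(region="r", hemisphere="left", section_id="S1", animal_id="A01")


class TestFindHighestPeak:
    def test_apex_at_predicted_mz_within_one_bin(self):
        mz = mz_axis(1535.0, 1555.0)
        spec = MassSpectrum(mz, gaussian_peak(mz, D18.predicted_mz, 5.0, 0.15))
        apex_mz, apex_it = find_highest_peak(spec, D18)
        assert abs(apex_mz - D18.predicted_mz) <= 0.02
        assert apex_it == pytest.approx(5.0, rel=5e-3)  # apex sampled up to half a bin off-center

    def test_tie_broken_toward_predicted_then_lower_mz(self):
        # 0.25 Da spacing is binary-exact, so tie distances compare exactly
        target = make_target(1560.0)
        mz = 1550.0 + 0.25 * np.arange(81)
        it = np.zeros_like(mz)
        # two equal spikes: one 0.50 Da below, one 0.25 Da above the anchor
        it[mz == 1559.50] = 4.0
        it[mz == 1560.25] = 4.0
        apex_mz, _ = find_highest_peak(MassSpectrum(mz, it), target)
        assert apex_mz == 1560.25
        # exactly equidistant equal spikes -> lower m/z wins
        it = np.zeros_like(mz)
        it[mz == 1559.75] = 4.0
        it[mz == 1560.25] = 4.0
        apex_mz, _ = find_highest_peak(MassSpectrum(mz, it), target)
        assert apex_mz == 1559.75

    def test_all_zero_window_is_peak_not_found(self):
        mz = mz_axis(1550.0, 1570.0)
        with pytest.raises(PeakNotFoundError):
            find_highest_peak(MassSpectrum(mz, np.zeros_like(mz)), make_target(1560.0))

    def test_floor_suppresses_subthreshold_peaks(self):
        mz = mz_axis(1550.0, 1570.0)
        it = gaussian_peak(mz, 1560.0, 1.0, 0.15)
        with pytest.raises(PeakNotFoundError):
            find_highest_peak(MassSpectrum(mz, it), make_target(1560.0), detection_floor=2.0)


class TestIntegrateAuc:
    def test_gaussian_auc_within_1pct_of_closed_form(self):
        amp, sigma = 7.0, 0.15
        mz = mz_axis(1550.0, 1570.0)
        spec = MassSpectrum(mz, gaussian_peak(mz, 1560.0, amp, sigma))
        auc, bounds = integrate_auc(spec, 1560.0, make_target(1560.0))
        assert auc == pytest.approx(amp * sigma * np.sqrt(2 * np.pi), rel=0.01)
        assert bounds == (1560.0 - 0.4, 1560.0 + 0.4)

    def test_zero_spectrum_gives_zero_auc(self):
        mz = mz_axis(1550.0, 1570.0)
        auc, _ = integrate_auc(MassSpectrum(mz, np.zeros_like(mz)), 1560.0, make_target(1560.0))
        assert auc == 0.0

    def test_doubling_intensities_doubles_auc(self):
        mz = mz_axis(1550.0, 1570.0)
        it = gaussian_peak(mz, 1560.0, 3.0, 0.15)
        t = make_target(1560.0)
        a1, _ = integrate_auc(MassSpectrum(mz, it), 1560.0, t)
        a2, _ = integrate_auc(MassSpectrum(mz, 2.0 * it), 1560.0, t)
        assert a2 == 2.0 * a1

    def test_bounds_exceeding_window_raise(self):
        mz = mz_axis(1559.0, 1561.0)
        with pytest.raises(ValueError, match="exceed"):
            integrate_auc(MassSpectrum(mz, np.ones_like(mz)), 1560.9, make_target(1560.0))


class TestRoiRatio:
    def test_symmetric_peaks_give_ratio_one(self):
        mz, it = symmetric_two_peak_spectrum(10.0, 10.0)
        ds = one_pixel_dataset(mz, it)
        rec = roi_ratio(ds, ROI((0,), **ROI_00))
        assert rec.valid
        assert rec.ratio == pytest.approx(1.0, abs=1e-6)

    def test_missing_denominator_flags_invalid_not_infinite(self):
        mz, it = symmetric_two_peak_spectrum(10.0, 0.0)
        ds = one_pixel_dataset(mz, it)
        rec = roi_ratio(ds, ROI((0,), **ROI_00))
        assert not rec.valid
        assert "GM1d20:1" in rec.reason
        assert np.isnan(rec.ratio)

    @pytest.mark.parametrize("c", [2.0, 0.5, 256.0])
    def test_scale_invariance_exact_for_binary_scalings(self, c):
        mz, it = symmetric_two_peak_spectrum(10.0, 4.0)
        r1 = roi_ratio(one_pixel_dataset(mz, it), ROI((0,), **ROI_00)).ratio
        r2 = roi_ratio(one_pixel_dataset(mz, c * it), ROI((0,), **ROI_00)).ratio
        assert r1 == r2

    def test_scale_invariance_general_gain(self):
        mz, it = symmetric_two_peak_spectrum(10.0, 4.0)
        r1 = roi_ratio(one_pixel_dataset(mz, it), ROI((0,), **ROI_00)).ratio
        r2 = roi_ratio(one_pixel_dataset(mz, 3.7 * it), ROI((0,), **ROI_00)).ratio
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_isotope_window_isolation(self):
        """The integration halfwidth barely matters while peaks stay
        baseline-resolved: 0.3 vs 0.45 Da changes the ratio by < 1%."""
        config = SimulationConfig(
            regions={"region": RegionParams(3.0)},
            mz_range=(1520.0, 1600.0),
            noise_sigma=0.0, gain_sigma=0.0,
            ratio_animal_cv=0.0, ratio_roi_cv=0.0,
            roi_max_pixels=4,
        )
        phantom = build_phantom("single", (8, 8))
        datasets, rois, _ = simulate_study(config, phantom)
        import dataclasses

        ratios = {}
        for ihw in (0.3, 0.45):
            t18 = dataclasses.replace(D18, integration_halfwidth=ihw)
            t20 = dataclasses.replace(D20, integration_halfwidth=ihw)
            ratios[ihw] = roi_ratio(datasets[0], rois[0], targets=(t18, t20)).ratio
        assert ratios[0.45] == pytest.approx(ratios[0.3], rel=0.01)

    def test_records_frame_is_tidy(self):
        mz, it = symmetric_two_peak_spectrum()
        rec = roi_ratio(one_pixel_dataset(mz, it), ROI((0,), **ROI_00))
        df = records_to_frame([rec])
        assert list(df.columns[:5]) == ["animal_id", "section_id", "hemisphere", "region", "ratio"]
        assert len(df) == 1 and bool(df.valid[0])


def test_quantify_target_full_pipeline_on_offset_peak():
    """Peak on a constant offset: baseline removal + apex + AUC end to end."""
    amp, sigma = 6.0, 0.15
    mz = mz_axis(1535.0, 1555.0)
    it = gaussian_peak(mz, D18.predicted_mz, amp, sigma) + 3.0
    q = quantify_target(MassSpectrum(mz, it), D18)
    assert q.auc == pytest.approx(amp * sigma * np.sqrt(2 * np.pi), rel=0.01)
    assert abs(q.apex_mz - D18.predicted_mz) <= 0.02
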