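"""Phantoms, the study simulator, and its calibration guarantees."""

import numpy as np
import pytest

from gm1quant.quantify import roi_ratio
from gm1quant.roi_analysis import animal_averages
from gm1quant.synthetic import (
    BaselineParams,
    RegionParams,
    SimulationConfig,
    build_phantom,
    simulate_pixel_spectrum,
    simulate_study,
)

MZ_RANGE = (1520.0, 1600.0)


def config(**overrides):
    base = dict(
        regions={"region": RegionParams(2.0)},
        mz_range=MZ_RANGE,
        noise_sigma=0.0,
        gain_sigma=0.0,
        ratio_animal_cv=0.0,
        ratio_roi_cv=0.0,
        rng_seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestBuildPhantom:
    def test_cortex3_is_three_equal_depth_bands(self):
        ph = build_phantom("cortex3", (30, 60))
        assert ph.labels == ("superficial", "intermediate", "deep")
        for i, lbl in enumerate(ph.labels):
            assert np.all(ph.grid[i * 10 : (i + 1) * 10] == lbl)

    def test_single_layout_is_one_label(self):
        ph = build_phantom("single", (9, 13))
        assert np.all(ph.grid == "region")

    def test_pair_layout_partitions_tissue(self):
        ph = build_phantom("pair", (20, 40))
        a, b = (ph.grid == "A"), (ph.grid == "B")
        assert a.any() and b.any()
        assert not (a & b).any()
        assert (a | b).all()

    def test_hippo6_has_six_nonempty_regions(self):
        ph = build_phantom("hippo6", (12, 30))
        assert len(ph.labels) == 6
        for lbl in ph.labels:
            assert (ph.grid == lbl).any()

    def test_unknown_layout_rejected(self):
        with pytest.raises(ValueError, match="unknown phantom layout"):
            build_phantom("spiral", (10, 10))

    def test_minimum_dims_enforced(self):
        with pytest.raises(ValueError, match="8x8"):
            build_phantom("single", (4, 100))


class TestPixelSpectrum:
    def test_same_seed_gives_identical_spectrum(self):
        cfg = config(noise_sigma=1.0, gain_sigma=0.3)
        s1 = simulate_pixel_spectrum(cfg, "region", np.random.default_rng(5))
        s2 = simulate_pixel_spectrum(cfg, "region", np.random.default_rng(5))
        assert np.array_equal(s1.intensity, s2.intensity)

    def test_undeclared_region_rejected(self):
        with pytest.raises(ValueError, match="not declared"):
            simulate_pixel_spectrum(config(), "nope", np.random.default_rng(0))

    def test_intensities_clipped_nonnegative(self):
        cfg = config(noise_sigma=5.0, baseline=BaselineParams(constant=0.0, slope=0.0,
                                                              bump_amplitude=0.0))
        spec = simulate_pixel_spectrum(cfg, "region", np.random.default_rng(1))
        assert spec.intensity.min() == 0.0

    def test_equal_ratio_gives_equal_highest_peak_aucs(self):
        """true_ratio = 1 with no noise/baseline: the envelope-corrected
        abundance split makes the two monoisotopic AUCs equal."""
        cfg = config(regions={"region": RegionParams(1.0)},
                     baseline=BaselineParams(0.0, 0.0, 0.0))
        ab18, ab20 = cfg.species_abundances("region")
        t18, t20 = cfg.targets
        f18 = t18.envelope().monoisotopic_fraction()
        f20 = t20.envelope().monoisotopic_fraction()
        assert ab18 * f18 == pytest.approx(ab20 * f20, rel=1e-12)
        assert ab18 + ab20 == pytest.approx(100.0, rel=1e-12)


class TestSimulateStudy:
    def test_four_measurements_per_animal(self):
        cfg = config(n_animals=1, sections_per_animal=2)
        datasets, rois, truth = simulate_study(cfg, build_phantom("single", (8, 8)))
        assert len(datasets) == 2  # one per animal-section
        assert len(rois) == 4  # 2 sections x 2 hemispheres x 1 region
        assert {r.animal_id for r in rois} == {"A01"}

    def test_fixed_seed_reproduces_study_bit_identically(self):
        cfg = config(noise_sigma=1.0, gain_sigma=0.3, ratio_animal_cv=0.08,
                     ratio_roi_cv=0.08, n_animals=2, rng_seed=123)
        ph = build_phantom("pair", (8, 8), labels=["region", "other"])
        cfg2 = config(noise_sigma=1.0, gain_sigma=0.3, ratio_animal_cv=0.08,
                      ratio_roi_cv=0.08, n_animals=2, rng_seed=123)
        cfg.regions["other"] = RegionParams(3.0)
        cfg2.regions["other"] = RegionParams(3.0)
        d1, r1, t1 = simulate_study(cfg, ph)
        d2, r2, t2 = simulate_study(cfg2, ph)
        for a, b in zip(d1, d2):
            assert np.array_equal(a.intensities, b.intensities)
            assert np.array_equal(a.coordinates, b.coordinates)
        assert r1 == r2
        assert t1.rois == t2.rois

    def test_drop_rate_one_excludes_animal_downstream(self):
        cfg = config(n_animals=2, roi_drop_rate={"A01": 1.0})
        datasets, rois, truth = simulate_study(cfg, build_phantom("single", (8, 8)))
        assert all(r.animal_id != "A01" for r in rois)
        records = []
        by_key = {(d.metadata["animal_id"], d.metadata["section_id"]): d for d in datasets}
        for roi in rois:
            records.append(roi_ratio(by_key[(roi.animal_id, roi.section_id)], roi))
        means = animal_averages(records)
        assert {m.animal_id for m in means} == {"A02"}

    def test_ground_truth_covers_every_roi(self):
        cfg = config(n_animals=2, ratio_roi_cv=0.1, noise_sigma=1.0)
        _, rois, truth = simulate_study(cfg, build_phantom("single", (8, 8)))
        assert len(truth.rois) == 2 * 2 * 2  # animals x sections x hemispheres
        assert truth.true_ratios == {"region": 2.0}
        assert truth.seed == 0

    def test_hemisphere_symmetry_in_noise_free_runs(self):
        cfg = config(n_animals=1, sections_per_animal=1)
        datasets, rois, _ = simulate_study(cfg, build_phantom("single", (8, 8)))
        recs = {r.hemisphere: roi_ratio(datasets[0], r) for r in rois}
        assert recs["left"].ratio == recs["right"].ratio

    def test_recovery_on_linear_ramp_baseline_within_1pct(self):
        """Noise-free ratio-2 study on a sloped baseline recovers 2.0
        within 1% after local baseline removal."""
        cfg = config(baseline=BaselineParams(constant=3.0, slope=0.08,
                                             bump_amplitude=0.0))
        datasets, rois, _ = simulate_study(cfg, build_phantom("single", (8, 8)))
        rec = roi_ratio(datasets[0], rois[0])
        assert rec.ratio == pytest.approx(2.0, rel=0.01)

    def test_expected_ratio_monotone_in_true_ratio(self):
        recovered = []
        for r in (1.0, 2.0, 4.0, 8.0):
            cfg = config(regions={"region": RegionParams(r)})
            datasets, rois, _ = simulate_study(cfg, build_phantom("single", (8, 8)))
            recovered.append(roi_ratio(datasets[0], rois[0]).ratio)
        assert np.all(np.diff(recovered) > 0)

    def test_gain_cancels_in_ratio(self):
        """Strong per-pixel gain dispersion leaves the noise-free recovered
        ratio unchanged: the normalization argument for reporting ratios."""
        cfg = config(gain_sigma=1.0)
        datasets, rois, _ = simulate_study(cfg, build_phantom("single", (8, 8)))
        rec = roi_ratio(datasets[0], rois[0])
        assert rec.ratio == pytest.approx(2.0, rel=0.01)


class TestConfigValidation:
    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            RegionParams(true_ratio=0.0)

    def test_mz_range_must_contain_envelopes(self):
        with pytest.raises(ValueError, match="does not contain"):
            config(mz_range=(1000.0, 1550.0))

    def test_bad_mz_range_order(self):
        with pytest.raises(ValueError):
            config(mz_range=(1600.0, 1520.0))
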