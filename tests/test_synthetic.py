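"""Generator contracts: determinism, quantile fidelity, ground-truth closure."""

import numpy as np
import pandas as pd
import pytest

from berrystage import synthetic
from berrystage.design import QuantileSpec, StudyDesign
from berrystage.reference import SENSOR_QUANTILES


class TestQuantileMatchedSampling:
    @pytest.mark.parametrize(
        "spec",
        [
            SENSOR_QUANTILES["S7"]["red"],  # widest, asymmetric
            SENSOR_QUANTILES["S7"]["half-red"],
            SENSOR_QUANTILES["S1"]["half-red"],
            SENSOR_QUANTILES["S10"]["red"],
        ],
    )
    def test_quantile_fidelity(self, spec, rng):
        """Empirical median/p5/p95 reproduce the spec within 2% relative."""
        x = synthetic.sample_from_quantiles(spec, rng.normal(size=5000))
        for target, q in ((spec.p5, 5), (spec.median, 50), (spec.p95, 95)):
            emp = np.percentile(x, q)
            assert abs(emp - target) / abs(target) < 0.02

    def test_support_stays_inside_printed_range(self, rng):
        spec = SENSOR_QUANTILES["S7"]["red"]
        x = synthetic.sample_from_quantiles(spec, rng.normal(size=2000))
        assert x.min() >= spec.p5 and x.max() <= spec.p95

    def test_degenerate_spec_collapses_to_median(self, rng):
        spec = QuantileSpec(median=1.5, p5=1.5, p95=1.5)
        x = synthetic.sample_from_quantiles(spec, rng.normal(size=100))
        assert np.all(x == 1.5)


class TestGenEnose:
    def test_observation_count_and_grid(self, default_design, enose_observations):
        assert len(enose_observations) == default_design.n_obs_enose
        tr = enose_observations[0].traces["S1"]
        assert len(tr.time) == 81 and tr.time[0] == 0 and tr.time[-1] == 80

    def test_same_seed_bit_identical(self, default_design):
        d2 = StudyDesign(seed=default_design.seed)
        a = synthetic.gen_enose(StudyDesign(seed=0, samples_per_stage_per_harvest=1))
        b = synthetic.gen_enose(StudyDesign(seed=0, samples_per_stage_per_harvest=1))
        for oa, ob in zip(a, b):
            for s in oa.traces:
                np.testing.assert_array_equal(oa.traces[s].value, ob.traces[s].value)

    def test_s7_plateaus_disjoint_between_stages(self, enose_observations):
        """S7's printed 5th-95th ranges do not overlap, so plateau supports
        must be disjoint between stages."""
        by_stage = {"half-red": [], "red": []}
        for obs in enose_observations:
            by_stage[obs.stage].append(obs.plateau["S7"])
        assert max(by_stage["half-red"]) < min(by_stage["red"])

    def test_missing_sensor_spec_rejected(self, default_design):
        specs = {k: v for k, v in SENSOR_QUANTILES.items() if k != "S3"}
        with pytest.raises(ValueError, match="S3"):
            synthetic.gen_enose(default_design, sensor_specs=specs)


class TestGenFtir:
    def test_grid_has_3401_points(self, ftir_spectra):
        assert ftir_spectra.absorbance.shape == (30, 3401)
        assert ftir_spectra.wavenumber[0] == 600 and ftir_spectra.wavenumber[-1] == 4000

    def test_sugar_band_higher_in_red(self, ftir_spectra):
        """The 1026 cm^-1 band grows with ripening."""
        i = int(np.where(ftir_spectra.wavenumber == 1026)[0][0])
        red = ftir_spectra.absorbance[ftir_spectra.stage == "red", i].mean()
        half = ftir_spectra.absorbance[ftir_spectra.stage == "half-red", i].mean()
        assert red > half

    def test_clean_single_band_is_exact_gaussian(self):
        d = StudyDesign(seed=1, n_harvests=1, reps_ftir=1)
        band = synthetic.Band(1500.0, 50.0, {"half-red": 1.0, "red": 1.0})
        sp = synthetic.gen_ftir(
            d, band_table=[band], scatter_sd=0.0, baseline_offset_sd=0.0,
            baseline_slope_sd=0.0, amp_sample_cv=0.0, amp_rep_cv=0.0, noise_sd=0.0,
        )
        expected = np.exp(-0.5 * ((sp.wavenumber - 1500.0) / 50.0) ** 2)
        # remaining difference is only the fixed 0.04 baseline offset mean
        np.testing.assert_allclose(sp.absorbance[0] - 0.04, expected, atol=1e-12)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            synthetic.Band(1000.0, -1.0, {"half-red": 1.0, "red": 1.0})
        with pytest.raises(ValueError):
            synthetic.Band(1000.0, 10.0, {"half-red": 0.0, "red": 1.0})

    def test_same_seed_identical(self):
        d = StudyDesign(seed=3, n_harvests=1, reps_ftir=2)
        a, b = synthetic.gen_ftir(d), synthetic.gen_ftir(d)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)


class TestRenderBerryImage:
    def test_masks_partition_berry_pixels_exactly(self, rng):
        img = synthetic.render_berry_image(6, 0.5, rng, size=(300, 400))
        assert not np.any(img.red_mask & img.green_mask)
        np.testing.assert_array_equal(img.red_mask | img.green_mask, img.berry_mask)

    def test_fully_red_has_empty_green_mask(self, rng):
        img = synthetic.render_berry_image(4, 1.0, rng, size=(300, 400))
        assert img.green_mask.sum() == 0
        assert img.true_red_pct == 100.0

    def test_half_red_fractions_within_jitter(self, rng):
        img = synthetic.render_berry_image(12, 0.5, rng, size=(432, 512))
        fr = np.array(img.berry_red_fractions)
        assert len(fr) == 12
        assert np.all(np.abs(fr - 0.5) < 4 * synthetic.RED_FRACTION_JITTER)

    def test_checker_has_24_reference_patches(self, rng):
        img = synthetic.render_berry_image(4, 0.7, rng, size=(432, 512), with_checker=True)
        assert len(img.checker.boxes) == 24
        assert img.checker.reference_rgb.shape == (24, 3)
        r0, r1, c0, c1 = img.checker.boxes[5]
        np.testing.assert_allclose(
            img.image[r0:r1, c0:c1].reshape(-1, 3).mean(axis=0),
            img.checker.reference_rgb[5], atol=1.0,
        )

    def test_invalid_red_fraction_rejected(self, rng):
        with pytest.raises(ValueError):
            synthetic.render_berry_image(4, 1.2, rng)

    def test_too_many_berries_rejected(self, rng):
        with pytest.raises(ValueError, match="fit"):
            synthetic.render_berry_image(500, 0.5, rng, size=(60, 80))


class TestGenChemistryVoc:
    def test_voc_table_has_57_compounds(self, default_design):
        chem, voc = synthetic.gen_chemistry_voc(default_design)
        assert len(synthetic.VOC_NAMES) == 57
        assert voc[list(synthetic.VOC_NAMES)].shape == (24, 57)
        assert (voc[list(synthetic.VOC_NAMES)] >= 0).all().all()

    def test_chemistry_correlation_structure(self):
        """TA/TP/AA co-vary positively; TSS opposes them (large n)."""
        d = StudyDesign(seed=5, samples_per_stage_per_harvest=40)
        chem, _ = synthetic.gen_chemistry_voc(d)
        corr = chem[["TA", "TP", "AA", "TSS"]].corr()
        assert corr.loc["TA", "TP"] > 0
        assert corr.loc["TA", "AA"] > 0
        assert corr.loc["TA", "TSS"] < 0

    def test_stage_directions(self, default_design):
        chem, voc = synthetic.gen_chemistry_voc(default_design)
        med = chem.groupby("stage")[["TA", "TSS"]].median()
        assert med.loc["half-red", "TA"] > med.loc["red", "TA"]
        assert med.loc["half-red", "TSS"] < med.loc["red", "TSS"]
        vmed = voc.groupby("stage")[["V01", "V30"]].median()
        assert (vmed.loc["red"] > vmed.loc["half-red"]).all()


class TestWriteDataset:
    def test_manifest_and_determinism(self, tmp_path, small_design):
        m1 = synthetic.write_dataset(
            small_design, tmp_path / "a", berries_per_image=4,
            image_size=(150, 200),
        )
        m2 = synthetic.write_dataset(
            small_design, tmp_path / "b", berries_per_image=4,
            image_size=(150, 200),
        )
        assert m1["enose"] == m2["enose"]
        assert len(m1["enose"]) == small_design.n_obs_enose
        assert len(m1["images"]) == small_design.n_obs_image
        t1 = pd.read_csv(tmp_path / "a" / "enose_truth.csv")
        t2 = pd.read_csv(tmp_path / "b" / "enose_truth.csv")
        pd.testing.assert_frame_equal(t1, t2)
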