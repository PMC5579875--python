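import dataclasses

import numpy as np
import pytest

from hsigrade import (
    Endmember,
    SyntheticConfig,
    correct_reflectance,
    endmember_reflectance,
    make_wavelength_axis,
    simulate_dataset,
    simulate_sample,
)
from hsigrade.synth import COMPONENTS, iter_dataset, read_manifest


class TestWavelengthAxis:
    def test_instrument_axis_spacing_and_membership(self):
        axis = make_wavelength_axis(256, 975.01, 1645.82, 200)
        assert axis.size == 256
        spacing = (1645.82 - 975.01) / 199
        assert np.allclose(np.diff(axis), spacing)
        assert spacing == pytest.approx(3.3709, abs=5e-5)
        in_range = (axis >= 975.01 - 1e-6) & (axis <= 1645.82 + 1e-6)
        assert in_range.sum() == 200

    def test_exact_small_axis(self):
        assert list(make_wavelength_axis(5, 1000, 1004, 5)) == [1000, 1001, 1002, 1003, 1004]

    def test_padding_split(self):
        axis = make_wavelength_axis(10, 1000, 1004, 5)
        assert np.allclose(np.diff(axis), 1.0)
        in_range = (axis >= 1000 - 1e-9) & (axis <= 1004 + 1e-9)
        assert in_range.sum() == 5
        assert (~in_range).sum() == 5

    @pytest.mark.parametrize("args", [(5, 1000, 1004, 6), (5, 1000, 1004, 1), (5, 1004, 1000, 3)])
    def test_infeasible_counts_rejected(self, args):
        with pytest.raises(ValueError):
            make_wavelength_axis(*args)


class TestEndmemberReflectance:
    def test_single_feature_minimum(self):
        em = Endmember("x", 0.6, ((1210.0, 20.0, 0.2),))
        axis = make_wavelength_axis(256, 975.01, 1645.82, 200)
        refl = endmember_reflectance(em, axis)
        i = int(np.argmin(refl))
        assert abs(axis[i] - 1210.0) <= np.diff(axis)[0] / 2
        assert refl[i] == pytest.approx(0.4, abs=1e-3)

    def test_zero_depth_is_constant_baseline(self):
        em = Endmember("x", 0.37)
        assert np.allclose(endmember_reflectance(em, np.linspace(900, 1700, 50)), 0.37)

    def test_overlapping_gaussians_match_brute_force(self):
        feats = ((1100.0, 30.0, 0.1), (1120.0, 25.0, 0.15))
        em = Endmember("x", 0.7, feats)
        axis = np.linspace(980, 1300, 123)
        oracle = np.full(axis.size, 0.7)
        for lam_i in range(axis.size):
            for c, w, d in feats:
                oracle[lam_i] -= d * np.exp(-((axis[lam_i] - c) ** 2) / (2 * w * w))
        assert np.allclose(endmember_reflectance(em, axis), oracle, atol=1e-12)

    def test_out_of_range_center_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            Endmember("x", 0.5, ((2000.0, 10.0, 0.1),))


class TestSimulateSample:
    def test_calibration_inverts_simulation_exactly(self, clean_config, rng):
        cfg = dataclasses.replace(clean_config, noise_sd=0.0)
        cube, refs, truth = simulate_sample(cfg, 2, "intact", rng)
        refl = correct_reflectance(cube, refs)
        E = cfg.endmember_matrix()
        expected = truth.fractions.reshape(-1, 4) @ E
        assert np.allclose(refl.data.reshape(-1, cfg.n_bands), expected, atol=1e-9)

    def test_same_seed_is_bit_identical(self, tiny_config):
        a = simulate_sample(tiny_config, 1, "sliced", np.random.default_rng(7))
        b = simulate_sample(tiny_config, 1, "sliced", np.random.default_rng(7))
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[2].fractions, b[2].fractions)

    def test_grade_ordering_at_lean_band(self, clean_config):
        """More lean meat -> deeper absorption at a lean-only feature band."""
        rng = np.random.default_rng(0)
        cfg = dataclasses.replace(clean_config, noise_sd=0.0)
        axis = cfg.wavelength_axis()
        band = int(np.argmin(np.abs(axis - 1450.0)))  # strong lean water feature
        means = []
        for grade in (1, 2, 3):
            cube, refs, truth = simulate_sample(cfg, grade, "intact", rng)
            refl = correct_reflectance(cube, refs)
            means.append(refl.data[truth.mask][:, band].mean())
        assert means[0] < means[1] < means[2]

    def test_reflectance_and_dn_ranges(self, tiny_config, rng):
        cube, refs, truth = simulate_sample(tiny_config, 3, "sliced", rng)
        refl = correct_reflectance(cube, refs)
        noise_margin = 6 * tiny_config.noise_sd / tiny_config.dn_gain
        assert refl.data.min() > -noise_margin
        assert refl.data.max() < 1.0 + noise_margin
        assert cube.data.min() >= 0
        assert cube.data.max() < 65535

    def test_fractions_sum_to_one_and_mask_matches_geometry(self, tiny_config, rng):
        cube, refs, truth = simulate_sample(tiny_config, 2, "intact", rng)
        assert np.allclose(truth.fractions.sum(axis=2), 1.0)
        assert np.array_equal(truth.fractions[..., 3] == 1.0, ~truth.mask)

    def test_zero_dispersion_gives_uniform_pixels(self, clean_config):
        cfg = dataclasses.replace(clean_config, noise_sd=0.0)
        cube, refs, truth = simulate_sample(cfg, 1, "intact", np.random.default_rng(3))
        refl = correct_reflectance(cube, refs)
        pixels = refl.data[truth.mask]
        assert np.allclose(pixels.std(axis=0), 0.0, atol=1e-12)

    def test_bad_grade_and_form_rejected(self, tiny_config, rng):
        with pytest.raises(ValueError, match="grade"):
            simulate_sample(tiny_config, 4, "intact", rng)
        with pytest.raises(ValueError, match="form"):
            simulate_sample(tiny_config, 1, "minced", rng)


class TestDataset:
    def test_manifest_counts(self, tmp_path, tiny_config):
        manifest = simulate_dataset(tiny_config, tmp_path / "ds")
        n, s = tiny_config.n_intact_per_grade, tiny_config.slices_per_sausage
        assert len(manifest) == 3 * n * (1 + s)
        for grade in (1, 2, 3):
            block = manifest[manifest.grade == grade]
            assert (block.form == "intact").sum() == n
            assert (block.form == "sliced").sum() == n * s

    def test_default_layout_yields_150_slices_per_grade(self):
        """50 sausages per grade x 3 slices = 150 slices per grade."""
        cfg = SyntheticConfig()
        assert cfg.n_intact_per_grade * cfg.slices_per_sausage == 150

    def test_no_slices(self, tmp_path):
        cfg = SyntheticConfig(n_intact_per_grade=1, slices_per_sausage=0, rows=16, cols=12)
        manifest = simulate_dataset(cfg, tmp_path / "ds")
        assert len(manifest) == 3
        assert (manifest.form == "intact").all()

    def test_slices_inherit_parent_grade(self, tiny_config):
        for record, *_ in iter_dataset(tiny_config):
            if record["form"] == "sliced":
                assert record["parent_id"]
                assert record["id"].startswith(record["parent_id"])

    def test_manifest_round_trip_records_seed(self, tmp_path, tiny_config):
        simulate_dataset(tiny_config, tmp_path / "ds")
        text = (tmp_path / "ds" / "manifest.csv").read_text()
        assert text.startswith(f"# seed = {tiny_config.seed}\n")
        back = read_manifest(tmp_path / "ds" / "manifest.csv")
        assert len(back) == 3 * tiny_config.n_intact_per_grade * (
            1 + tiny_config.slices_per_sausage
        )

    def test_unwritable_path_rejected(self, tiny_config):
        with pytest.raises(OSError):
            simulate_dataset(tiny_config, "/proc/nonexistent/ds")


class TestConfigValidation:
    def test_lean_means_must_decrease(self):
        with pytest.raises(ValueError, match="decrease"):
            SyntheticConfig(grade_lean_means=(0.5, 0.6, 0.4))

    def test_multiplier_must_exceed_one(self):
        with pytest.raises(ValueError, match="multiplier"):
            SyntheticConfig(slice_variance_multiplier=0.9)

    def test_endmember_reflectance_bounds_enforced(self):
        ems = {c: Endmember(c, 0.5) for c in COMPONENTS}
        ems["lean"] = Endmember("lean", 0.995)
        with pytest.raises(ValueError, match="lean"):
            SyntheticConfig(endmembers=ems)


class TestVariabilityStructure:
    def test_sliced_roi_means_vary_more_than_intact(self):
        """Between-sample SD of ROI means: sliced > intact at every band."""
        n_seeds = 20
        ratios = []
        for seed in range(n_seeds):
            cfg = SyntheticConfig(
                n_intact_per_grade=8, slices_per_sausage=3, rows=20, cols=14, seed=seed
            )
            E = cfg.endmember_matrix()
            by_form = {"intact": [], "sliced": []}
            for record, cube, refs, truth in iter_dataset(cfg):
                if record["grade"] != 2:
                    continue
                refl = correct_reflectance(cube, refs)
                by_form[record["form"]].append(refl.data[truth.mask].mean(axis=0))
            sd_i = np.std(by_form["intact"], axis=0, ddof=1)
            sd_s = np.std(by_form["sliced"], axis=0, ddof=1)
            ratios.append(sd_s / sd_i)
        mean_ratio = np.mean(ratios, axis=0)
        assert np.all(mean_ratio > 1.0)

    def test_grade_separation_monotone_in_fraction_gap(self, clean_config):
        """Wider configured lean-fraction gaps -> farther grade-mean spectra."""
        distances = []
        for means in [(0.55, 0.50, 0.45), (0.65, 0.55, 0.45), (0.75, 0.60, 0.45)]:
            cfg = dataclasses.replace(
                clean_config, grade_lean_means=means, noise_sd=0.0
            )
            rng = np.random.default_rng(0)
            spectra = {}
            for grade in (1, 2, 3):
                cube, refs, truth = simulate_sample(cfg, grade, "intact", rng)
                refl = correct_reflectance(cube, refs)
                spectra[grade] = refl.data[truth.mask].mean(axis=0)
            distances.append(np.linalg.norm(spectra[1] - spectra[3]))
        assert distances[0] < distances[1] < distances[2]
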