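import dataclasses

import numpy as np
import pytest

from hsigrade import (
    SpectralCube,
    SpectrumTable,
    correct_reflectance,
    denoise_spectrum,
    extract_mean_spectrum,
    segment_sample,
    simulate_sample,
    summarize_grades,
)


def refl_cube(data, wl=None):
    data = np.asarray(data, dtype=float)
    if wl is None:
        wl = 1000.0 + 10.0 * np.arange(data.shape[2])
    return SpectralCube(data, wl, kind="reflectance")


class TestSegmentation:
    def test_recovers_exact_geometry_on_clean_sample(self, clean_config):
        cfg = dataclasses.replace(clean_config, noise_sd=0.0)
        cube, refs, truth = simulate_sample(cfg, 1, "intact", np.random.default_rng(0))
        mask = segment_sample(correct_reflectance(cube, refs))
        assert np.array_equal(mask, truth.mask)

    def test_constant_cube_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            segment_sample(refl_cube(np.full((8, 8, 4), 0.05)))

    def test_raw_cube_rejected(self):
        cube = SpectralCube(np.zeros((4, 4, 3)), np.arange(3.0), kind="raw")
        with pytest.raises(ValueError, match="reflectance"):
            segment_sample(cube)

    def test_iou_on_noisy_samples(self, tiny_config):
        rng = np.random.default_rng(5)
        for grade, form in [(1, "intact"), (2, "sliced"), (3, "intact")]:
            cube, refs, truth = simulate_sample(tiny_config, grade, form, rng)
            mask = segment_sample(correct_reflectance(cube, refs))
            iou = (mask & truth.mask).sum() / (mask | truth.mask).sum()
            assert iou >= 0.95


class TestDenoise:
    def test_constant_spectrum_unchanged(self):
        x = np.full(200, 0.42)
        assert np.allclose(denoise_spectrum(x), x, atol=1e-9)

    def test_length_preserved(self, rng):
        x = rng.normal(size=200)
        assert denoise_spectrum(x).shape == (200,)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            denoise_spectrum(np.zeros(30))

    def test_reduces_noise_on_smooth_signal(self, rng):
        """Monte-Carlo: denoised MSE beats noisy MSE for a smooth sinusoid."""
        t = np.linspace(0, 4 * np.pi, 200)
        clean = 0.5 + 0.2 * np.sin(t)
        noisy = clean + rng.normal(0, 0.02, size=(50, 200))
        den = denoise_spectrum(noisy)
        mse_noisy = ((noisy - clean) ** 2).mean(axis=1)
        mse_den = ((den - clean) ** 2).mean(axis=1)
        assert mse_den.mean() < mse_noisy.mean()
        assert (mse_den < mse_noisy).mean() > 0.9

    def test_near_idempotent(self, rng):
        """Second application changes less than the first (contraction)."""
        x = 0.5 + 0.2 * np.sin(np.linspace(0, 12, 200)) + rng.normal(0, 0.05, 200)
        once = denoise_spectrum(x)
        twice = denoise_spectrum(once)
        assert np.linalg.norm(twice - once) < np.linalg.norm(once - x)

    def test_vectorized_matches_per_row(self, rng):
        X = rng.normal(0.5, 0.05, size=(7, 200))
        stacked = denoise_spectrum(X)
        rows = np.stack([denoise_spectrum(r) for r in X])
        assert np.allclose(stacked, rows)


class TestExtractMeanSpectrum:
    def test_plain_average(self):
        data = np.zeros((1, 2, 3))
        data[0, 0] = [0.2, 0.2, 0.2]
        data[0, 1] = [0.4, 0.4, 0.4]
        mask = np.array([[True, True]])
        out = extract_mean_spectrum(refl_cube(data), mask, denoise=False)
        assert np.allclose(out, 0.3)

    def test_single_pixel_is_its_denoised_spectrum(self, rng):
        data = rng.uniform(0.3, 0.7, size=(1, 1, 200))
        mask = np.ones((1, 1), dtype=bool)
        out = extract_mean_spectrum(refl_cube(data), mask, denoise=True)
        assert np.allclose(out, denoise_spectrum(data[0, 0]))

    def test_denoise_then_average_order(self, rng):
        """Thresholding is nonlinear: pipeline denoises pixels, then averages."""
        base = 0.5 + 0.1 * np.sin(np.linspace(0, 10, 200))
        data = np.stack([base + rng.normal(0, 0.08, 200),
                         base + rng.normal(0, 0.001, 200)])[None]
        mask = np.ones((1, 2), dtype=bool)
        cube = refl_cube(data)
        pipeline_out = extract_mean_spectrum(cube, mask, denoise=True)
        mean_then_denoise = denoise_spectrum(data[0].mean(axis=0))
        assert np.allclose(pipeline_out, denoise_spectrum(data[0]).mean(axis=0))
        assert not np.allclose(pipeline_out, mean_then_denoise, atol=1e-6)

    def test_pixel_permutation_invariant(self, rng):
        data = rng.uniform(0.2, 0.8, size=(4, 5, 200))
        mask = rng.random((4, 5)) > 0.4
        out = extract_mean_spectrum(refl_cube(data), mask)
        perm = rng.permutation(np.argwhere(mask))
        data2 = data.copy()
        data2[tuple(np.argwhere(mask).T)] = data[tuple(perm.T)]
        out2 = extract_mean_spectrum(refl_cube(data2), mask)
        assert np.allclose(out, out2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_mean_spectrum(refl_cube(np.zeros((2, 2, 3))), np.zeros((2, 2), bool))


class TestSummarizeGrades:
    def make_table(self, spectra, grades):
        spectra = np.asarray(spectra)
        return SpectrumTable(
            spectra, np.arange(spectra.shape[1], dtype=float),
            np.asarray(grades), np.array(["intact"] * len(grades), dtype=object),
            np.arange(len(grades)).astype(str),
        )

    def test_identical_samples_have_zero_sd(self):
        base = 0.5 + 0.1 * np.sin(np.linspace(0, 6, 80))
        table = self.make_table([base] * 6, [1, 1, 2, 2, 3, 3])
        summary = summarize_grades(table)
        assert summary.extrema_indices.size > 0
        for g in (1, 2, 3):
            assert np.allclose(summary.grade_sd_at_extrema[g], 0.0)

    def test_constant_offset_between_grades(self):
        base = 0.5 + 0.1 * np.sin(np.linspace(0, 6, 80))
        table = self.make_table(
            [base, base, base + 0.07, base + 0.07], [1, 1, 2, 2]
        )
        summary = summarize_grades(table)
        assert np.allclose(summary.grade_means[2] - summary.grade_means[1], 0.07)

    def test_undersized_grade_rejected(self):
        base = np.linspace(0, 1, 30)
        table = self.make_table([base, base, base], [1, 1, 2])
        with pytest.raises(ValueError, match="grade 2"):
            summarize_grades(table)


class TestSpectrumTableIO:
    def test_csv_round_trip(self, tmp_path, rng):
        table = SpectrumTable(
            rng.uniform(size=(4, 6)),
            1000.0 + 3.37 * np.arange(6),
            np.array([1, 2, 3, 1]),
            np.array(["intact", "sliced", "intact", "sliced"], dtype=object),
            np.array(["a", "b", "c", "d"], dtype=object),
        )
        table.to_csv(tmp_path / "t.csv")
        back = SpectrumTable.from_csv(tmp_path / "t.csv")
        assert np.allclose(back.spectra, table.spectra, atol=1e-9)
        assert np.array_equal(back.grades, table.grades)
        assert np.array_equal(back.ids, table.ids)
        # header wavelengths carry 2 decimals
        assert back.wavelengths[1] == pytest.approx(1003.37)


class TestGradeOverlapInvariant:
    def test_default_dataset_grade_means_overlap(self, default_table):
        """Grade-mean spectra overlap: at every band, each pairwise mean gap
        stays inside the sum of the two grades' between-sample SD envelopes."""
        t = default_table
        means = {g: t.spectra[t.grades == g].mean(axis=0) for g in (1, 2, 3)}
        sds = {g: t.spectra[t.grades == g].std(axis=0, ddof=1) for g in (1, 2, 3)}
        for a, b in ((1, 2), (1, 3), (2, 3)):
            assert np.all(np.abs(means[a] - means[b]) < sds[a] + sds[b])
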