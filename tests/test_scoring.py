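import numpy as np
import pytest

from ionrank.io import IonImage
from ionrank.isotopes import IonCandidate, IsotopePattern, pattern_for
from ionrank.scoring import (
    FeatureVector,
    compute_features,
    msm,
    mz_error_abs,
    mz_error_rel,
    observed_isotope_stack,
    rho_chaos,
    rho_spatial,
    rho_spectral,
)

from conftest import grid_dataset


def image(values, mask=None):
    values = np.asarray(values, dtype=float)
    return IonImage(values=values, mask=np.ones_like(values, bool) if mask is None else mask)


class TestObservedStack:
    def test_unweighted_mean_mz(self):
        ds = grid_dataset([([100.0], [2.0]), ([100.0004], [2.0])], shape=(1, 2))
        pat = IsotopePattern(mzs=(100.0002,), rel_intensities=(1.0,))
        stack = observed_isotope_stack(ds, pat, tol_ppm=5.0)
        assert stack.mean_mz[0] == pytest.approx(100.0002, abs=1e-9)

    def test_intensity_weighted_mean_mz(self):
        ds = grid_dataset([([100.0], [1.0]), ([100.0004], [3.0])], shape=(1, 2))
        pat = IsotopePattern(mzs=(100.0002,), rel_intensities=(1.0,))
        stack = observed_isotope_stack(ds, pat, tol_ppm=5.0)
        assert stack.mean_mz[0] == pytest.approx(100.0003, abs=1e-9)

    def test_unmatched_isotope_flagged_missing(self):
        ds = grid_dataset([([100.0], [1.0])], shape=(1, 1))
        pat = IsotopePattern(mzs=(100.0, 200.0), rel_intensities=(1.0, 0.1))
        stack = observed_isotope_stack(ds, pat, tol_ppm=3.0)
        assert not stack.missing[0] and stack.missing[1]


class TestMzErrors:
    def test_zero_error(self):
        assert mz_error_abs(500.0, 500.0) == 1.0

    def test_direct_arithmetic(self):
        assert mz_error_abs(500.0005, 500.0) == pytest.approx(0.9995)

    def test_uniform_shift_cancels(self):
        d = np.full(4, 0.001)
        rel = np.array([1.0, 0.5, 0.3, 0.2])
        assert mz_error_rel(d, rel, np.ones(4, bool)) == pytest.approx(1.0)

    def test_weighted_deviation(self):
        d = np.array([0.0, 0.002, 0.0, 0.0])
        rel = np.array([1.0, 0.5, 0.3, 0.2])
        assert mz_error_rel(d, rel, np.ones(4, bool)) == pytest.approx(0.999)

    def test_only_first_isotope_observed(self):
        d = np.zeros(4)
        rel = np.array([1.0, 0.5, 0.3, 0.2])
        observed = np.array([True, False, False, False])
        assert mz_error_rel(d, rel, observed) == 0.0

    def test_missing_higher_isotopes_excluded_from_sums(self):
        d = np.array([0.0, 0.002, 99.0, 99.0])  # garbage in missing slots
        rel = np.array([1.0, 0.5, 0.3, 0.2])
        observed = np.array([True, True, False, False])
        assert mz_error_rel(d, rel, observed) == pytest.approx(1 - 0.002)


class TestRhoSpectral:
    def test_proportional_is_perfect(self):
        p = np.array([1.0, 0.4, 0.1])
        assert rho_spectral(p, 7.0 * p) == pytest.approx(1.0)

    def test_hand_l1(self):
        assert rho_spectral(np.array([0.7, 0.2, 0.1]), np.array([1.0, 0.0, 0.0])) == pytest.approx(0.7)

    def test_all_zero_observed(self):
        assert rho_spectral(np.array([1.0, 0.5]), np.zeros(2)) == 0.0

    def test_invariant_under_rescaling(self):
        p = np.array([1.0, 0.3, 0.1, 0.05])
        q = np.array([10.0, 2.0, 1.5, 0.1])
        assert rho_spectral(p, q) == pytest.approx(rho_spectral(p, 1e6 * q))


class TestRhoSpatial:
    def test_scalar_multiples_perfect(self):
        base = image([[1.0, 2.0], [3.0, 4.0]])
        imgs = [base, image(2 * base.values), image(0.5 * base.values)]
        rel = np.array([1.0, 0.5, 0.2])
        assert rho_spatial(imgs, rel) == pytest.approx(1.0)

    def test_all_higher_missing(self):
        base = image([[1.0, 2.0], [3.0, 4.0]])
        imgs = [base, image(np.zeros((2, 2))), image(np.zeros((2, 2)))]
        assert rho_spatial(imgs, np.array([1.0, 0.5, 0.2])) == 0.0

    def test_weighted_mean_of_correlations(self):
        base = image([[1.0, 2.0], [3.0, 4.0]])
        perfect = image(base.values.copy())
        uncorrelated = image(np.full((2, 2), 5.0))  # zero variance -> corr 0
        rel = np.array([1.0, 0.6, 0.4])
        assert rho_spatial([base, perfect, uncorrelated], rel) == pytest.approx(0.6)

    def test_negative_correlation_clipped(self):
        base = image([[1.0, 2.0], [3.0, 4.0]])
        anti = image(5.0 - base.values)
        assert rho_spatial([base, anti], np.array([1.0, 1.0])) == 0.0

    def test_constant_first_image(self):
        base = image(np.ones((2, 2)))
        other = image([[1.0, 2.0], [3.0, 4.0]])
        assert rho_spatial([base, other], np.array([1.0, 1.0])) == 0.0

    def test_invariant_under_positive_affine_map(self):
        rng = np.random.default_rng(2)
        base = image(rng.uniform(0, 10, (4, 4)))
        second = image(rng.uniform(0, 10, (4, 4)))
        rel = np.array([1.0, 0.4])
        before = rho_spatial([base, second], rel)
        after = rho_spatial([base, image(3.0 * second.values + 2.0)], rel)
        assert after == pytest.approx(before, abs=1e-12)


class TestRhoChaos:
    def test_solid_blob(self):
        values = np.zeros((20, 20))
        values[5:15, 5:15] = 7.0  # 100-pixel solid square
        assert rho_chaos(image(values)) == pytest.approx(0.99)

    def test_checkerboard_isolated_pixels(self):
        values = np.indices((10, 10)).sum(axis=0) % 2 * 3.0
        assert rho_chaos(image(values)) == pytest.approx(0.0)

    def test_empty_image(self):
        assert rho_chaos(image(np.zeros((5, 5)))) == 0.0


class TestMsm:
    def test_product(self):
        assert msm(FeatureVector(0.5, 0.8, 0.9, 1.0, 1.0)) == pytest.approx(0.36)

    def test_any_zero_factor(self):
        assert msm(FeatureVector(0.0, 0.8, 0.9, 1.0, 1.0)) == 0.0

    def test_bounded_by_factors(self):
        fv = FeatureVector(0.7, 0.6, 0.9, 1.0, 1.0)
        assert msm(fv) <= min(fv.rho_spatial, fv.rho_spectral, fv.rho_chaos)


class TestComputeFeatures:
    def test_planted_ion_noiseless_limit(self, noiseless_dataset):
        ds, truth = noiseless_dataset
        formula, adduct = truth.planted[0]
        cand = IonCandidate(formula, adduct, "positive", False, pattern_for(formula, adduct))
        fv = compute_features(ds, cand)
        assert fv.rho_spectral == pytest.approx(1.0, abs=1e-6)
        assert fv.mz_error_abs == pytest.approx(1.0, abs=1e-9)
        assert fv.mz_error_rel == pytest.approx(1.0, abs=1e-9)
        assert fv.rho_spatial > 0.95 and fv.rho_chaos > 0.9

    def test_no_matched_peaks_gives_zeros(self, noiseless_dataset):
        ds, _ = noiseless_dataset
        pat = IsotopePattern(mzs=(1500.0, 1501.0), rel_intensities=(1.0, 0.1))
        cand = IonCandidate("X", "+H", "positive", False, pat)
        fv = compute_features(ds, cand)
        assert fv.as_array().tolist() == [0.0, 0.0, 0.0, 0.0, 0.0]

    def test_mz_errors_invariant_under_intensity_rescaling(self, clean_dataset):
        ds, truth = clean_dataset
        formula, adduct = truth.planted[0]
        cand = IonCandidate(formula, adduct, "positive", False, pattern_for(formula, adduct))
        fv1 = compute_features(ds, cand)
        scaled = grid_dataset(
            [
                (ds.spectra[p].mz.copy(), 100.0 * ds.spectra[p].intensity)
                for p in sorted(ds.spectra)
            ],
            shape=ds.grid_shape(),
        )
        fv2 = compute_features(scaled, cand)
        assert fv2.mz_error_abs == pytest.approx(fv1.mz_error_abs, abs=1e-12)
        assert fv2.mz_error_rel == pytest.approx(fv1.mz_error_rel, abs=1e-12)
        assert fv2.rho_spectral == pytest.approx(fv1.rho_spectral, abs=1e-12)

    def test_features_within_bounds(self, clean_dataset, toy_db):
        ds, _ = clean_dataset
        from ionrank.isotopes import build_candidates

        cands, _ = build_candidates(toy_db[:4], target_adducts=("+H",), S_D=3, seed=0)
        for cand in cands:
            fv = compute_features(ds, cand)
            for rho in (fv.rho_spatial, fv.rho_spectral, fv.rho_chaos):
                assert 0.0 <= rho <= 1.0
            assert fv.mz_error_abs <= 1.0 and fv.mz_error_rel <= 1.0
            assert 0.0 <= msm(fv) <= 1.0
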