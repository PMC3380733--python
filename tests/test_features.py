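import numpy as np
import pytest

from msqc import features as F
from msqc.spectra import Spectrum

from conftest import random_spectrum

C = F.MassConstants()
GLY = C.residue_masses["G"]


# ---------------------------------------------------------------------------
# brute-force oracles: plain O(p^2) double loops over unordered pairs

def brute_diff_count(s, targets, tol=C.tolerance):
    mz = s.mz
    return sum(
        1
        for i in range(len(mz)) for j in range(i + 1, len(mz))
        if any(abs(abs(mz[j] - mz[i]) - t) <= tol for t in targets)
    )


def brute_diff_normi(s, targets, tol=C.tolerance):
    mz, w = s.mz, F.normalized_intensities(s)
    return sum(
        w[i] + w[j]
        for i in range(len(mz)) for j in range(i + 1, len(mz))
        if any(abs(abs(mz[j] - mz[i]) - t) <= tol for t in targets)
    )


def brute_sum_count(s, target, tol=C.tolerance):
    mz = s.mz
    return sum(
        1
        for i in range(len(mz)) for j in range(i + 1, len(mz))
        if abs(mz[i] + mz[j] - target) <= tol
    )


def brute_sum_normi(s, target, tol=C.tolerance):
    mz, w = s.mz, F.normalized_intensities(s)
    return sum(
        w[i] + w[j]
        for i in range(len(mz)) for j in range(i + 1, len(mz))
        if abs(mz[i] + mz[j] - target) <= tol
    )


# ---------------------------------------------------------------------------

class TestHandDerivedFixture:
    """The three-peak fixture where every feature is checkable by hand."""

    def test_full_vector(self, spectrum_a):
        expected = [0.7, 600.0, 1, 100.0, 0.4, 1, 0, 1.0, 60.783, 0]
        np.testing.assert_allclose(F.feature_vector(spectrum_a), expected,
                                   rtol=0, atol=1e-3)

    def test_f9_sample_convention(self, spectrum_a):
        # gaps 57.02 and 142.98: sample (n-1) sd = |diff| / sqrt(2)
        assert F.f9_delta_mass_std(spectrum_a) == pytest.approx(85.96 / np.sqrt(2))


class TestNormalizedIntensities:
    def test_proportions(self, spectrum_a):
        np.testing.assert_allclose(F.normalized_intensities(spectrum_a),
                                   [0.1, 0.3, 0.6])

    def test_single_peak_and_sum_to_one(self):
        s = Spectrum.from_arrays("one", 500, 1, [100.0], [42.0])
        assert F.normalized_intensities(s)[0] == 1.0
        rng = np.random.default_rng(5)
        for _ in range(20):
            assert F.normalized_intensities(random_spectrum(rng)).sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_spectrum_errors(self):
        s = Spectrum("e", 500, 1, [])
        with pytest.raises(ValueError):
            F.normalized_intensities(s)


class TestUnchargedPrecursorMass:
    def test_singly_charged(self, spectrum_a):
        assert F.f2_uncharged_precursor_mass(spectrum_a) == pytest.approx(600.0, abs=1e-4)

    def test_doubly_charged(self):
        s = Spectrum.from_arrays("z2", 500.5, 2, [100.0], [1.0])
        assert F.f2_uncharged_precursor_mass(s) == pytest.approx(
            2 * 500.5 - 2 * C.proton)

    def test_boundary_zero(self):
        s = Spectrum.from_arrays("p", C.proton, 1, [100.0], [1.0])
        assert F.f2_uncharged_precursor_mass(s) == pytest.approx(0.0, abs=1e-9)


class TestPairFeatureEdgeCases:
    def test_no_matches_give_zero(self):
        s = Spectrum.from_arrays("nm", 5000.0, 1, [100.0, 100.6], [1, 1])
        assert F.f3_aa_difference_count(s) == 0
        assert F.f5_good_diff_fraction(s) == 0.0
        assert F.f6_complementary_pair_count(s) == 0
        assert F.f1_complement_intensity(s) == 0.0

    def test_degenerate_single_peak_is_zero_not_error(self):
        s = Spectrum.from_arrays("one", 500, 1, [100.0], [1.0])
        assert F.f1_complement_intensity(s) == 0.0
        assert F.f3_aa_difference_count(s) == 0
        assert F.f4_mean_delta_mass(s) == 0.0
        assert F.f5_good_diff_fraction(s) == 0.0
        assert F.f6_complementary_pair_count(s) == 0
        assert F.f9_delta_mass_std(s) == 0.0

    def test_two_peaks_exactly_one_gly_apart_equal_intensity(self):
        s = Spectrum.from_arrays("gly", 2000, 1, [300.0, 300.0 + GLY], [7, 7])
        assert F.f5_good_diff_fraction(s) == pytest.approx(1.0)
        assert F.f3_aa_difference_count(s) == 1

    def test_all_peaks_paired_gives_f1_of_one(self):
        # two disjoint complementary pairs covering all peaks
        target = 900.0
        mz = [200.0, 300.0, 600.0, 700.0]
        s = Spectrum.from_arrays("paired", target + C.proton, 1, mz, [1, 2, 3, 4])
        assert F.f1_complement_intensity(s) == pytest.approx(1.0)
        assert F.f6_complementary_pair_count(s) == 2

    def test_f1_capped_at_one_under_overlapping_pairs(self):
        # peak at target/2 pairs with both of its tolerant neighbours
        target = 800.0
        mz = [399.9, 400.0, 400.1]
        s = Spectrum.from_arrays("cap", target + C.proton, 1, mz, [1, 1, 1])
        assert F.f6_complementary_pair_count(s) == 3
        assert F.f1_complement_intensity(s) == 1.0

    def test_neutral_loss_pairs(self):
        s1 = Spectrum.from_arrays("w", 2000, 1, [300.0, 318.01], [1, 1])
        assert F.f7_neutral_loss_pair_count(s1) == 1
        s2 = Spectrum.from_arrays("wa", 2000, 1, [300.0, 317.03, 318.01], [1, 1, 1])
        assert F.f7_neutral_loss_pair_count(s2) == 2

    def test_support_ion_pairs(self):
        assert F.f10_support_ion_pair_count(
            Spectrum.from_arrays("co", 2000, 1, [300.0, 327.99], [1, 1])) == 1
        assert F.f10_support_ion_pair_count(
            Spectrum.from_arrays("nh", 2000, 1, [300.0, 315.01], [1, 1])) == 1

    def test_k_disjoint_planted_complement_pairs(self):
        target = 1200.0
        rng = np.random.default_rng(11)
        for k in (1, 2, 5):
            lows = rng.uniform(150, 450, size=k)
            mz = np.concatenate([lows, target - lows])
            s = Spectrum.from_arrays("plant", target + C.proton, 1, mz,
                                     np.ones(2 * k))
            assert F.f6_complementary_pair_count(s) == k


class TestDeltaMassFeatures:
    def test_equally_spaced(self):
        s = Spectrum.from_arrays("eq", 2000, 1, [100, 150, 200, 250], [1] * 4)
        assert F.f4_mean_delta_mass(s) == pytest.approx(50.0)
        assert F.f9_delta_mass_std(s) == 0.0

    def test_two_peaks(self):
        s = Spectrum.from_arrays("two", 2000, 1, [100.0, 173.5], [1, 1])
        assert F.f4_mean_delta_mass(s) == pytest.approx(73.5)
        assert F.f9_delta_mass_std(s) == 0.0  # degenerate rule


class TestIntensePeakRatio:
    def test_one_dominant_peak(self):
        s = Spectrum.from_arrays("dom", 500, 1, [100, 200, 300], [100, 0.5, 0.4])
        assert F.f8_intense_peak_ratio(s) == pytest.approx(1 / 3)

    def test_uniform_small_spectrum(self):
        s = Spectrum.from_arrays("uni", 500, 1, np.arange(1, 21) * 50.0, [3.0] * 20)
        assert F.f8_intense_peak_ratio(s) == 1.0


@pytest.fixture(scope="module")
def random_spectra():
    rng = np.random.default_rng(1234)
    return [random_spectrum(rng) for _ in range(100)]


class TestOracleEquivalence:
    """Windowed pair search == brute-force double loop on random spectra."""

    def test_f3_f5_vs_residue_oracle(self, random_spectra):
        targets = list(C.residue_masses.values())
        for s in random_spectra:
            assert F.f3_aa_difference_count(s) == brute_diff_count(s, targets)
            assert F.f5_good_diff_fraction(s) == pytest.approx(
                brute_diff_normi(s, targets), abs=1e-10)

    def test_f7_f10_vs_loss_oracle(self, random_spectra):
        for s in random_spectra:
            assert F.f7_neutral_loss_pair_count(s) == brute_diff_count(
                s, [C.water, C.ammonia])
            assert F.f10_support_ion_pair_count(s) == brute_diff_count(
                s, [C.co_group, C.nh_group])

    def test_f1_f6_vs_sum_oracle(self, random_spectra):
        for s in random_spectra:
            target = C.pair_sum_target(s)
            assert F.f6_complementary_pair_count(s) == brute_sum_count(s, target)
            assert F.f1_complement_intensity(s) == pytest.approx(
                min(1.0, brute_sum_normi(s, target)), abs=1e-10)


class TestInvariances:
    def test_intensity_scaling(self, spectrum_a):
        scaled = Spectrum.from_arrays("S_A*7", spectrum_a.precursor_mz, 1,
                                      spectrum_a.mz, spectrum_a.intensity * 7)
        np.testing.assert_allclose(F.feature_vector(scaled),
                                   F.feature_vector(spectrum_a), rtol=1e-12)

    def test_peak_order_is_canonical(self, spectrum_a):
        shuffled = Spectrum.from_arrays("S_A_shuf", spectrum_a.precursor_mz, 1,
                                        spectrum_a.mz[::-1],
                                        spectrum_a.intensity[::-1])
        np.testing.assert_allclose(F.feature_vector(shuffled),
                                   F.feature_vector(spectrum_a), rtol=1e-12)

    def test_planting_complementary_pair_never_decreases_f1_f6(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            s = random_spectrum(rng)
            target = C.pair_sum_target(s)
            lo = float(rng.uniform(120, target / 2 - 10))
            mz = np.concatenate([s.mz, [lo, target - lo]])
            inten = np.concatenate([s.intensity, [5.0, 5.0]])
            planted = Spectrum.from_arrays("plus", s.precursor_mz,
                                           s.precursor_charge, mz, inten)
            assert F.f6_complementary_pair_count(planted) >= F.f6_complementary_pair_count(s)
            assert F.f1_complement_intensity(planted) >= min(
                1.0, F.f1_complement_intensity(s) - 1e-12)


class TestFeatureMatrix:
    def test_fixture_row(self, spectrum_a):
        df = F.compute_feature_matrix([spectrum_a])
        assert list(df.columns) == F.FEATURE_NAMES
        np.testing.assert_allclose(
            df.loc["S_A"], [0.7, 600.0, 1, 100.0, 0.4, 1, 0, 1.0, 60.783, 0],
            atol=1e-3)

    def test_empty_input(self):
        df = F.compute_feature_matrix([])
        assert df.shape == (0, 10)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        spectra = [random_spectrum(rng) for _ in range(6)]
        a = F.compute_feature_matrix(spectra)
        b = F.compute_feature_matrix(spectra[::-1])
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy()[::-1])

    def test_tsv_round_trip(self, spectrum_a, tmp_path):
        df = F.compute_feature_matrix([spectrum_a])
        path = tmp_path / "features.tsv"
        F.write_feature_table(df, path)
        back = F.read_feature_table(path)
        np.testing.assert_allclose(back.to_numpy(), df.to_numpy())


class TestMassConstants:
    def test_defaults_from_standard_tables(self):
        assert C.residue_masses["G"] == pytest.approx(57.02146, abs=1e-4)
        assert C.water == pytest.approx(18.01056, abs=1e-4)
        assert C.tolerance == 0.5

    def test_yaml_overrides(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("tolerance: 0.25\nresidue_masses:\n  G: 57.0\n")
        c = F.MassConstants.from_yaml(p)
        assert c.tolerance == 0.25
        assert c.residue_masses["G"] == 57.0
        assert c.residue_masses["A"] == pytest.approx(71.03711, abs=1e-4)

    def test_pair_sum_conventions(self, spectrum_a):
        neutral = C.pair_sum_target(spectrum_a)
        prot = F.MassConstants(pair_sum_convention="protonated").pair_sum_target(spectrum_a)
        by_pair = F.MassConstants(pair_sum_convention="by_pair").pair_sum_target(spectrum_a)
        assert neutral == pytest.approx(600.0, abs=1e-4)
        assert prot == pytest.approx(601.00728, abs=1e-4)
        assert by_pair == pytest.approx(neutral + 2 * C.proton)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            F.MassConstants(tolerance=0.0)
        with pytest.raises(ValueError):
            F.MassConstants(pair_sum_convention="nope")
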