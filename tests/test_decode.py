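import numpy as np
import pytest
from scipy import linalg as sla

from sskit.codec import AliasingError, build_codebook
from sskit.decode import (
    FilterBankSpec,
    cca_coefficient,
    classify,
    default_filterbank,
    filterbank_classify,
    make_reference,
    phase_shift_template,
)
from sskit.synth import AcquisitionSpec, Epoch, SSVEPModel, simulate_epoch, simulate_session


def cca_oracle(X, Y, ridge=1e-12):
    """Independent brute-force CCA: generalized eigenproblem
    Cxy Cyy^-1 Cyx v = rho^2 Cxx v, solved with scipy.linalg.eigh."""
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Cxx = Xc @ Xc.T / n
    Cyy = Yc @ Yc.T / n
    Cxy = Xc @ Yc.T / n
    Cxx = Cxx + ridge * np.trace(Cxx) / Cxx.shape[0] * np.eye(Cxx.shape[0])
    Cyy = Cyy + ridge * np.trace(Cyy) / Cyy.shape[0] * np.eye(Cyy.shape[0])
    A = Cxy @ np.linalg.inv(Cyy) @ Cxy.T
    eigvals = sla.eigh(A, Cxx, eigvals_only=True)
    return float(np.sqrt(max(0.0, eigvals[-1])))


class TestMakeReference:
    def test_shape_is_2h_by_p(self):
        ref = make_reference(10.0, 2, 1000.0, 500)
        assert ref.matrix.shape == (4, 500)

    def test_first_element_matches_closed_form(self):
        ref = make_reference(10.0, 1, 1000.0, 100)
        assert ref.matrix[0, 0] == pytest.approx(np.sin(2 * np.pi * 10 / 1000))
        assert ref.matrix[1, 0] == pytest.approx(np.cos(2 * np.pi * 10 / 1000))

    def test_rows_orthogonal_over_integer_cycles(self):
        # P*f/F = 500*10/1000 = 5 whole cycles
        ref = make_reference(10.0, 3, 1000.0, 500)
        gram = ref.matrix @ ref.matrix.T
        norms = np.sqrt(np.diag(gram))
        off = gram / np.outer(norms, norms) - np.eye(6)
        assert np.abs(off).max() < 1e-10

    def test_harmonic_above_nyquist_rejected(self):
        with pytest.raises(AliasingError):
            make_reference(100.0, 6, 1000.0, 500)


class TestCCACoefficient:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 300))
        res = cca_coefficient(X, X)
        assert res.rho == pytest.approx(1.0, abs=1e-9)

    def test_sinusoid_in_reference_span(self):
        t = np.arange(1000) / 1000.0  # 10 whole cycles of 10 Hz
        x = np.sin(2 * np.pi * 10 * t)[None, :]
        ref = make_reference(10.0, 2, 1000.0, 1000)
        assert cca_coefficient(x, ref.matrix).rho == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_generalized_eigen_oracle(self):
        """50 random instances: production solver vs brute-force oracle."""
        rng = np.random.default_rng(12345)
        for _ in range(50):
            n_ch = rng.integers(1, 9)
            n = int(rng.integers(100, 1001))
            X = rng.standard_normal((n_ch, n))
            f = float(rng.uniform(5, 40))
            H = int(rng.integers(1, 4))
            Y = make_reference(f, H, 1000.0, n).matrix
            assert cca_coefficient(X, Y).rho == pytest.approx(
                cca_oracle(X, Y), abs=1e-8
            )

    def test_channel_scale_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((8, 500))
        Y = make_reference(10.0, 2, 1000.0, 500).matrix
        base = cca_coefficient(X, Y).rho
        X2 = X.copy()
        X2[3] *= 137.0
        assert abs(cca_coefficient(X2, Y).rho - base) < 1e-8

    def test_invertible_channel_mixing_invariance(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((5, 400))
        Y = make_reference(12.0, 2, 1000.0, 400).matrix
        A = rng.standard_normal((5, 5)) + 5 * np.eye(5)
        assert abs(cca_coefficient(A @ X, Y).rho - cca_coefficient(X, Y).rho) < 1e-8

    def test_rho_bounded(self):
        rng = np.random.default_rng(9)
        for seed in range(5):
            X = np.random.default_rng(seed).standard_normal((3, 200))
            rho = cca_coefficient(X, make_reference(9.0, 1, 1000.0, 200).matrix).rho
            assert 0.0 <= rho <= 1.0

    def test_mismatched_samples_rejected(self):
        with pytest.raises(ValueError):
            cca_coefficient(np.ones((2, 100)), np.ones((2, 99)))


class TestClassify:
    def test_noiseless_all_40_targets_recovered(self, codebook40, acq, noiseless_model):
        for code in codebook40.codes:
            ep = simulate_epoch(code, 0.5, noiseless_model, acq, seed=0)
            assert classify(ep, codebook40).predicted_index == code.index

    def test_predicted_frequency_consistent(self, codebook40, acq, noiseless_model):
        ep = simulate_epoch(codebook40[22], 0.5, noiseless_model, acq, seed=0)
        res = classify(ep, codebook40)
        assert res.predicted_frequency == codebook40[res.predicted_index].frequency

    def test_pure_noise_gives_valid_low_rho_decision(self, codebook40):
        # 8-channel white-noise epoch: the spurious canonical correlation
        # of 0.5 s of unstructured noise stays well below 0.5 (a 1/f
        # spectrum or more channels would inflate it)
        acq8 = AcquisitionSpec(montage=("P3", "Pz", "P4", "T5", "T6", "O1", "O2", "Cz"))
        model = SSVEPModel(snr_db=-np.inf, channel_gains=np.ones(8), noise_exponent=0.0)
        ep = simulate_epoch(codebook40[0], 0.5, model, acq8, seed=77)
        res = classify(ep, codebook40)
        assert 0 <= res.predicted_index < 40
        assert np.all(res.rho_per_target < 0.5)

    def test_correlation_spectrum_peaks_at_12p4(self, codebook40, acq):
        """An epoch at 12.4 Hz yields the largest rho at the 12.4 Hz entry,
        clearly above the adjacent-frequency entries."""
        ep = simulate_epoch(codebook40[22], 2.0, SSVEPModel(snr_db=0.0), acq, seed=11)
        res = classify(ep, codebook40)
        assert res.predicted_frequency == pytest.approx(12.4)
        rho = res.rho_per_target
        assert rho[22] > rho[21] + 0.05 and rho[22] > rho[23] + 0.05


class TestPhaseShiftTemplate:
    def test_zero_phase_is_identity(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 500))
        assert np.array_equal(phase_shift_template(x, 10.0, 0.0, 1000.0), x)
        assert np.array_equal(phase_shift_template(x, 10.0, 2 * np.pi, 1000.0), x)

    def test_pi_shift_of_sinusoid_matches_closed_form(self):
        t = np.arange(1000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t)
        shifted = phase_shift_template(x, 10.0, np.pi, 1000.0)
        # shift of ((2*pi - pi)/(2*pi*10))*1000 = 50 samples
        assert np.allclose(shifted, np.sin(2 * np.pi * 10 * t + np.pi), atol=1e-9)

    @pytest.mark.parametrize("phase", [np.pi / 2, np.pi, 1.5 * np.pi])
    def test_quarter_cycle_shifts_exact(self, phase):
        t = np.arange(2000) / 1000.0
        x = np.sin(2 * np.pi * 12.5 * t)  # 80 samples/cycle: all shifts integral
        shifted = phase_shift_template(x, 12.5, phase, 1000.0)
        assert np.allclose(shifted, np.sin(2 * np.pi * 12.5 * t + phase), atol=1e-9)

    def test_shift_and_inverse_shift_round_trip(self):
        """Shifting by phase then by 2*pi - phase moves the template one
        whole cycle, which is the identity when the template length is a
        multiple of the cycle (circular-shift group property)."""
        rng = np.random.default_rng(4)
        x = rng.standard_normal(100)  # exactly one 10 Hz cycle at 1 kHz
        fwd = phase_shift_template(x, 10.0, np.pi / 2, 1000.0)
        back = phase_shift_template(fwd, 10.0, 2 * np.pi - np.pi / 2, 1000.0)
        assert np.array_equal(back, x)


class TestFilterBank:
    def test_single_full_band_matches_plain_cca_decisions(self, codebook4, acq):
        fb = FilterBankSpec(band_edges=((0.5, 100.0),), weights=(1.0,))
        sess = simulate_session(codebook4, 2, 1.0, SSVEPModel(snr_db=-5.0), acq, seed=21)
        for ep in sess:
            assert (
                filterbank_classify(ep, codebook4, fb).predicted_index
                == classify(ep, codebook4).predicted_index
            )

    def test_noiseless_12p4_recovered_with_default_bank(self, codebook40, acq, noiseless_model):
        ep = simulate_epoch(codebook40[22], 0.5, noiseless_model, acq, seed=0)
        res = filterbank_classify(ep, codebook40)
        assert res.predicted_frequency == pytest.approx(12.4)

    def test_filterbank_beats_plain_cca_at_low_snr(self, codebook40, acq):
        """Sub-band weighting exploits harmonics: at -20 dB / 1 s FBCCA
        accuracy is at least that of plain CCA (fixed seed)."""
        sess = simulate_session(codebook40, 1, 1.0, SSVEPModel(snr_db=-20.0), acq, seed=3)
        acc_cca = np.mean([classify(e, codebook40).predicted_index == e.label for e in sess])
        acc_fb = np.mean(
            [filterbank_classify(e, codebook40).predicted_index == e.label for e in sess]
        )
        assert acc_fb >= acc_cca

    def test_default_bank_structure(self):
        fb = default_filterbank()
        assert fb.n_subbands == 5
        assert fb.band_edges[0] == (8.0, 88.0)
        assert fb.band_edges[4] == (40.0, 88.0)
        assert fb.weights[0] == pytest.approx(1.25)

    def test_invalid_bank_rejected(self):
        with pytest.raises(ValueError):
            FilterBankSpec(band_edges=((10.0, 5.0),), weights=(1.0,))
        with pytest.raises(ValueError):
            FilterBankSpec(band_edges=((5.0, 50.0),), weights=(-1.0,))
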