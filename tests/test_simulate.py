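"""Synthetic study generator: determinism, ground truth, mixing, behavior."""

from dataclasses import replace

import numpy as np
import pytest

from isocoh import (CouplingEdge, EpochSet, SimulationConfig, StudyConfig,
                    UnstableModelError, ValidationError,
                    apply_instantaneous_mixing, band_average, build_model,
                    fit_mvar, isolated_effective_coherence, simulate_epochs,
                    simulate_study)
from isocoh.simulate import DEFAULT_REPORT_PROBS

GAMMA = np.arange(30.0, 101.0)

#: small/fast config for generator behavior tests
TINY = SimulationConfig(roi_labels=("L", "R"), epoch_len=0.1, n_trials=8)


class TestSimulateEpochs:
    def test_same_config_and_seed_is_bit_identical(self):
        a = simulate_epochs(TINY, seed=5)
        b = simulate_epochs(TINY, seed=5)
        assert np.array_equal(a.data, b.data)
        assert a.fs == b.fs and a.t0 == b.t0

    def test_unstable_request_fails_naming_radius(self):
        cfg = replace(TINY, coupling_edges=(CouplingEdge("L", "R", 1.5),
                                            CouplingEdge("R", "L", 1.5)))
        with pytest.raises(UnstableModelError, match="spectral radius"):
            simulate_epochs(cfg)

    def test_oscillator_peaks_in_gamma_band(self):
        cfg = SimulationConfig(roi_labels=("L", "R"), n_trials=40)
        ep = simulate_epochs(cfg, seed=3)
        spec = np.abs(np.fft.rfft(ep.data, axis=2)).mean(axis=0)
        freqs = np.fft.rfftfreq(ep.n_samples, 1 / ep.fs)
        peak = freqs[np.argmax(spec[0])]
        assert 30.0 <= peak <= 55.0  # 40 Hz oscillator, coarse 5 Hz grid

    def test_generative_model_is_mvar_ground_truth(self):
        """The generator's stated model is exactly what a fit recovers."""
        cfg = SimulationConfig(
            roi_labels=("L", "R"), n_trials=400,
            coupling_edges=(CouplingEdge("R", "L", 0.3),),
        )
        model = build_model(cfg)
        ep = simulate_epochs(cfg, seed=9)
        res = fit_mvar(ep, order=2)
        assert np.max(np.abs(res.coeffs - model.coeffs)) < 0.05

    def test_condition_dependent_coupling_orders_icoh(self):
        """A strong LE-only rSAC->lSAC edge makes iCoh(lSAC<-rSAC) larger
        in LE than RE in every one of 20 seeded replicates."""
        cfg = SimulationConfig(
            coupling_edges=(CouplingEdge("rSAC", "lSAC", 0.0, {"LE": 0.4}),)
        )
        wins = 0
        for rep in range(20):
            vals = {}
            for cond in ("LE", "RE"):
                ep = simulate_epochs(cfg, condition=cond, seed=700 + rep)
                icoh = isolated_effective_coherence(fit_mvar(ep, 8), GAMMA)
                avg = band_average(icoh, 30, 100)
                vals[cond] = avg[ep.roi_index("lSAC"), ep.roi_index("rSAC")]
            wins += vals["LE"] > vals["RE"]
        assert wins == 20

    def test_null_coupling_stays_at_noise_floor(self):
        """With all couplings zero, band-averaged iCoh and LPS sit at the
        estimator noise floor, far below detectable coupling levels."""
        from isocoh import coherency, lagged_phase_synchronization

        icoh_vals, lps_vals = [], []
        for rep in range(20):
            ep = simulate_epochs(SimulationConfig(), seed=900 + rep)
            l, r = ep.roi_index("lSAC"), ep.roi_index("rSAC")
            avg = band_average(
                isolated_effective_coherence(fit_mvar(ep, 8), GAMMA), 30, 100)
            icoh_vals.append(avg[l, r])
            lps = lagged_phase_synchronization(coherency(ep.demeaned()))
            lps_vals.append(band_average(lps, 30, 100)[l, r])
        assert np.mean(icoh_vals) < 0.02
        assert np.mean(lps_vals) < 0.02


class TestMixing:
    def test_identity_returns_input_unchanged(self, rng):
        ep = EpochSet(rng.standard_normal((3, 2, 16)), ("a", "b"), 256.0)
        out = apply_instantaneous_mixing(ep, np.eye(2))
        assert np.array_equal(out.data, ep.data)

    def test_permutation_relabels_exactly(self, rng):
        ep = EpochSet(rng.standard_normal((3, 2, 16)), ("a", "b"), 256.0)
        out = apply_instantaneous_mixing(ep, np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.array_equal(out.data[:, 0], ep.data[:, 1])
        assert np.array_equal(out.data[:, 1], ep.data[:, 0])

    def test_mixing_independent_noise_gives_expected_correlation(self, rng):
        """[[1, .5], [.5, 1]] on independent unit noise: cov = 1.25 on the
        diagonal, 1.0 off -> correlation 0.8 (and no temporal filtering)."""
        ep = EpochSet(rng.standard_normal((50, 2, 256)), ("a", "b"), 256.0)
        out = apply_instantaneous_mixing(ep, np.array([[1.0, 0.5], [0.5, 1.0]]))
        x = out.data.transpose(1, 0, 2).reshape(2, -1)
        corr = np.corrcoef(x)[0, 1]
        assert corr == pytest.approx(0.8, abs=0.02)

    def test_singular_matrix_is_error(self, rng):
        ep = EpochSet(rng.standard_normal((3, 2, 16)), ("a", "b"), 256.0)
        with pytest.raises(ValidationError, match="singular"):
            apply_instantaneous_mixing(ep, np.ones((2, 2)))

    def test_dimension_mismatch_is_error(self, rng):
        ep = EpochSet(rng.standard_normal((3, 2, 16)), ("a", "b"), 256.0)
        with pytest.raises(ValidationError):
            apply_instantaneous_mixing(ep, np.eye(3))


class TestSimulateStudy:
    def test_too_few_subjects_is_error(self):
        with pytest.raises(ValidationError):
            simulate_study(0)
        with pytest.raises(ValidationError):
            simulate_study(1)

    def test_deterministic_in_seed(self):
        cfg = StudyConfig(base=TINY)
        a = simulate_study(3, cfg, seed=4)
        b = simulate_study(3, cfg, seed=4)
        for s in a.subjects:
            for cond in ("LE", "RE"):
                assert np.array_equal(a.epochs[s][cond].data,
                                      b.epochs[s][cond].data)
        assert a.behavior == b.behavior

    def test_behavioral_multinomial_matches_calibration(self):
        """Law of large numbers: the mean simulated right-ear report count
        approaches 240 x p_RE ~ 134.5, within +-1 of the calibrated 134.8."""
        cfg = StudyConfig(base=TINY)
        study = simulate_study(3000, cfg, seed=8)
        re_counts = np.array([b.RE for b in study.behavior])
        assert abs(re_counts.mean() - 134.8) < 1.0
        assert all(b.RE + b.LE + b.ERR == b.total for b in study.behavior)

    def test_invalid_probability_vector_rejected(self):
        cfg = StudyConfig(base=TINY, behavior_probs=(0.5, 0.4, 0.3))
        with pytest.raises(ValidationError, match="probability"):
            simulate_study(3, cfg)

    def test_default_probs_are_a_simplex(self):
        assert sum(DEFAULT_REPORT_PROBS) == pytest.approx(1.0)
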