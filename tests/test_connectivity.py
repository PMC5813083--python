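"""Coherency, lagged phase synchronization and isolated effective coherence."""

import numpy as np
import pytest
from helpers import naive_icoh, random_stable_model

from isocoh import (Coherency, EpochSet, MVARModel, SpectralConnectivity,
                    ValidationError, band_average, coherency, icoh_pair,
                    isolated_effective_coherence,
                    lagged_phase_synchronization)


def _coh_1f(f_xy):
    """2-ROI coherency object with a single frequency bin."""
    values = np.array([[[1.0 + 0j, f_xy], [np.conj(f_xy), 1.0 + 0j]]])
    return Coherency(freqs=np.array([40.0]), values=values,
                     roi_labels=("x", "y"), n_trials=10)


class TestCoherency:
    def test_identical_rois_have_unit_coherency(self, rng):
        x = rng.standard_normal((20, 1, 64))
        ep = EpochSet(np.concatenate([x, x], axis=1), ("x", "x2"), 256.0)
        coh = coherency(ep)
        assert np.allclose(np.abs(coh.values[:, 0, 1]), 1.0)

    def test_independent_noise_stays_below_null_bound(self, white_epochs):
        """|coherency| of independent ROIs stays near the analytic null
        bound sqrt(-ln(0.05)/n_trials) for unit phasor averages."""
        coh = coherency(white_epochs)
        bound = np.sqrt(-np.log(0.05) / white_epochs.n_trials)
        offdiag = np.abs(coh.values[1:-1, 0, 1])  # skip DC/Nyquist
        # each frequency exceeds the 95% bound with prob ~5%
        assert (offdiag > bound).mean() < 0.15
        assert offdiag.mean() < bound

    def test_pure_delay_keeps_unit_modulus_with_phase(self, rng):
        x = rng.standard_normal((12, 1, 64))
        y = np.roll(x, 2, axis=2)
        ep = EpochSet(np.concatenate([x, y], axis=1), ("x", "y"), 256.0)
        coh = coherency(ep)
        inner = slice(1, 31)  # interior frequencies
        vals = coh.values[inner, 0, 1]
        assert np.allclose(np.abs(vals), 1.0, atol=1e-10)
        assert np.abs(np.angle(vals)).min() > 1e-6

    def test_single_trial_is_error(self, rng):
        ep = EpochSet(rng.standard_normal((1, 2, 32)), ("a", "b"), 256.0)
        with pytest.raises(ValidationError, match="2 trials"):
            coherency(ep)

    def test_hermitian_with_unit_diagonal(self, white_epochs):
        coh = coherency(white_epochs)
        assert np.allclose(coh.values,
                           np.conj(coh.values.transpose(0, 2, 1)))
        assert np.allclose(coh.values[:, 0, 0], 1.0)
        assert np.all(np.abs(coh.values) <= 1 + 1e-12)


class TestLPS:
    @pytest.mark.parametrize(
        "f_xy,expected",
        [
            (0.0 + 0.0j, 0.0),        # no coupling
            (0.6j, 0.36),             # purely lagged: 0.36 / (1 - 0)
            (0.5 + 0.0j, 0.0),        # purely instantaneous
            (0.3 + 0.4j, 0.16 / (1 - 0.09)),
        ],
    )
    def test_formula_on_hand_built_coherency(self, f_xy, expected):
        lps = lagged_phase_synchronization(_coh_1f(f_xy))
        assert lps.values[0, 0, 1] == pytest.approx(expected, abs=1e-12)

    def test_perfect_instantaneous_coherence_guarded_to_zero(self):
        lps = lagged_phase_synchronization(_coh_1f(1.0 + 0.0j))
        assert lps.values[0, 0, 1] == 0.0

    def test_output_is_exactly_symmetric(self, white_epochs):
        lps = lagged_phase_synchronization(coherency(white_epochs))
        assert np.array_equal(lps.values, lps.values.transpose(0, 2, 1))
        assert lps.kind == "lps"


class TestICoh:
    def test_closed_form_unidirectional_model(self):
        """c = 1 coupling, unit noise, no self-lags: kappa = c^2/(c^2+1) = 0.5
        at every frequency; the reverse direction is exactly 0."""
        model = MVARModel(np.array([[[0.0, 0.0], [1.0, 0.0]]]), np.eye(2),
                          256.0, ("x", "y"))
        freqs = np.arange(0.0, 129.0)
        icoh = isolated_effective_coherence(model, freqs)
        assert np.allclose(icoh.pair("y", "x"), 0.5, atol=1e-14)
        assert np.allclose(icoh.pair("x", "y"), 0.0, atol=1e-14)
        assert np.isnan(icoh.values[:, 0, 0]).all()

    def test_diagonal_model_has_zero_cross_icoh(self):
        coeffs = np.zeros((2, 3, 3))
        coeffs[0] = np.diag([0.5, -0.3, 0.8])
        coeffs[1] = np.diag([-0.2, 0.1, -0.5])
        model = MVARModel(coeffs, np.diag([1.0, 2.0, 0.5]), 256.0,
                          ("a", "b", "c"))
        icoh = isolated_effective_coherence(model, np.arange(30.0, 101.0))
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(icoh.values[:, off], 0.0)

    def test_matches_independent_naive_oracle(self, rng):
        """Vectorized iCoh equals the explicit-loop oracle to 1e-10 on
        random stable 3-ROI models."""
        freqs = np.array([0.0, 10.0, 40.0, 77.5, 100.0])
        for _ in range(50):
            coeffs, noise = random_stable_model(rng)
            model = MVARModel(coeffs, noise, 256.0, ("a", "b", "c"))
            icoh = isolated_effective_coherence(model, freqs)
            for i in range(3):
                for j in range(3):
                    if i == j:
                        continue
                    expected = naive_icoh(coeffs, noise, 256.0, freqs, i, j)
                    assert np.max(np.abs(icoh.values[:, i, j] - expected)) < 1e-10

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(200):
            coeffs, noise = random_stable_model(rng, n_roi=2, order=3)
            model = MVARModel(coeffs, noise, 256.0, ("a", "b"))
            icoh = isolated_effective_coherence(model, np.linspace(0, 128, 9))
            off = icoh.values[:, ~np.eye(2, dtype=bool)]
            assert np.all((off >= 0) & (off <= 1))

    def test_zero_noise_variance_rejected(self):
        with pytest.raises(ValidationError):
            MVARModel(np.zeros((1, 2, 2)), np.diag([1.0, 0.0]), 256.0,
                      ("a", "b"))

    def test_same_roi_pair_rejected(self):
        model = MVARModel(np.zeros((1, 2, 2)), np.eye(2), 256.0, ("a", "b"))
        with pytest.raises(ValidationError):
            icoh_pair(model, "a", "a", [40.0])


class TestBandAverage:
    def _conn(self, freqs, vals):
        values = np.array(vals, dtype=float).reshape(-1, 1, 1) * np.ones((1, 2, 2))
        return SpectralConnectivity(freqs=np.array(freqs, dtype=float),
                                    kind="lps", values=values,
                                    roi_labels=("a", "b"))

    def test_constant_spectrum(self):
        conn = self._conn([30.0, 65.0, 100.0], [0.5, 0.5, 0.5])
        assert band_average(conn, 30, 100)[0, 1] == 0.5

    def test_arithmetic_mean_with_inclusive_edges(self):
        conn = self._conn([20.0, 30.0, 65.0, 100.0, 110.0],
                          [0.9, 0.2, 0.4, 0.6, 0.9])
        assert band_average(conn, 30, 100)[0, 1] == pytest.approx(0.4)

    def test_empty_intersection_is_error(self):
        conn = self._conn([10.0, 20.0], [0.1, 0.2])
        with pytest.raises(ValidationError, match="intersect"):
            band_average(conn, 30, 100)

    def test_closed_form_model_band_average(self):
        model = MVARModel(np.array([[[0.0, 0.0], [1.0, 0.0]]]), np.eye(2),
                          256.0, ("x", "y"))
        icoh = isolated_effective_coherence(model, np.arange(30.0, 101.0))
        assert band_average(icoh, 30, 100)[1, 0] == pytest.approx(0.5)
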