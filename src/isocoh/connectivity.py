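"""Connectivity statistics: lagged phase synchronization and isolated
effective coherence.

Two complementary measures of coupling between ROI signals in the
frequency domain:

* **Lagged phase synchronization (LPS)** — undirected functional
  connectivity.  From the complex coherency :math:`f_{x,y}(\\omega)`
  (trial-averaged outer products of unit-modulus-normalized Fourier
  coefficients),

  .. math:: \\varphi^2_{x \\rightleftarrows y}(\\omega)
            = \\frac{\\mathrm{Im}[f_{x,y}(\\omega)]^2}
                    {1 - \\mathrm{Re}[f_{x,y}(\\omega)]^2},

  which discards the instantaneous (zero-lag) part of the coherency —
  the component that volume conduction / linear mixing inflates — and
  keeps only the lagged, physiologically interpretable part.

* **Isolated effective coherence (iCoh)** — directed (Granger-sense)
  effective connectivity computed on an MVAR model in which every
  connection other than the one of interest is set to zero.  For source
  ROI ``j`` and target ``i``,

  .. math:: \\kappa_{i \\leftarrow j}(\\omega) =
            \\frac{[S_\\varepsilon]^{-1}_{ii}\\,|\\bar A(\\omega)_{ij}|^2}
                 {[S_\\varepsilon]^{-1}_{ii}\\,|\\bar A(\\omega)_{ij}|^2
                  + [S_\\varepsilon]^{-1}_{jj}\\,|\\bar A(\\omega)_{jj}|^2}
            \\in [0, 1],

  evaluated on the *isolated* model: all cross-ROI lag coefficients
  except the ``j -> i`` entries are zeroed, self-connections (diagonal
  lag coefficients) of every ROI are retained, and the innovation
  covariance is reduced to its diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet
from .errors import DegenerateModelError, ValidationError
from .mvar import MVARModel

__all__ = [
    "Coherency",
    "SpectralConnectivity",
    "coherency",
    "lagged_phase_synchronization",
    "isolated_effective_coherence",
    "icoh_pair",
    "band_average",
]

logger = logging.getLogger(__name__)

#: Denominator floor for Eq.-style ratios; values below it yield 0 with a warning.
DENOM_FLOOR = 1e-12

#: Running counts of numerical-guard activations, reported by the pipeline log.
guard_counters = {"lps_denominator": 0, "icoh_denominator": 0}


def reset_guard_counters() -> None:
    for key in guard_counters:
        guard_counters[key] = 0


@dataclass(frozen=True)
class Coherency:
    """Complex coherency per frequency, Hermitian with unit diagonal."""

    freqs: np.ndarray
    values: np.ndarray  # (n_freq, n_roi, n_roi) complex
    roi_labels: tuple[str, ...]
    n_trials: int = 0


@dataclass(frozen=True)
class SpectralConnectivity:
    """Real connectivity values per frequency and ROI pair.

    ``kind='lps'``: symmetric matrices of :math:`\\varphi^2` values.
    ``kind='icoh'``: entry ``[i, j]`` is :math:`\\kappa_{i \\leftarrow j}`
    (target row, source column); the diagonal is NaN (undefined).
    """

    freqs: np.ndarray
    kind: str
    values: np.ndarray  # (n_freq, n_roi, n_roi) real
    roi_labels: tuple[str, ...]

    def __post_init__(self):
        if self.kind not in ("lps", "icoh"):
            raise ValidationError(f"kind must be 'lps' or 'icoh', got {self.kind!r}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValidationError(
                f"connectivity values outside [0, 1]: "
                f"[{finite.min()}, {finite.max()}]"
            )

    def band_average(self, lo: float, hi: float) -> np.ndarray:
        return band_average(self, lo, hi)

    def pair(self, target: str, source: str) -> np.ndarray:
        """Spectrum for one (target, source) entry."""
        i = self.roi_labels.index(target)
        j = self.roi_labels.index(source)
        return self.values[:, i, j]


def coherency(epochs: EpochSet, window: str | None = None) -> Coherency:
    """Trial-averaged coherency from unit-modulus Fourier coefficients.

    Per trial, each ROI's epoch is Fourier transformed (single taper;
    ``window='hann'`` applies a Hann taper first); every complex
    coefficient is normalized to unit modulus; outer products are averaged
    across trials and normalized to coherency form.  The frequency grid is
    the native DFT grid of the epoch length.

    Requires at least 2 trials — a single normalized sample has modulus 1
    at every frequency and carries no phase-consistency information.
    """
    if epochs.n_trials < 2:
        raise ValidationError(
            f"coherency needs >= 2 trials, got {epochs.n_trials}"
        )
    data = epochs.data
    if window == "hann":
        data = data * np.hanning(epochs.n_samples)
    elif window is not None:
        raise ValidationError(f"unknown window {window!r}")

    freqs = np.fft.rfftfreq(epochs.n_samples, d=1.0 / epochs.fs)
    z = np.fft.rfft(data, axis=2)  # (trial, roi, freq)
    mag = np.abs(z)
    # Coefficients with (numerically) zero modulus have no phase; drop them.
    z_unit = np.where(mag > DENOM_FLOOR, z / np.where(mag > 0, mag, 1.0), 0.0)
    z_unit = z_unit.transpose(0, 2, 1)  # (trial, freq, roi)
    cross = np.einsum("tfi,tfj->fij", z_unit, np.conj(z_unit)) / epochs.n_trials
    # Normalize to coherency form; with unit-modulus inputs the diagonal is
    # already 1 except where coefficients were dropped.
    diag = np.real(np.einsum("fii->fi", cross))
    scale = np.sqrt(np.einsum("fi,fj->fij", diag, diag))
    values = np.where(scale > DENOM_FLOOR, cross / np.where(scale > 0, scale, 1.0), 0.0)
    idx = np.arange(epochs.n_roi)
    values[:, idx, idx] = 1.0
    return Coherency(freqs=freqs, values=values, roi_labels=epochs.roi_labels,
                     n_trials=epochs.n_trials)


def lagged_phase_synchronization(coh: Coherency) -> SpectralConnectivity:
    """LPS :math:`\\varphi^2 = \\mathrm{Im}[f]^2 / (1 - \\mathrm{Re}[f]^2)`.

    Entries with :math:`\\mathrm{Re}[f]^2 \\ge 1 -` ``DENOM_FLOOR``
    (perfect instantaneous coherence, including the diagonal) are set to 0
    with a logged warning rather than raising.
    """
    re = np.real(coh.values)
    im = np.imag(coh.values)
    denom = 1.0 - re**2
    bad = denom < DENOM_FLOOR
    n_off_diag_bad = int(bad.sum()) - bad.shape[0] * bad.shape[1]  # diagonal always trips
    if n_off_diag_bad > 0:
        guard_counters["lps_denominator"] += n_off_diag_bad
        logger.warning(
            "LPS denominator guard: %d off-diagonal entries at perfect "
            "instantaneous coherence set to 0", n_off_diag_bad,
        )
    phi2 = np.where(bad, 0.0, im**2 / np.where(bad, 1.0, denom))
    phi2 = np.clip(phi2, 0.0, 1.0)
    return SpectralConnectivity(freqs=coh.freqs, kind="lps", values=phi2,
                                roi_labels=coh.roi_labels)


def _icoh_kernel(coeffs: np.ndarray, noise_diag: np.ndarray, fs: float,
                 freqs: np.ndarray, i: int, j: int) -> np.ndarray:
    """kappa_{i<-j}(f) on the isolated model, vectorized over frequency.

    On the isolated model only the (i, j) cross entry and the diagonals of
    the lag matrices survive, so the two transfer entries needed are
    ``abar_ij = -sum_k A_k[i,j] e^{-i w k}`` and
    ``abar_jj = 1 - sum_k A_k[j,j] e^{-i w k}``.
    """
    lags = np.arange(1, coeffs.shape[0] + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) / fs)  # (f, k)
    abar_ij = -(phase @ coeffs[:, i, j])
    abar_jj = 1.0 - phase @ coeffs[:, j, j]
    num = np.abs(abar_ij) ** 2 / noise_diag[i]
    den = num + np.abs(abar_jj) ** 2 / noise_diag[j]
    small = den < DENOM_FLOOR
    if np.any(small):
        guard_counters["icoh_denominator"] += int(small.sum())
        logger.warning("iCoh denominator guard tripped at %d frequencies",
                       int(small.sum()))
    kappa = np.where(small, 0.0, num / np.where(small, 1.0, den))
    return np.clip(kappa, 0.0, 1.0)


def _check_icoh_model(model: MVARModel) -> np.ndarray:
    noise_diag = np.diag(model.noise_cov).copy()
    if np.any(noise_diag <= 0):
        bad = model.roi_labels[int(np.argmin(noise_diag))]
        raise DegenerateModelError(
            f"zero/negative innovation variance on ROI {bad!r}; iCoh undefined"
        )
    if not model.is_stable:
        logger.warning(
            "iCoh requested on an unstable model (spectral radius %.3f); "
            "spectra are not interpretable as stationary quantities",
            model.spectral_radius,
        )
    return noise_diag


def icoh_pair(model: MVARModel, target: str, source: str, freqs) -> np.ndarray:
    """iCoh spectrum :math:`\\kappa_{\\mathrm{target} \\leftarrow \\mathrm{source}}(f)`."""
    if target == source:
        raise ValidationError("iCoh requires target != source")
    freqs = np.atleast_1d(np.asarray(freqs, dtype=np.float64))
    model.spectral_transfer(freqs[:1])  # reuse Nyquist-range validation
    noise_diag = _check_icoh_model(model)
    i = model.roi_labels.index(target)
    j = model.roi_labels.index(source)
    return _icoh_kernel(model.coeffs, noise_diag, model.fs, freqs, i, j)


def isolated_effective_coherence(model: MVARModel, freqs) -> SpectralConnectivity:
    """iCoh for every ordered ROI pair; ``values[:, i, j]`` is
    :math:`\\kappa_{i \\leftarrow j}`, diagonal NaN."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=np.float64))
    model.spectral_transfer(freqs[:1])
    noise_diag = _check_icoh_model(model)
    n = model.n_roi
    values = np.full((freqs.size, n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i != j:
                values[:, i, j] = _icoh_kernel(
                    model.coeffs, noise_diag, model.fs, freqs, i, j
                )
    return SpectralConnectivity(freqs=freqs, kind="icoh", values=values,
                                roi_labels=model.roi_labels)


def band_average(conn: SpectralConnectivity, lo: float, hi: float) -> np.ndarray:
    """Arithmetic mean over grid frequencies ``lo <= f <= hi`` (inclusive).

    Returns an ``(n_roi, n_roi)`` matrix; NaN entries (the iCoh diagonal)
    stay NaN.
    """
    if hi < lo:
        raise ValidationError(f"empty band [{lo}, {hi}]")
    mask = (conn.freqs >= lo) & (conn.freqs <= hi)
    if not mask.any():
        raise ValidationError(
            f"band [{lo}, {hi}] Hz does not intersect the frequency grid "
            f"[{conn.freqs.min()}, {conn.freqs.max()}] Hz"
        )
    return conn.values[mask].mean(axis=0)
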