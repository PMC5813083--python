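"""Multivariate autoregressive (MVAR) modelling of epoched ROI signals.

An order-:math:`p` MVAR model writes each sample as a lagged linear
combination of all ROIs plus innovation noise,

.. math:: y_t = \\sum_{k=1}^{p} A_k\\, y_{t-k} + \\varepsilon_t,
          \\qquad \\varepsilon_t \\sim \\mathcal{N}(0, S_\\varepsilon).

Following statsmodels conventions, :class:`MVAR` is the model bound to the
data and :meth:`MVAR.fit` returns an :class:`MVARResults` carrying the
estimates and diagnostics.  The plain parameter container
:class:`MVARModel` is shared with the simulator, where the coefficients
are ground truth rather than estimates.

Estimation is ordinary least squares on lagged design rows stacked across
trials; lag windows never straddle a trial boundary, so samples from one
trial never predict another ("high order-concatenation" across
stimulus-locked trials).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .epochs import EpochSet
from .errors import SingularFitError, ValidationError

__all__ = ["MVAR", "MVARModel", "MVARResults", "SpectralTransfer", "fit_mvar"]

#: Minimum recommended regression rows per free parameter column.
_ROWS_PER_PARAM = 10


@dataclass(frozen=True)
class SpectralTransfer:
    """Frequency-domain AR polynomial :math:`\\bar A(f)`.

    ``abar[k]`` holds :math:`I - \\sum_{m=1}^{p} A_m e^{-i 2\\pi f_k m / f_s}`
    evaluated at ``freqs[k]``; the identity matrix when all lag
    coefficients are zero.
    """

    freqs: np.ndarray
    abar: np.ndarray  # (n_freq, n_roi, n_roi) complex
    roi_labels: tuple[str, ...]


@dataclass(frozen=True)
class MVARModel:
    """MVAR parameters: lag matrices, innovation covariance, sampling rate.

    ``coeffs`` has shape ``(order, n_roi, n_roi)``; ``coeffs[k-1][i, j]``
    is the influence of ROI ``j`` at lag ``k`` on ROI ``i``.
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray
    fs: float
    roi_labels: tuple[str, ...]

    def __post_init__(self):
        coeffs = np.atleast_3d(np.asarray(self.coeffs, dtype=np.float64))
        noise_cov = np.asarray(self.noise_cov, dtype=np.float64)
        object.__setattr__(self, "coeffs", coeffs)
        object.__setattr__(self, "noise_cov", noise_cov)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        object.__setattr__(self, "fs", float(self.fs))
        p, n, m = coeffs.shape
        if p < 1 or n != m:
            raise ValidationError(f"coeffs must be (order, n_roi, n_roi); got {coeffs.shape}")
        if noise_cov.shape != (n, n):
            raise ValidationError(
                f"noise_cov shape {noise_cov.shape} does not match {n} ROIs"
            )
        if not np.allclose(noise_cov, noise_cov.T, atol=1e-8):
            raise ValidationError("noise_cov is not symmetric")
        if np.any(np.diag(noise_cov) <= 0):
            raise ValidationError("noise_cov diagonal must be strictly positive")
        if len(self.roi_labels) != n:
            raise ValidationError("roi_labels do not match coefficient dimension")

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_roi(self) -> int:
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        """Companion form of the lag polynomial, shape ``(n*p, n*p)``."""
        p, n = self.order, self.n_roi
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = np.concatenate(list(self.coeffs), axis=1)
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return comp

    @property
    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    @property
    def is_stable(self) -> bool:
        """True iff the companion spectral radius is < 1 (stationary model)."""
        return self.spectral_radius < 1.0

    def spectral_transfer(self, freqs) -> SpectralTransfer:
        """Evaluate :math:`\\bar A(f)` on a frequency grid (Hz, within [0, fs/2])."""
        freqs = np.atleast_1d(np.asarray(freqs, dtype=np.float64))
        nyquist = self.fs / 2.0
        if np.any(freqs < 0) or np.any(freqs > nyquist + 1e-9):
            raise ValidationError(
                f"frequencies must lie in [0, {nyquist}] Hz; got "
                f"[{freqs.min()}, {freqs.max()}]"
            )
        lags = np.arange(1, self.order + 1)
        # phase[f, k] = exp(-i 2 pi f k / fs)
        phase = np.exp(-2j * np.pi * np.outer(freqs, lags) / self.fs)
        abar = np.eye(self.n_roi) - np.einsum("fk,kij->fij", phase, self.coeffs)
        return SpectralTransfer(freqs=freqs, abar=abar, roi_labels=self.roi_labels)


class MVAR:
    """MVAR model bound to an :class:`~isocoh.epochs.EpochSet`.

    Parameters
    ----------
    epochs
        Multi-trial input data.
    demean
        Remove the per-trial, per-ROI mean before building the regression
        (default True; band-passed signals are already near zero-mean).
    """

    def __init__(self, epochs: EpochSet, demean: bool = True):
        self.epochs = epochs.demeaned() if demean else epochs
        self.demean = demean

    def fit(self, order: int = 8) -> "MVARResults":
        """Estimate lag matrices by pooled OLS across trials.

        Each trial contributes rows for samples ``order .. n_samples-1``
        only, so no design row mixes samples of different trials.  The
        innovation covariance is the dof-adjusted covariance of the pooled
        residuals.
        """
        order = int(order)
        if order < 1:
            raise ValidationError(f"order must be >= 1, got {order}")
        ep = self.epochs
        n_trials, n_roi, n_samples = ep.data.shape
        if n_samples <= order:
            raise ValidationError(
                f"epochs of {n_samples} samples cannot support order {order} "
                f"(need more than {order} samples per trial)"
            )
        rows_per_trial = n_samples - order
        n_rows = n_trials * rows_per_trial
        n_cols = n_roi * order
        if n_rows < _ROWS_PER_PARAM * n_cols:
            warnings.warn(
                f"only {n_rows} regression rows for {n_cols} design columns "
                f"(< {_ROWS_PER_PARAM}x); coefficient estimates will be noisy",
                UserWarning,
                stacklevel=2,
            )
        # Design: row t of trial r is [y_{t-1}; ...; y_{t-p}] (each n_roi wide).
        X = np.empty((n_rows, n_cols))
        Y = np.empty((n_rows, n_roi))
        for k in range(1, order + 1):
            X[:, (k - 1) * n_roi : k * n_roi] = (
                ep.data[:, :, order - k : n_samples - k]
                .transpose(0, 2, 1)
                .reshape(n_rows, n_roi)
            )
        Y[:] = ep.data[:, :, order:].transpose(0, 2, 1).reshape(n_rows, n_roi)

        beta, _, rank, sv = np.linalg.lstsq(X, Y, rcond=None)
        if rank < n_cols:
            # Name the (roi, lag) block dominating the null direction.
            _, _, vt = np.linalg.svd(X, full_matrices=True)
            null_vec = vt[-1]
            col = int(np.argmax(np.abs(null_vec)))
            lag = col // n_roi + 1
            roi = ep.roi_labels[col % n_roi]
            raise SingularFitError(
                f"rank-deficient MVAR design (rank {rank} < {n_cols}); "
                f"offending regressor: ROI {roi!r} at lag {lag}",
                roi=roi,
                lag=lag,
            )
        resid = Y - X @ beta
        dof = max(n_rows - n_cols, 1)
        noise_cov = resid.T @ resid / dof
        coeffs = np.stack(
            [beta[(k - 1) * n_roi : k * n_roi, :].T for k in range(1, order + 1)]
        )
        return MVARResults(
            coeffs=coeffs,
            noise_cov=noise_cov,
            fs=ep.fs,
            roi_labels=ep.roi_labels,
            nobs=n_rows,
            df_resid=dof,
            resid=resid,
        )


@dataclass(frozen=True)
class MVARResults(MVARModel):
    """Fitted MVAR parameters plus diagnostics."""

    nobs: int = 0
    df_resid: int = 0
    resid: np.ndarray = field(default=None, repr=False, compare=False)

    def resid_autocorr(self, max_lag: int | None = None) -> np.ndarray:
        """Pooled-residual autocorrelations, shape ``(max_lag, n_roi)``.

        Approximate: residual rows of all trials are treated as one
        sequence, adequate for whiteness diagnostics when trials are long
        relative to ``max_lag``.
        """
        if self.resid is None:
            raise ValidationError("residuals were not stored")
        max_lag = max_lag or self.order
        r = self.resid - self.resid.mean(axis=0)
        denom = (r**2).sum(axis=0)
        return np.stack(
            [(r[lag:] * r[:-lag]).sum(axis=0) / denom for lag in range(1, max_lag + 1)]
        )

    def summary(self) -> str:
        lines = [
            f"MVAR({self.order}) fit: {self.n_roi} ROIs "
            f"({', '.join(self.roi_labels)}), {self.nobs} regression rows",
            f"  spectral radius: {self.spectral_radius:.4f} "
            f"({'stable' if self.is_stable else 'UNSTABLE'})",
            f"  innovation variances: "
            + ", ".join(
                f"{l}={v:.4g}" for l, v in zip(self.roi_labels, np.diag(self.noise_cov))
            ),
        ]
        for k in range(self.order):
            amax = np.abs(self.coeffs[k]).max()
            lines.append(f"  |A_{k + 1}|_max = {amax:.4f}")
        return "\n".join(lines)


def fit_mvar(epochs: EpochSet, order: int = 8, demean: bool = True) -> MVARResults:
    """Convenience wrapper: ``MVAR(epochs, demean).fit(order)``."""
    return MVAR(epochs, demean=demean).fit(order)
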