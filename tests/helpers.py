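"""Independent oracles and tiny simulators used by the test suite.

Everything here is deliberately naive (explicit loops, direct formulas)
and shares no code with the package paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def simulate_var_trials(coeffs, noise_std, n_trials, n_samples, seed, burn=100):
    """Direct VAR simulation with per-sample loops (oracle-side generator)."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, n, _ = coeffs.shape
    rng = np.random.default_rng(seed)
    out = np.zeros((n_trials, n, n_samples))
    for tr in range(n_trials):
        x = np.zeros((n, burn + n_samples))
        eps = rng.standard_normal((n, burn + n_samples)) * np.asarray(noise_std)[:, None]
        for t in range(burn + n_samples):
            acc = eps[:, t].copy()
            for k in range(1, p + 1):
                if t - k >= 0:
                    acc += coeffs[k - 1] @ x[:, t - k]
            x[:, t] = acc
        out[tr] = x[:, burn:]
    return out


def naive_abar(coeffs, fs, freq):
    """I - sum_k A_k exp(-i 2 pi f k / fs), by explicit loops."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, n, _ = coeffs.shape
    out = np.eye(n, dtype=complex)
    for k in range(1, p + 1):
        out = out - coeffs[k - 1] * np.exp(-2j * np.pi * freq * k / fs)
    return out


def naive_icoh(coeffs, noise_cov, fs, freqs, target, source):
    """Isolated effective coherence by explicit construction of the
    isolated model and scalar loops over frequency."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, n, _ = coeffs.shape
    i, j = target, source
    iso = np.zeros_like(coeffs)
    for k in range(p):
        for a in range(n):
            iso[k, a, a] = coeffs[k, a, a]
        iso[k, i, j] = coeffs[k, i, j]
    s = np.diag(np.asarray(noise_cov, dtype=float))
    vals = []
    for f in np.atleast_1d(freqs):
        abar = naive_abar(iso, fs, f)
        num = (1.0 / s[i]) * abs(abar[i, j]) ** 2
        den = num + (1.0 / s[j]) * abs(abar[j, j]) ** 2
        vals.append(num / den if den > 0 else 0.0)
    return np.array(vals)


def random_stable_model(rng, n_roi=3, order=2, max_coeff=0.6):
    """Random stable VAR coefficients + SPD-diagonal noise (rejection/shrink)."""
    coeffs = rng.uniform(-max_coeff, max_coeff, size=(order, n_roi, n_roi))
    for _ in range(50):
        comp = np.zeros((n_roi * order, n_roi * order))
        comp[:n_roi, :] = np.concatenate(list(coeffs), axis=1)
        if order > 1:
            comp[n_roi:, : n_roi * (order - 1)] = np.eye(n_roi * (order - 1))
        radius = np.abs(np.linalg.eigvals(comp)).max()
        if radius < 0.95:
            break
        coeffs = coeffs * (0.9 / radius)
    noise = np.diag(rng.uniform(0.5, 2.0, size=n_roi))
    return coeffs, noise


def exact_wilcoxon_p(diffs):
    """Two-sided signed-rank p by full enumeration of sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append((ranks * np.array(signs)).sum())
    stats = np.array(stats)
    p = np.mean(np.abs(stats - mu) >= abs(w_obs - mu) - 1e-12)
    return p


def paired_t_f(contrast):
    """Squared paired-t (one-sample t on a contrast) and its p-value."""
    from scipy import stats as sps

    c = np.asarray(contrast, dtype=float)
    t, p = sps.ttest_1samp(c, 0.0)
    return t * t, p
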