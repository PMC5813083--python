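"""Group-level statistics: laterality index, paired Wilcoxon signed-rank
tests with effect size r, 2x2 repeated-measures ANOVA with partial
eta-squared, and Holm step-down multiple-comparison correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "laterality_index",
    "effect_size_r",
    "wilcoxon_paired",
    "WilcoxonResult",
    "rm_anova_2x2",
    "AnovaEffect",
    "AnovaTable",
    "holm_adjust",
]

logger = logging.getLogger(__name__)


def effect_size_r(z: float, n_pairs: int) -> float:
    """Wilcoxon effect size ``r = |Z| / sqrt(n_pairs)``."""
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    return abs(float(z)) / np.sqrt(n_pairs)


def laterality_index(RE: float, LE: float) -> float:
    """Behavioral laterality index ``LI = 100 * (RE - LE) / (RE + LE)``.

    RE and LE are the correct right-ear and left-ear report counts.  The
    scale runs from -100 (complete left-ear advantage) to +100 (complete
    right-ear advantage); 0 means no ear advantage.
    """
    if RE < 0 or LE < 0:
        raise ValidationError("report counts must be non-negative")
    if RE + LE == 0:
        raise ValidationError("LI undefined: RE + LE = 0")
    return 100.0 * (RE - LE) / (RE + LE)


@dataclass(frozen=True)
class WilcoxonResult:
    """Paired signed-rank test outcome.

    ``z`` is the normal-approximation statistic (signed so that positive
    means ``a > b`` on average); ``r = |z| / sqrt(n_pairs)`` is the
    standard effect-size convention with ``n_pairs`` the number of pairs
    supplied (zero differences included).
    """

    z: float
    p: float
    r: float
    n_pairs: int
    n_used: int
    median_a: float
    median_b: float


def wilcoxon_paired(values_a, values_b) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking.  The p-value uses the
    exact null distribution when at most 25 non-zero differences remain,
    and the tie-corrected normal approximation otherwise; ``z`` always
    comes from the normal approximation so the effect size ``r`` is well
    defined.  If all
    differences are zero the test is degenerate: p = 1, r = 0, with a
    warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired samples must be equal-length 1-D arrays")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("paired samples contain non-finite values")
    n_pairs = a.size
    diffs = a - b
    nz = diffs[diffs != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; degenerate Wilcoxon "
                      "test (p = 1, r = 0)", UserWarning, stacklevel=2)
        return WilcoxonResult(0.0, 1.0, 0.0, n_pairs, 0,
                              float(np.median(a)), float(np.median(b)))
    if nz.size < 5:
        raise ValidationError(
            f"only {nz.size} non-zero differences; need >= 5 for a "
            "meaningful signed-rank test"
        )
    # Signed normal-approximation statistic from the positive-rank sum,
    # with midranks for ties: Var(W+) = sum(ranks^2) / 4.
    ranks = sps.rankdata(np.abs(nz))
    w_plus = ranks[nz > 0].sum()
    z = float((w_plus - ranks.sum() / 2.0) / np.sqrt((ranks**2).sum() / 4.0))
    if nz.size <= 25:
        p = float(sps.wilcoxon(a, b, zero_method="wilcox",
                               method="exact").pvalue)
    else:
        p = float(sps.wilcoxon(a, b, zero_method="wilcox", correction=False,
                               method="approx").pvalue)
    return WilcoxonResult(z=z, p=p, r=effect_size_r(z, n_pairs),
                          n_pairs=n_pairs, n_used=int(nz.size),
                          median_a=float(np.median(a)),
                          median_b=float(np.median(b)))


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df1: int
    df2: int
    p: float
    eta2_partial: float


@dataclass(frozen=True)
class AnovaTable:
    """Effects of a 2x2 within-subject ANOVA: two mains and the interaction."""

    condition: AnovaEffect
    direction: AnovaEffect
    interaction: AnovaEffect
    n_subjects: int
    n_dropped: int = 0

    def __iter__(self):
        return iter((self.condition, self.direction, self.interaction))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"effect": e.name, "F": e.F, "df1": e.df1, "df2": e.df2,
                 "p": e.p, "eta2_partial": e.eta2_partial}
                for e in self
            ]
        )


def rm_anova_2x2(values, factor_names=("condition", "direction")) -> AnovaTable:
    """2x2 repeated-measures ANOVA on a ``(n_subjects, 2, 2)`` array.

    Axis 1 indexes the first within factor, axis 2 the second.  With two
    levels per factor sphericity holds trivially (Greenhouse-Geisser
    epsilon = 1) and every effect F equals the squared paired t of the
    corresponding subject-level contrast.  Partial eta-squared is
    recovered as ``F * df1 / (F * df1 + df2)``.

    Subjects with any missing (NaN) cell are dropped listwise (count
    logged).  A zero-variance contrast with a non-zero mean is degenerate:
    the effect is reported with ``F = inf, p = 0``.
    """
    import pingouin as pg

    y = np.asarray(values, dtype=float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise ValidationError(
            f"values must have shape (n_subjects, 2, 2), got {y.shape}"
        )
    complete = np.isfinite(y).all(axis=(1, 2))
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("rm_anova_2x2: dropping %d incomplete subjects", n_dropped)
    y = y[complete]
    n = y.shape[0]
    if n < 3:
        raise ValidationError(f"need >= 3 complete subjects, got {n}")

    # Subject-level contrasts; effect F is the squared one-sample t on each.
    contrasts = {
        factor_names[0]: y[:, 0, :].mean(axis=1) - y[:, 1, :].mean(axis=1),
        factor_names[1]: y[:, :, 0].mean(axis=1) - y[:, :, 1].mean(axis=1),
        f"{factor_names[0]} * {factor_names[1]}":
            (y[:, 0, 0] - y[:, 0, 1]) - (y[:, 1, 0] - y[:, 1, 1]),
    }
    degenerate = {
        name: (np.ptp(c) < 1e-12 * max(1.0, float(np.abs(c).max())) and
               abs(c.mean()) > 0)
        for name, c in contrasts.items()
    }

    effects = {}
    if not any(degenerate.values()):
        subj = np.repeat(np.arange(n), 4)
        f0 = np.tile([0, 0, 1, 1], n)
        f1 = np.tile([0, 1, 0, 1], n)
        df = pd.DataFrame({
            "subject": subj,
            factor_names[0]: f0,
            factor_names[1]: f1,
            "y": y.reshape(-1),
        })
        table = pg.rm_anova(data=df, dv="y", within=list(factor_names),
                            subject="subject")
        for _, row in table.iterrows():
            F = float(row["F"])
            df1, df2 = int(row["ddof1"]), int(row["ddof2"])
            effects[str(row["Source"])] = AnovaEffect(
                name=str(row["Source"]), F=F, df1=df1, df2=df2,
                p=float(row["p_unc"]),
                eta2_partial=F * df1 / (F * df1 + df2),
            )
    else:
        logger.warning("rm_anova_2x2: zero-variance contrast; reporting "
                       "degenerate effects with infinite F")
    for name, c in contrasts.items():
        if name in effects:
            continue
        if degenerate[name]:
            effects[name] = AnovaEffect(name, np.inf, 1, n - 1, 0.0, 1.0)
        else:
            sd = c.std(ddof=1)
            if sd == 0:
                t2, p = 0.0, 1.0
            else:
                t = c.mean() / (sd / np.sqrt(n))
                t2 = t * t
                p = float(sps.f.sf(t2, 1, n - 1))
            effects[name] = AnovaEffect(name, t2, 1, n - 1, p,
                                        t2 / (t2 + n - 1))
    key_int = f"{factor_names[0]} * {factor_names[1]}"
    return AnovaTable(condition=effects[factor_names[0]],
                      direction=effects[factor_names[1]],
                      interaction=effects[key_int],
                      n_subjects=n, n_dropped=n_dropped)


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]
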