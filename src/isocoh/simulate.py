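"""Synthetic ROI signals and two-condition study datasets with known
directed coupling.

The generator emulates source-level auditory gamma activity in a dichotic
listening study: four ROIs (left/right primary and secondary auditory
cortex), each a stochastically driven damped AR(2) oscillator in the
gamma band, with directed lag-1 cross couplings whose strengths may
differ between the two report conditions (left-ear vs right-ear report).
Because the generative model is itself an MVAR process, the directed
ground truth is exact and recoverable by the fitting machinery.

Behavioral report counts are drawn from a multinomial whose default
right-ear / left-ear / error proportions mirror a strongly right-ear-
advantaged group (about 56% / 33% / 11% of 240 trials).

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .epochs import DEFAULT_ROI_LABELS, EpochSet
from .errors import UnstableModelError, ValidationError
from .mvar import MVARModel

__all__ = [
    "CouplingEdge",
    "SimulationConfig",
    "StudyConfig",
    "BehavioralRecord",
    "report_percentages",
    "StudySet",
    "build_model",
    "simulate_epochs",
    "simulate_study",
    "apply_instantaneous_mixing",
    "DEFAULT_REPORT_COUNTS",
    "DEFAULT_REPORT_PROBS",
]

#: Mean correct right-ear, correct left-ear and error report counts (of 240
#: dichotic trials) of a typical right-ear-advantaged group; used as the
#: default multinomial calibration for behavioral simulation.
DEFAULT_REPORT_COUNTS = (134.81, 80.00, 25.69)
DEFAULT_REPORT_PROBS = tuple(
    c / sum(DEFAULT_REPORT_COUNTS) for c in DEFAULT_REPORT_COUNTS
)


@dataclass(frozen=True)
class CouplingEdge:
    """Directed lag-1 coupling ``source -> target``.

    ``strength`` is the baseline lag-1 coefficient; ``condition_delta``
    maps condition labels to additive strength changes (e.g. a left-ear-
    report-specific boost); ``subject_sd`` is the between-subject SD of
    the baseline strength in study simulations.
    """

    source: str
    target: str
    strength: float
    condition_delta: Mapping[str, float] = field(default_factory=dict)
    subject_sd: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Generative recipe for one (subject, condition) epoch set.

    Each ROI is a damped AR(2) oscillator with poles at modulus
    ``pole_modulus`` and center frequency ``osc_freq`` Hz; directed
    couplings enter as lag-1 cross coefficients.  The resulting model has
    order 2 and must be stable (hard failure otherwise).
    """

    roi_labels: tuple[str, ...] = DEFAULT_ROI_LABELS
    fs: float = 256.0
    epoch_len: float = 0.2
    n_trials: int = 82
    t0: float = 0.5
    osc_freq: float = 40.0
    pole_modulus: float = 0.95
    noise_var: float | tuple[float, ...] = 1.0
    coupling_edges: tuple[CouplingEdge, ...] = ()
    mixing_matrix: np.ndarray | None = None
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_len * self.fs))


def build_model(config: SimulationConfig, condition: str | None = None) -> MVARModel:
    """Assemble the generative MVAR(2) model for one condition."""
    n = len(config.roi_labels)
    if not (0 < config.osc_freq <= config.fs / 2):
        raise ValidationError(
            f"oscillator frequency {config.osc_freq} Hz outside (0, Nyquist]"
        )
    if not (0 < config.pole_modulus < 1):
        raise ValidationError("pole_modulus must lie in (0, 1)")
    theta = 2 * math.pi * config.osc_freq / config.fs
    a1 = 2 * config.pole_modulus * math.cos(theta)
    a2 = -config.pole_modulus**2
    coeffs = np.zeros((2, n, n))
    coeffs[0] = np.eye(n) * a1
    coeffs[1] = np.eye(n) * a2
    labels = list(config.roi_labels)
    for edge in config.coupling_edges:
        if edge.source not in labels or edge.target not in labels:
            raise ValidationError(
                f"coupling edge {edge.source}->{edge.target} names unknown ROI"
            )
        strength = edge.strength
        if condition is not None:
            strength += edge.condition_delta.get(condition, 0.0)
        coeffs[0, labels.index(edge.target), labels.index(edge.source)] += strength
    var = np.broadcast_to(np.asarray(config.noise_var, dtype=float), (n,))
    if np.any(var <= 0):
        raise ValidationError("noise variances must be positive")
    return MVARModel(coeffs=coeffs, noise_cov=np.diag(var), fs=config.fs,
                     roi_labels=config.roi_labels)


def simulate_epochs(
    config: SimulationConfig,
    condition: str | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EpochSet:
    """Draw independent trials from the generative model.

    Each trial starts from zeros, runs a burn-in of ``10 * order * 4``
    samples (discarded), then records ``epoch_len * fs`` samples; if a
    mixing matrix is configured it is applied sample-wise afterwards.
    Deterministic given (config, seed).
    """
    model = build_model(config, condition)
    radius = model.spectral_radius
    if radius >= 1.0:
        raise UnstableModelError(
            f"requested generative model is unstable (spectral radius "
            f"{radius:.4f} >= 1)", spectral_radius=radius,
        )
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    n = model.n_roi
    p = model.order
    n_keep = config.n_samples
    if n_keep < 1:
        raise ValidationError("epoch_len * fs must be at least one sample")
    burn = 10 * p * 4
    total = burn + n_keep
    scale = np.sqrt(np.diag(model.noise_cov))
    x = rng.standard_normal((config.n_trials, n, total)) * scale[:, None]
    for t in range(p, total):
        for k in range(1, p + 1):
            x[:, :, t] += x[:, :, t - k] @ model.coeffs[k - 1].T
    data = x[:, :, burn:]
    epochs = EpochSet(np.ascontiguousarray(data), config.roi_labels,
                      config.fs, config.t0)
    if config.mixing_matrix is not None:
        epochs = apply_instantaneous_mixing(epochs, config.mixing_matrix)
    return epochs


def apply_instantaneous_mixing(epochs: EpochSet, matrix) -> EpochSet:
    """Sample-wise linear mix of ROI signals (a volume-conduction stand-in).

    The matrix must be square, match the ROI count, and be invertible; no
    temporal filtering is applied, so the mix is purely zero-lag.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"mixing matrix must be square, got {m.shape}")
    if m.shape[0] != epochs.n_roi:
        raise ValidationError(
            f"mixing matrix dimension {m.shape[0]} != {epochs.n_roi} ROIs"
        )
    if np.linalg.matrix_rank(m) < m.shape[0]:
        raise ValidationError("mixing matrix is singular")
    mixed = np.einsum("ab,tbs->tas", m, epochs.data)
    return EpochSet(mixed, epochs.roi_labels, epochs.fs, epochs.t0)


def report_percentages(RE: float, LE: float, ERR: float,
                       total: float) -> tuple[float, float, float]:
    """Report counts as percentages of the trial total.

    Accepts fractional counts so it also applies to group means.
    """
    if total <= 0:
        raise ValidationError("total trial count must be positive")
    return tuple(100.0 * c / total for c in (RE, LE, ERR))


@dataclass(frozen=True)
class BehavioralRecord:
    """Per-subject dichotic report counts: correct right-ear (RE), correct
    left-ear (LE) and error reports, summing to the trial total."""

    subject: str
    RE: int
    LE: int
    ERR: int
    total: int = 240

    def __post_init__(self):
        for name in ("RE", "LE", "ERR", "total"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} count must be >= 0")
        if self.RE + self.LE + self.ERR != self.total:
            raise ValidationError(
                f"subject {self.subject}: RE+LE+ERR = "
                f"{self.RE + self.LE + self.ERR} != total {self.total}"
            )

    @property
    def percentages(self) -> tuple[float, float, float]:
        """(RE, LE, ERR) as percentages of the trial total."""
        return report_percentages(self.RE, self.LE, self.ERR, self.total)

    @property
    def laterality_index(self) -> float:
        from .stats import laterality_index

        return laterality_index(self.RE, self.LE)


# Default study conditions: homotopic SAC and PAC couplings in both
# directions; the right-SAC -> left-SAC edge carries a left-ear-report-
# specific boost (the callosal-relay effect the pipeline is meant to
# detect).  The boost and between-subject SD are calibrated so that the
# condition x direction interaction reaches ~80-90% power at 33 subjects
# with 82 trials of 200 ms per condition.
DEFAULT_EFFECT_DELTA = 0.008
DEFAULT_SUBJECT_SD = 0.03
DEFAULT_STUDY_EDGES = (
    CouplingEdge("rSAC", "lSAC", 0.08, {"LE": DEFAULT_EFFECT_DELTA},
                 subject_sd=DEFAULT_SUBJECT_SD),
    CouplingEdge("lSAC", "rSAC", 0.08, subject_sd=DEFAULT_SUBJECT_SD),
    CouplingEdge("rPAC", "lPAC", 0.08, subject_sd=DEFAULT_SUBJECT_SD),
    CouplingEdge("lPAC", "rPAC", 0.08, subject_sd=DEFAULT_SUBJECT_SD),
)


@dataclass(frozen=True)
class StudyConfig:
    """Template for a two-condition group study."""

    base: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(coupling_edges=DEFAULT_STUDY_EDGES)
    )
    conditions: tuple[str, ...] = ("LE", "RE")
    behavior_probs: tuple[float, float, float] = DEFAULT_REPORT_PROBS
    behavior_total: int = 240


@dataclass(frozen=True)
class StudySet:
    """In-memory study: per-subject, per-condition epochs plus behavior."""

    epochs: Mapping[str, Mapping[str, EpochSet]]  # subject -> condition -> EpochSet
    behavior: tuple[BehavioralRecord, ...]
    config: StudyConfig
    seed: int

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(self.epochs.keys())

    def to_directory(self, out_dir) -> Path:
        """Write HDF5 epochs, behavior TSV and a JSON manifest; returns the
        manifest path."""
        from .io import write_behavior, write_epochs

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        subjects = []
        for subject, by_cond in self.epochs.items():
            entry = {"id": subject, "epochs": {}}
            for cond, ep in by_cond.items():
                rel = f"{subject}_{cond}.h5"
                write_epochs(ep, out_dir / rel)
                entry["epochs"][cond] = rel
            subjects.append(entry)
        write_behavior(self.behavior, out_dir / "behavior.tsv")
        manifest = {
            "schema_version": 1,
            "seed": self.seed,
            "behavior": "behavior.tsv",
            "subjects": subjects,
        }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2))
        return path


def simulate_study(
    n_subjects: int,
    config: StudyConfig | None = None,
    seed: int = 0,
) -> StudySet:
    """Simulate a full two-condition study with between-subject variability.

    Per subject, baseline coupling strengths are perturbed by
    ``Normal(0, subject_sd)`` deviations.  One deviation is drawn per
    unordered ROI pair and applied to both directions of that pair: a
    subject's interhemispheric coupling strength is modelled as shared
    between directions, so between-subject variability moves overall
    coupling but not its directional asymmetry (condition deltas stay
    fixed).  Both conditions' epochs are then simulated from the
    resulting models, and report counts are drawn from the behavioral
    multinomial.
    """
    if n_subjects < 2:
        raise ValidationError(f"need n_subjects >= 2, got {n_subjects}")
    config = config or StudyConfig()
    probs = np.asarray(config.behavior_probs, dtype=float)
    if probs.ndim != 1 or probs.size != 3 or np.any(probs < 0) or not np.isclose(
        probs.sum(), 1.0
    ):
        raise ValidationError(
            f"behavior_probs must be a 3-way probability vector, got {probs}"
        )
    root = np.random.default_rng(seed)
    streams = root.spawn(n_subjects)
    width = len(str(n_subjects))
    epochs: dict[str, dict[str, EpochSet]] = {}
    behavior = []
    for s, rng in enumerate(streams):
        subject = f"sub{s + 1:0{width}d}"
        pair_dev: dict[frozenset, float] = {}
        edges = []
        for edge in config.base.coupling_edges:
            pair = frozenset((edge.source, edge.target))
            if pair not in pair_dev:
                pair_dev[pair] = float(rng.standard_normal())
            edges.append(
                replace(edge,
                        strength=edge.strength + edge.subject_sd * pair_dev[pair])
            )
        sub_config = replace(config.base, coupling_edges=tuple(edges))
        epochs[subject] = {
            cond: simulate_epochs(sub_config, condition=cond, rng=rng)
            for cond in config.conditions
        }
        re_n, le_n, err_n = rng.multinomial(config.behavior_total, probs)
        behavior.append(
            BehavioralRecord(subject, int(re_n), int(le_n), int(err_n),
                             config.behavior_total)
        )
    return StudySet(epochs=epochs, behavior=tuple(behavior), config=config,
                    seed=seed)
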