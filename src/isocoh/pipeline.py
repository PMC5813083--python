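"""Group analysis pipeline: per-subject windowing, connectivity
extraction, laterality, and condition x direction statistics.

The pipeline mirrors a dichotic-listening connectivity study design:

1. per subject and report condition (left-ear vs right-ear report),
   trials are balanced between conditions by seeded subsampling and a
   post-stimulus analysis window (default 500-700 ms) is extracted;
2. functional connectivity (lagged phase synchronization) is computed
   for the homotopic ROI pairs and effective connectivity (isolated
   effective coherence) for the directed pairs from an MVAR fit
   (default order 8, 1 Hz grid); both are averaged over the gamma band
   (default 30-100 Hz inclusive);
3. group inference: paired Wilcoxon tests on LPS (LE vs RE), a 2x2
   repeated-measures ANOVA (Condition x Direction) on iCoh per homotopic
   pair, four Holm-corrected post-hoc Wilcoxon contrasts, and a
   behavioral right-ear-advantage test on the laterality index.

Following the Model/Results convention, :class:`GroupStudy` binds the
data and configuration and :meth:`GroupStudy.fit` returns a
:class:`StudyResult` with a :meth:`~StudyResult.summary` table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import connectivity as conn_mod
from .connectivity import (band_average, coherency, isolated_effective_coherence,
                           lagged_phase_synchronization)
from .epochs import EpochSet
from .errors import ValidationError
from .mvar import MVAR
from .simulate import BehavioralRecord, StudySet
from .stats import (AnovaTable, WilcoxonResult, holm_adjust, laterality_index,
                    rm_anova_2x2, wilcoxon_paired)

__all__ = ["PipelineConfig", "GroupStudy", "StudyResult", "extract_window",
           "run_study"]

logger = logging.getLogger(__name__)


def extract_window(epochs: EpochSet, start: float, stop: float) -> EpochSet:
    """Select the half-open time window ``[start, stop)`` (s, stimulus-locked).

    Sample indices are ``round((t - t0) * fs)``; the window must lie on
    the epoch's time axis.
    """
    if stop <= start:
        raise ValidationError(f"empty window [{start}, {stop})")
    i0 = int(round((start - epochs.t0) * epochs.fs))
    i1 = int(round((stop - epochs.t0) * epochs.fs))
    if i0 < 0 or i1 > epochs.n_samples:
        raise ValidationError(
            f"window [{start}, {stop}) s outside epoch axis "
            f"[{epochs.t0}, {epochs.t0 + epochs.n_samples / epochs.fs}) s"
        )
    if i1 <= i0:
        raise ValidationError(f"window [{start}, {stop}) contains no samples")
    return EpochSet(epochs.data[:, :, i0:i1], epochs.roi_labels, epochs.fs,
                    epochs.t0 + i0 / epochs.fs)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline parameters.

    ``lps_pairs`` are unordered homotopic pairs for functional
    connectivity; ``anova_pairs`` maps a pair name to its (left, right)
    ROI labels — the ANOVA's Direction factor is right-to-left
    (``left <- right``) vs left-to-right; ``icoh_extra_pairs`` adds
    directed heterotopic pairs (source, target) to the subject table.
    """

    window: tuple[float, float] = (0.5, 0.7)
    band: tuple[float, float] = (30.0, 100.0)
    ar_order: int = 8
    alpha: float = 0.05
    icoh_freq_step: float = 1.0
    conditions: tuple[str, str] = ("LE", "RE")
    lps_pairs: tuple[tuple[str, str], ...] = (("lSAC", "rSAC"), ("lPAC", "rPAC"))
    anova_pairs: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: {"SAC": ("lSAC", "rSAC"), "PAC": ("lPAC", "rPAC")}
    )
    icoh_extra_pairs: tuple[tuple[str, str], ...] = (
        ("rPAC", "lSAC"), ("lSAC", "rPAC"), ("lPAC", "rSAC"), ("rSAC", "lPAC"),
    )
    balance_trials: bool = True
    demean: bool = True
    hann_window: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(cfg)
        for key in ("window", "band", "conditions"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        if "lps_pairs" in cfg:
            cfg["lps_pairs"] = tuple(tuple(p) for p in cfg["lps_pairs"])
        if "icoh_extra_pairs" in cfg:
            cfg["icoh_extra_pairs"] = tuple(tuple(p) for p in cfg["icoh_extra_pairs"])
        if "anova_pairs" in cfg:
            cfg["anova_pairs"] = {k: tuple(v) for k, v in cfg["anova_pairs"].items()}
        return cls(**cfg)

    def icoh_freqs(self) -> np.ndarray:
        lo, hi = self.band
        return np.arange(lo, hi + self.icoh_freq_step / 2, self.icoh_freq_step)


#: The four post-hoc contrasts tested per homotopic pair (one Holm family).
POSTHOC_CONTRASTS = (
    ("LE: R->L vs L->R", ("LE", "RL"), ("LE", "LR")),
    ("RE: R->L vs L->R", ("RE", "RL"), ("RE", "LR")),
    ("R->L: LE vs RE", ("LE", "RL"), ("RE", "RL")),
    ("L->R: LE vs RE", ("LE", "LR"), ("RE", "LR")),
)


@dataclass(frozen=True)
class StudyResult:
    """Fitted group-study outcome.

    ``subject_table`` holds one row per subject x condition x measure x
    directed (or unordered) ROI pair with the band-averaged value;
    the remaining fields are the group-level inferential results.
    """

    subject_table: pd.DataFrame
    laterality: pd.DataFrame
    behavior_test: WilcoxonResult | None
    lps_tests: Mapping[str, WilcoxonResult]
    anova: Mapping[str, AnovaTable]
    posthoc: Mapping[str, pd.DataFrame]
    config: PipelineConfig
    seed: int
    n_subjects: int
    excluded: tuple[tuple[str, str], ...]
    guard_counts: Mapping[str, int]

    def summary(self) -> str:
        cfg = self.config
        lo, hi = cfg.band
        lines = [
            "Dichotic-listening connectivity study",
            "=" * 54,
            f"Subjects analysed: {self.n_subjects}"
            + (f" (excluded: {[s for s, _ in self.excluded]})" if self.excluded else ""),
            f"Window {cfg.window[0] * 1000:.0f}-{cfg.window[1] * 1000:.0f} ms, "
            f"band {lo:.0f}-{hi:.0f} Hz, AR order {cfg.ar_order}",
            "",
        ]
        if len(self.laterality):
            li = self.laterality["LI"]
            lines.append(
                f"Behavioral laterality index: mean {li.mean():.2f} "
                f"+/- {li.std(ddof=1):.2f} "
                f"(positive LI: {(li > 0).sum()}/{len(li)} subjects)"
            )
            if self.behavior_test is not None:
                bt = self.behavior_test
                lines.append(
                    f"  RE vs LE reports: Z = {bt.z:.3f}, p = {bt.p:.3g}, "
                    f"r = {bt.r:.2f}"
                )
            lines.append("")
        lines.append("Functional connectivity (LPS), LE vs RE:")
        for pair, res in self.lps_tests.items():
            lines.append(
                f"  {pair}: Md(LE) = {res.median_a:.4f}, "
                f"Md(RE) = {res.median_b:.4f}; Z = {res.z:.3f}, "
                f"p = {res.p:.4g}, r = {res.r:.2f}"
            )
        lines.append("")
        lines.append("Effective connectivity (iCoh), 2x2 RM-ANOVA "
                     "(Condition x Direction):")
        for pair, table in self.anova.items():
            lines.append(f"  {pair}:")
            for eff in table:
                lines.append(
                    f"    {eff.name}: F({eff.df1},{eff.df2}) = {eff.F:.3f}, "
                    f"p = {eff.p:.4g}, eta2p = {eff.eta2_partial:.2f}"
                )
        lines.append("")
        lines.append(f"Post-hoc Wilcoxon contrasts (Holm-corrected, "
                     f"alpha = {cfg.alpha}):")
        for pair, table in self.posthoc.items():
            lines.append(f"  {pair}:")
            for _, row in table.iterrows():
                star = " *" if row["significant"] else ""
                lines.append(
                    f"    {row['contrast']}: Z = {row['z']:.3f}, "
                    f"p = {row['p_raw']:.4g}, p_holm = {row['p_holm']:.4g}, "
                    f"r = {row['r']:.2f}{star}"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def wres(w: WilcoxonResult | None):
            if w is None:
                return None
            return {"z": w.z, "p": w.p, "r": w.r, "n_pairs": w.n_pairs,
                    "median_a": w.median_a, "median_b": w.median_b}

        return {
            "n_subjects": self.n_subjects,
            "seed": self.seed,
            "excluded": [list(e) for e in self.excluded],
            "config": {
                k: (list(v) if isinstance(v, tuple) else
                    {kk: list(vv) for kk, vv in v.items()} if isinstance(v, dict)
                    else v)
                for k, v in dataclasses.asdict(self.config).items()
            },
            "laterality": {
                "per_subject": self.laterality.to_dict(orient="records"),
                "mean": float(self.laterality["LI"].mean())
                if len(self.laterality) else None,
            },
            "behavior_test": wres(self.behavior_test),
            "lps": {pair: wres(res) for pair, res in self.lps_tests.items()},
            "anova": {
                pair: table.to_frame().to_dict(orient="records")
                for pair, table in self.anova.items()
            },
            "posthoc": {
                pair: df.to_dict(orient="records")
                for pair, df in self.posthoc.items()
            },
            "numerical_guards": dict(self.guard_counts),
        }

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "study_result.json").write_text(
            json.dumps(self.to_dict(), indent=2, default=float)
        )
        self.subject_table.to_csv(out_dir / "subject_connectivity.tsv",
                                  sep="\t", index=False)
        if len(self.laterality):
            self.laterality.to_csv(out_dir / "laterality.tsv", sep="\t",
                                   index=False)


class GroupStudy:
    """Group connectivity study bound to per-subject epoch data.

    Parameters
    ----------
    epochs
        Mapping ``subject -> condition -> EpochSet``.
    behavior
        Optional behavioral records (one per subject).
    config
        Pipeline parameters; defaults reproduce the standard analysis.
    """

    def __init__(
        self,
        epochs: Mapping[str, Mapping[str, EpochSet]],
        behavior: tuple[BehavioralRecord, ...] = (),
        config: PipelineConfig | None = None,
    ):
        self.epochs = epochs
        self.behavior = tuple(behavior)
        self.config = config or PipelineConfig()

    @classmethod
    def from_studyset(cls, study: StudySet,
                      config: PipelineConfig | None = None) -> "GroupStudy":
        return cls(study.epochs, study.behavior, config)

    @classmethod
    def from_manifest(cls, manifest_path,
                      config: PipelineConfig | None = None) -> "GroupStudy":
        from .io import StudyManifest, read_behavior, read_epochs

        manifest = StudyManifest.load(manifest_path)
        epochs = {
            entry["id"]: {
                cond: read_epochs(manifest.root / rel)
                for cond, rel in entry["epochs"].items()
            }
            for entry in manifest.subjects
        }
        behavior = read_behavior(manifest.behavior) if manifest.behavior else ()
        return cls(epochs, behavior, config)

    # -- per-subject extraction ------------------------------------------
    def _subject_scalars(self, subject: str, by_cond: Mapping[str, EpochSet],
                         rng: np.random.Generator) -> list[dict]:
        cfg = self.config
        eps = {c: by_cond[c] for c in cfg.conditions}
        if cfg.balance_trials:
            n_min = min(ep.n_trials for ep in eps.values())
            for c, ep in eps.items():
                if ep.n_trials > n_min:
                    keep = np.sort(rng.choice(ep.n_trials, size=n_min,
                                              replace=False))
                    logger.info("subject %s %s: subsampled %d -> %d trials",
                                subject, c, ep.n_trials, n_min)
                    eps[c] = ep.select_trials(keep)
        rows = []
        freqs = cfg.icoh_freqs()
        for cond, ep in eps.items():
            win = extract_window(ep, *cfg.window)
            if cfg.demean:
                win = win.demeaned()
            coh = coherency(win, window="hann" if cfg.hann_window else None)
            lps = lagged_phase_synchronization(coh)
            lps_avg = band_average(lps, *cfg.band)
            for x, y in cfg.lps_pairs:
                i, j = win.roi_index(x), win.roi_index(y)
                rows.append({"subject": subject, "condition": cond,
                             "measure": "lps", "source_roi": x,
                             "target_roi": y, "value": float(lps_avg[i, j]),
                             "n_trials": win.n_trials})
            model = MVAR(win, demean=False).fit(cfg.ar_order)
            icoh = isolated_effective_coherence(model, freqs)
            icoh_avg = band_average(icoh, *cfg.band)
            directed = set()
            for _, (left, right) in cfg.anova_pairs.items():
                directed.update([(right, left), (left, right)])
            directed.update(cfg.icoh_extra_pairs)
            for source, target in sorted(directed):
                i, j = win.roi_index(target), win.roi_index(source)
                rows.append({"subject": subject, "condition": cond,
                             "measure": "icoh", "source_roi": source,
                             "target_roi": target,
                             "value": float(icoh_avg[i, j]),
                             "n_trials": win.n_trials})
        return rows

    # -- fitting ----------------------------------------------------------
    def fit(self, seed: int | None = None) -> StudyResult:
        """Run the full pipeline and return the group result."""
        cfg = self.config
        seed = cfg.seed if seed is None else int(seed)
        conn_mod.reset_guard_counters()
        cond_a, cond_b = cfg.conditions

        usable, excluded = {}, []
        for subject, by_cond in self.epochs.items():
            missing = [c for c in cfg.conditions if c not in by_cond]
            if missing:
                logger.warning("excluding subject %s: missing condition(s) %s",
                               subject, missing)
                excluded.append((subject, f"missing {','.join(missing)}"))
                continue
            usable[subject] = by_cond
        if len(usable) < 3:
            raise ValidationError(
                f"only {len(usable)} subjects with both conditions; need >= 3"
            )
        logger.info("pipeline: %d subjects, window %s s, band %s Hz, "
                    "AR order %d, seed %d", len(usable), cfg.window, cfg.band,
                    cfg.ar_order, seed)

        root = np.random.default_rng(seed)
        streams = root.spawn(len(usable))
        rows = []
        for (subject, by_cond), rng in zip(sorted(usable.items()), streams):
            rows.extend(self._subject_scalars(subject, by_cond, rng))
        table = pd.DataFrame(rows)
        subjects = sorted(usable)
        lookup = {
            (r["subject"], r["condition"], r["measure"], r["source_roi"],
             r["target_roi"]): r["value"]
            for r in rows
        }

        def value(subject, cond, measure, source, target):
            return lookup[(subject, cond, measure, source, target)]

        # LPS: paired Wilcoxon LE vs RE per unordered pair
        lps_tests = {}
        for x, y in cfg.lps_pairs:
            a = np.array([value(s, cond_a, "lps", x, y) for s in subjects])
            b = np.array([value(s, cond_b, "lps", x, y) for s in subjects])
            lps_tests[f"{x}-{y}"] = wilcoxon_paired(a, b)

        # iCoh: 2x2 RM-ANOVA and post-hoc contrasts per homotopic pair.
        # Direction RL = left <- right (right-to-left flow), LR = right <- left.
        anova, posthoc = {}, {}
        for pair_name, (left, right) in cfg.anova_pairs.items():
            cell = {}
            for cond in cfg.conditions:
                cell[(cond, "RL")] = np.array(
                    [value(s, cond, "icoh", right, left) for s in subjects])
                cell[(cond, "LR")] = np.array(
                    [value(s, cond, "icoh", left, right) for s in subjects])
            y = np.stack(
                [np.stack([cell[(cond, d)] for d in ("RL", "LR")], axis=1)
                 for cond in cfg.conditions], axis=1)
            anova[pair_name] = rm_anova_2x2(y)
            results = [
                (name, wilcoxon_paired(cell[key_a], cell[key_b]))
                for name, key_a, key_b in POSTHOC_CONTRASTS
            ]
            adj = holm_adjust([w.p for _, w in results])
            posthoc[pair_name] = pd.DataFrame([
                {"contrast": name, "z": w.z, "p_raw": w.p,
                 "p_holm": float(ph), "r": w.r,
                 "significant": bool(ph < cfg.alpha)}
                for (name, w), ph in zip(results, adj)
            ])

        # Behavior: per-subject LI and RE-vs-LE signed-rank test
        beh = [b for b in self.behavior if b.subject in subjects]
        laterality = pd.DataFrame([
            {"subject": b.subject, "RE": b.RE, "LE": b.LE,
             "LI": laterality_index(b.RE, b.LE)}
            for b in beh
        ])
        behavior_test = None
        if len(beh) >= 5:
            behavior_test = wilcoxon_paired(
                np.array([b.RE for b in beh], dtype=float),
                np.array([b.LE for b in beh], dtype=float),
            )

        guard_counts = dict(conn_mod.guard_counters)
        if any(guard_counts.values()):
            logger.warning("numerical guards tripped: %s", guard_counts)
        return StudyResult(
            subject_table=table, laterality=laterality,
            behavior_test=behavior_test, lps_tests=lps_tests, anova=anova,
            posthoc=posthoc, config=cfg, seed=seed, n_subjects=len(subjects),
            excluded=tuple(excluded), guard_counts=guard_counts,
        )


def run_study(study, config: PipelineConfig | None = None,
              seed: int | None = None) -> StudyResult:
    """One-call pipeline over a :class:`~isocoh.simulate.StudySet`, a
    manifest path, or a ``subject -> condition -> EpochSet`` mapping."""
    if isinstance(study, StudySet):
        model = GroupStudy.from_studyset(study, config)
    elif isinstance(study, (str, Path)):
        model = GroupStudy.from_manifest(study, config)
    else:
        model = GroupStudy(study, config=config)
    return model.fit(seed)
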