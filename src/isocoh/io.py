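"""Readers and writers: HDF5 epoch containers, behavior TSV, study
manifests, run configuration, and connectivity serialization.

Formats are deliberately language-neutral: HDF5 for arrays (datasets
``/data`` ``(trial, roi, sample)`` float64 and ``/roi_labels``, file
attributes ``fs`` and ``t0``), tab-separated UTF-8 text with ``.``
decimals for tables, JSON for nested results and manifests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .connectivity import SpectralConnectivity
from .epochs import EpochSet
from .errors import SchemaError, ValidationError
from .simulate import BehavioralRecord

__all__ = [
    "read_epochs",
    "write_epochs",
    "read_behavior",
    "write_behavior",
    "StudyManifest",
    "load_config",
    "save_connectivity",
    "connectivity_table",
    "plot_connectivity_spectrum",
]


def write_epochs(epochs: EpochSet, path) -> None:
    """Write an :class:`EpochSet`; float64 round-trips bit-exactly."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, dtype=np.float64)
        f.create_dataset(
            "roi_labels",
            data=np.array(epochs.roi_labels, dtype=h5py.string_dtype("utf-8")),
        )
        f.attrs["fs"] = epochs.fs
        f.attrs["t0"] = epochs.t0


def read_epochs(path) -> EpochSet:
    """Read and validate an epoch container written by :func:`write_epochs`."""
    with h5py.File(path, "r") as f:
        for name in ("data", "roi_labels"):
            if name not in f:
                raise SchemaError(f"{path}: missing dataset '/{name}'")
        for attr in ("fs", "t0"):
            if attr not in f.attrs:
                raise SchemaError(f"{path}: missing file attribute {attr!r}")
        data = f["data"][()]
        labels = tuple(
            s.decode("utf-8") if isinstance(s, bytes) else str(s)
            for s in f["roi_labels"][()]
        )
        fs = float(f.attrs["fs"])
        t0 = float(f.attrs["t0"])
    return EpochSet(data, labels, fs, t0)


_BEHAVIOR_COLUMNS = ["subject", "RE", "LE", "ERR", "total"]


def write_behavior(records, path) -> None:
    pd.DataFrame(
        [
            {"subject": r.subject, "RE": r.RE, "LE": r.LE, "ERR": r.ERR,
             "total": r.total}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_behavior(path) -> tuple[BehavioralRecord, ...]:
    """Read a behavior TSV; every row must satisfy RE + LE + ERR = total."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty behavior file") from None
    missing = [c for c in _BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing behavior columns {missing}")
    if len(df) == 0:
        raise ValidationError(f"{path}: behavior file has no rows")
    records = []
    for _, row in df.iterrows():
        try:
            records.append(
                BehavioralRecord(str(row["subject"]), int(row["RE"]),
                                 int(row["LE"]), int(row["ERR"]),
                                 int(row["total"]))
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from None
    return tuple(records)


@dataclass(frozen=True)
class StudyManifest:
    """Index of a study directory: per-subject epoch files and behavior."""

    subjects: tuple[dict, ...]  # {"id": str, "epochs": {condition: path}}
    behavior: Path | None
    root: Path
    schema_version: int = 1
    seed: int | None = None

    @classmethod
    def load(cls, path) -> "StudyManifest":
        path = Path(path)
        try:
            raw = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from None
        if "subjects" not in raw:
            raise SchemaError(f"{path}: missing 'subjects' list")
        root = path.parent
        ids = [s.get("id") for s in raw["subjects"]]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"{path}: duplicate subject ids")
        for entry in raw["subjects"]:
            if "id" not in entry or "epochs" not in entry:
                raise SchemaError(f"{path}: subject entry missing id/epochs")
            for cond, rel in entry["epochs"].items():
                if not (root / rel).exists():
                    raise ValidationError(
                        f"{path}: epochs file {rel!r} for subject "
                        f"{entry['id']} ({cond}) does not exist"
                    )
        behavior = raw.get("behavior")
        if behavior is not None:
            behavior = root / behavior
            if not behavior.exists():
                raise ValidationError(f"{path}: behavior file {behavior} missing")
        return cls(subjects=tuple(raw["subjects"]), behavior=behavior,
                   root=root, schema_version=int(raw.get("schema_version", 1)),
                   seed=raw.get("seed"))

    def epochs_path(self, subject_id: str, condition: str) -> Path:
        for entry in self.subjects:
            if entry["id"] == subject_id:
                return self.root / entry["epochs"][condition]
        raise ValidationError(f"unknown subject {subject_id!r}")


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    return cfg


def save_connectivity(conn: SpectralConnectivity, base_path) -> tuple[Path, Path]:
    """Serialize a spectrum as JSON metadata + HDF5 values.

    Returns (json_path, h5_path).
    """
    base = Path(base_path)
    h5_path = base.with_suffix(".h5")
    json_path = base.with_suffix(".json")
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("values", data=conn.values)
        f.create_dataset("freqs", data=conn.freqs)
    json_path.write_text(json.dumps({
        "kind": conn.kind,
        "roi_labels": list(conn.roi_labels),
        "freqs_hz": [float(f) for f in conn.freqs],
        "values_file": h5_path.name,
    }, indent=2))
    return json_path, h5_path


def plot_connectivity_spectrum(conn: SpectralConnectivity, target: str,
                               source: str, ax=None):
    """Per-frequency line plot of one connectivity spectrum entry.

    For LPS the (target, source) order is immaterial; for iCoh the curve
    is kappa_{target <- source}.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    label = (f"{source} ↔ {target}" if conn.kind == "lps"
             else f"{target} ← {source}")
    ax.plot(conn.freqs, conn.pair(target, source), label=label)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel(r"$\varphi^2$" if conn.kind == "lps" else r"$\kappa$")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    return ax


def connectivity_table(conn: SpectralConnectivity, lo: float, hi: float,
                       subject: str = "", condition: str = "") -> pd.DataFrame:
    """Band-averaged scalars as a long table (one row per ordered pair).

    For LPS only the upper triangle is emitted (the measure is symmetric).
    """
    from .connectivity import band_average

    avg = band_average(conn, lo, hi)
    rows = []
    n = len(conn.roi_labels)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if conn.kind == "lps" and i > j:
                continue
            rows.append({
                "subject": subject,
                "condition": condition,
                "source_roi": conn.roi_labels[j],
                "target_roi": conn.roi_labels[i],
                "measure": conn.kind,
                "value": float(avg[i, j]),
            })
    return pd.DataFrame(rows)
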