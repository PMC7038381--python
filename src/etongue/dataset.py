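"""Core data containers: one sample's electrode-response matrix and labeled
collections of samples, with lossless on-disk bundles.

A voltammetric e-tongue sample is an ``m x d`` matrix: ``m`` working
electrodes, each sampled at ``d`` time points during one excitation cycle.
Row order (the electrode order) is part of a dataset's identity and must be
identical across samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import DatasetError

__all__ = ["SensorResponseMatrix", "LabeledDataset"]

_SCHEMA_VERSION = 1


@dataclass
class SensorResponseMatrix:
    """Raw responses of one sample: ``m`` electrodes by ``d`` time points.

    Parameters
    ----------
    values : (m, d) array
        Electrode currents (arbitrary instrument units); finite, no gaps.
    electrode_ids : list of str, optional
        Ordered electrode identifiers; defaults to ``E1..Em``.
    label : hashable, optional
        Class identifier (e.g. the beverage name).
    sample_id : str
        Free-form sample identifier.
    concentration : float, optional
        Dilution fraction of the original solution in (0, 1].
    replicate : int, optional
        Repeat-measurement index.
    """

    values: np.ndarray
    electrode_ids: list[str] | None = None
    label: object | None = None
    sample_id: str = ""
    concentration: float | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DatasetError(f"values must be 2-D, got ndim={self.values.ndim}")
        m, d = self.values.shape
        if m < 2:
            raise DatasetError(f"need at least 2 electrodes, got m={m}")
        if d < 1:
            raise DatasetError("need at least one time point")
        if not np.all(np.isfinite(self.values)):
            raise DatasetError("values contain non-finite entries")
        if self.electrode_ids is None:
            self.electrode_ids = [f"E{i + 1}" for i in range(m)]
        if len(self.electrode_ids) != m:
            raise DatasetError(
                f"electrode_ids has {len(self.electrode_ids)} entries for m={m}"
            )

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Time series as a DataFrame indexed by electrode id."""
        return pd.DataFrame(self.values, index=self.electrode_ids)


@dataclass
class LabeledDataset:
    """An ordered collection of samples sharing electrode layout and length.

    ``provenance`` records whatever is needed to regenerate the dataset
    (generator spec and seed for simulated data, acquisition notes for
    real data).
    """

    samples: list[SensorResponseMatrix]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.samples:
            first = self.samples[0]
            for s in self.samples:
                if s.values.shape != first.values.shape:
                    raise DatasetError(
                        "heterogeneous sample shapes: "
                        f"{s.values.shape} vs {first.values.shape}"
                    )
                if s.electrode_ids != first.electrode_ids:
                    raise DatasetError("electrode order differs between samples")

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, i: int) -> SensorResponseMatrix:
        return self.samples[i]

    def __iter__(self):
        return iter(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([s.label for s in self.samples], dtype=object)

    @property
    def concentrations(self) -> np.ndarray:
        return np.asarray([s.concentration for s in self.samples], dtype=object)

    @property
    def classes(self) -> list:
        return sorted(set(self.labels.tolist()))

    # ---------------------------------------------------------------- I/O

    def to_bundle(self, path: str | Path, fmt: str = "csv") -> Path:
        """Write the dataset as a directory bundle.

        ``fmt="csv"``: one full-precision delimited matrix per sample plus a
        YAML manifest (labels, concentrations, replicate ids, provenance).
        ``fmt="npz"``: a single compressed binary array stack next to the
        manifest — the lossless fidelity format.
        """
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "schema_version": _SCHEMA_VERSION,
            "format": fmt,
            "n_samples": len(self),
            "electrode_ids": self.samples[0].electrode_ids if self.samples else [],
            "samples": [
                {
                    "sample_id": s.sample_id,
                    "label": None if s.label is None else str(s.label),
                    "concentration": s.concentration,
                    "replicate": s.replicate,
                    "file": f"samples/sample_{i:04d}.csv" if fmt == "csv" else None,
                }
                for i, s in enumerate(self.samples)
            ],
            "provenance": json.loads(json.dumps(self.provenance, default=str)),
        }
        with open(path / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        if fmt == "csv":
            (path / "samples").mkdir(exist_ok=True)
            for i, s in enumerate(self.samples):
                # %.17e round-trips float64 exactly through text
                np.savetxt(
                    path / "samples" / f"sample_{i:04d}.csv",
                    s.values,
                    fmt="%.17e",
                    delimiter=",",
                )
        elif fmt == "npz":
            np.savez_compressed(
                path / "samples.npz",
                values=np.stack([s.values for s in self.samples])
                if self.samples
                else np.zeros((0, 0, 0)),
            )
        else:
            raise DatasetError(f"unknown bundle format {fmt!r}")
        return path

    @classmethod
    def from_bundle(cls, path: str | Path) -> "LabeledDataset":
        path = Path(path)
        with open(path / "manifest.yaml") as fh:
            manifest = yaml.safe_load(fh)
        fmt = manifest.get("format", "csv")
        if fmt == "npz":
            stack = np.load(path / "samples.npz")["values"]
        samples = []
        for i, rec in enumerate(manifest["samples"]):
            if fmt == "csv":
                values = np.loadtxt(path / rec["file"], delimiter=",", ndmin=2)
            else:
                values = stack[i]
            samples.append(
                SensorResponseMatrix(
                    values=values,
                    electrode_ids=list(manifest["electrode_ids"]),
                    label=rec["label"],
                    sample_id=rec["sample_id"],
                    concentration=rec["concentration"],
                    replicate=rec["replicate"],
                )
            )
        return cls(samples=samples, provenance=manifest.get("provenance", {}))
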