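"""Dataset container, HDF5 round-trip, and run configuration.

The on-disk layout (HDF5) is::

    /ersp          float array, trial x ic x freq x time (dB)
    /labels        string array, per-trial type
    /spatial_maps  float array, ic x electrode
    /region_labels string array, per electrode (pTC/aTC/aPFC/other)
    /freqs, /times grid coordinate vectors
    attrs: metadata (JSON string), incl. ground truth and the seed registry

The flattening order of the time-frequency dimension used by the tensor
stages is frequency-major and is recorded in the metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np

from .grids import TFGrid
from .paradigm import TRIAL_TYPES

__all__ = ["Dataset", "RunConfig", "read_dataset", "write_dataset"]

REGIONS = ("pTC", "aTC", "aPFC", "other")


@dataclass
class Dataset:
    """Trial-resolved ERSP data for one subject (real or synthetic)."""

    ersp: np.ndarray            # (n_trials, n_ics, n_freqs, n_times), dB
    labels: np.ndarray          # (n_trials,) strings from TRIAL_TYPES
    spatial_maps: np.ndarray    # (n_ics, n_electrodes)
    region_labels: np.ndarray   # (n_electrodes,) strings
    grid: TFGrid
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ersp = np.asarray(self.ersp, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.spatial_maps = np.asarray(self.spatial_maps, dtype=float)
        self.region_labels = np.asarray(self.region_labels, dtype=object)
        if self.ersp.ndim != 4:
            raise ValueError("ersp must be 4-D (trial, ic, freq, time)")
        n_trials, n_ics, n_f, n_t = self.ersp.shape
        if len(self.labels) != n_trials:
            raise ValueError("labels length must match the trial axis")
        unknown = set(self.labels) - set(TRIAL_TYPES)
        if unknown:
            raise ValueError(f"unknown trial labels: {sorted(unknown)}")
        if self.spatial_maps.shape[0] != n_ics:
            raise ValueError("spatial_maps first axis must match the IC axis")
        if len(self.region_labels) != self.spatial_maps.shape[1]:
            raise ValueError("region_labels length must match the electrode axis")
        if (n_f, n_t) != self.grid.shape:
            raise ValueError(
                f"ersp grid {(n_f, n_t)} does not match grid {self.grid.shape}")

    @property
    def n_trials(self) -> int:
        return self.ersp.shape[0]

    @property
    def n_ics(self) -> int:
        return self.ersp.shape[1]

    def trials_of(self, trial_type: str) -> np.ndarray:
        """ERSP stack of all trials of one type."""
        if trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {trial_type!r}")
        return self.ersp[self.labels == trial_type]

    def type_means(self) -> dict[str, np.ndarray]:
        """Mean ERSP per trial type, (n_ics, n_freqs, n_times) each."""
        out = {}
        for t in TRIAL_TYPES:
            stack = self.trials_of(t)
            if len(stack) == 0:
                raise ValueError(f"no trials of type {t!r}")
            out[t] = stack.mean(axis=0)
        return out


def write_dataset(ds: Dataset, path: str | Path) -> None:
    meta = dict(ds.metadata)
    meta.setdefault("tf_flatten_order", ds.grid.flatten_order)
    with h5py.File(path, "w") as f:
        f.create_dataset("ersp", data=ds.ersp)
        f.create_dataset("labels", data=np.asarray(ds.labels, dtype="S"))
        f.create_dataset("spatial_maps", data=ds.spatial_maps)
        f.create_dataset("region_labels", data=np.asarray(ds.region_labels, dtype="S"))
        f.create_dataset("freqs", data=ds.grid.freqs)
        f.create_dataset("times", data=ds.grid.times)
        f.attrs["metadata"] = json.dumps(meta)


def read_dataset(path: str | Path) -> Dataset:
    with h5py.File(path, "r") as f:
        for key in ("ersp", "labels", "spatial_maps", "region_labels", "freqs", "times"):
            if key not in f:
                raise ValueError(f"dataset file is missing required group '/{key}'")
        grid = TFGrid(freqs=f["freqs"][:], times=f["times"][:])
        ds = Dataset(
            ersp=f["ersp"][:],
            labels=np.array([s.decode() for s in f["labels"][:]], dtype=object),
            spatial_maps=f["spatial_maps"][:],
            region_labels=np.array([s.decode() for s in f["region_labels"][:]],
                                   dtype=object),
            grid=grid,
            metadata=json.loads(f.attrs.get("metadata", "{}")),
        )
    return ds


@dataclass
class RunConfig:
    """All stage parameters of a pipeline run, with protocol defaults.

    Defaults mirror the standard analysis settings: 500 permutations at
    alpha = 0.05 for the cluster test, ALS tolerance 1e-6, 21-point scaling
    grids (9261 models), 80% consistency threshold, 75%/40 Hz projection
    mask, and a 40-100% sweep in 1% steps.
    """

    seed: int = 0
    # cluster permutation
    n_permutations: int = 500
    alpha: float = 0.05
    # tensor fit
    tol: float = 1e-6
    max_iter: int = 500
    n_s0: int = 21
    n_s1: int = 21
    n_s2: int = 21
    consistency_threshold: float = 80.0
    # projection
    mask_quantile: float = 0.75
    mask_fmin: float = 40.0
    # sensitivity sweep
    sweep_thresholds: tuple[float, float, float] = (40.0, 100.0, 1.0)
    # synthetic generation (None -> generator defaults)
    synthetic: dict | None = None

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("invalid ALS settings")
        if min(self.n_s0, self.n_s1, self.n_s2) < 1:
            raise ValueError("grid axes must have at least one value")
        if not (0 < self.mask_quantile <= 1):
            raise ValueError("mask_quantile must be in (0, 1]")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "sweep_thresholds" in d:
            d["sweep_thresholds"] = tuple(d["sweep_thresholds"])
        return cls(**d)
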