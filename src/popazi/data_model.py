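"""Core containers and trial-table I/O for population azimuth analysis.

The central object is :class:`ResponseDataset`: a trial x unit matrix of
non-negative responses (summed spike probabilities for imaging data, spike
counts for electrophysiology) together with a per-trial stimulus label.
Azimuth labels live on a discrete :class:`AzimuthGrid` covering the frontal
hemifield; decoding errors are absolute angular differences on that grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AzimuthGrid",
    "ResponseDataset",
    "ErrorDistribution",
    "AnalysisConfig",
    "read_dataset",
    "write_dataset",
    "absolute_error",
    "DEFAULT_GRID",
]

_LABEL_TOL = 1e-9


@dataclass(frozen=True)
class AzimuthGrid:
    """Discrete stimulus-azimuth space: 13 angles spanning the frontal
    hemifield (-90 deg to +90 deg) in 15 deg steps by default.

    ``contralateral_sign`` records which sign of azimuth denotes the
    hemifield contralateral to the recorded structure (+1: positive angles
    are contralateral). It only matters for deterministic tie-breaking and
    reporting, never for error arithmetic.
    """

    angles: tuple[float, ...] = tuple(float(a) for a in range(-90, 91, 15))
    contralateral_sign: int = 1

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        if a.size < 2:
            raise ValueError("grid needs at least two angles")
        if np.unique(a).size != a.size:
            raise ValueError("grid angles must be distinct")
        if not np.all(np.diff(a) > 0):
            raise ValueError("grid angles must be sorted ascending")
        steps = np.diff(a)
        if not np.allclose(steps, steps[0]):
            raise ValueError("grid angles must be uniformly spaced")
        if self.contralateral_sign not in (-1, 1):
            raise ValueError("contralateral_sign must be +1 or -1")

    @property
    def n_classes(self) -> int:
        return len(self.angles)

    @property
    def step(self) -> float:
        return float(self.angles[1] - self.angles[0])

    def contains(self, label: float) -> bool:
        return bool(np.any(np.abs(np.asarray(self.angles) - label) < _LABEL_TOL))

    def index(self, label: float) -> int:
        d = np.abs(np.asarray(self.angles) - label)
        i = int(np.argmin(d))
        if d[i] >= _LABEL_TOL:
            raise ValueError(f"azimuth {label!r} is not on the grid {self.angles}")
        return i

    def indices(self, labels: Iterable[float]) -> np.ndarray:
        return np.array([self.index(x) for x in labels], dtype=int)


DEFAULT_GRID = AzimuthGrid()


def absolute_error(
    true_azimuth: float, predicted_azimuth: float, grid: AzimuthGrid | None = None
) -> float:
    """Absolute angular difference |true - predicted| in degrees.

    No wrap-around is applied: the paradigm covers the frontal hemifield
    only, so errors range over {0, 15, ..., 180} on the default grid.
    """
    grid = grid or DEFAULT_GRID
    for name, value in (("true", true_azimuth), ("predicted", predicted_azimuth)):
        if not grid.contains(value):
            raise ValueError(f"{name} azimuth {value!r} is not on the grid")
    return float(abs(true_azimuth - predicted_azimuth))


@dataclass
class ResponseDataset:
    """Trial-table of single-trial population responses.

    responses : (n_trials, n_units) non-negative finite values
    labels    : per-trial stimulus value (azimuth in degrees, or tone
                frequency in kHz for frequency blocks)
    baseline  : optional per-trial pre-stimulus responses, same shape as
                ``responses`` (used for baseline-subtracted nS/N)
    """

    responses: np.ndarray
    labels: np.ndarray
    unit_ids: tuple[str, ...] = ()
    modality: str = "imaging"
    block: str = "azimuth"
    grid: AzimuthGrid = field(default_factory=AzimuthGrid)
    baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D trial x unit matrix")
        n_trials, n_units = self.responses.shape
        if n_units == 0 or n_trials == 0:
            raise ValueError("dataset must contain at least one unit and one trial")
        if self.labels.shape != (n_trials,):
            raise ValueError("labels must align with the trial axis")
        if not np.all(np.isfinite(self.responses)):
            bad = np.argwhere(~np.isfinite(self.responses))[0]
            raise ValueError(f"non-finite response at trial {bad[0]}, unit {bad[1]}")
        if np.any(self.responses < 0):
            bad = np.argwhere(self.responses < 0)[0]
            raise ValueError(f"negative response at trial {bad[0]}, unit {bad[1]}")
        if not self.unit_ids:
            self.unit_ids = tuple(f"unit_{j + 1:04d}" for j in range(n_units))
        if len(self.unit_ids) != n_units:
            raise ValueError("unit_ids must align with the unit axis")
        if len(set(self.unit_ids)) != n_units:
            raise ValueError("duplicated unit id")
        if self.modality not in ("imaging", "ephys"):
            raise ValueError("modality must be 'imaging' or 'ephys'")
        if self.block not in ("azimuth", "frequency"):
            raise ValueError("block must be 'azimuth' or 'frequency'")
        if self.block == "azimuth":
            for t, lab in enumerate(self.labels):
                if not self.grid.contains(lab):
                    raise ValueError(
                        f"trial {t}: label {lab!r} is not on the azimuth grid"
                    )
        _, counts = np.unique(self.labels, return_counts=True)
        if counts.min() < 2:
            raise ValueError("every stimulus label needs at least 2 repetitions")
        if self.baseline is not None:
            self.baseline = np.asarray(self.baseline, dtype=float)
            if self.baseline.shape != self.responses.shape:
                raise ValueError("baseline must match responses in shape")
            if not np.all(np.isfinite(self.baseline)):
                raise ValueError("non-finite baseline value")

    @property
    def n_trials(self) -> int:
        return self.responses.shape[0]

    @property
    def n_units(self) -> int:
        return self.responses.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Sorted distinct stimulus labels present in the dataset."""
        return np.unique(self.labels)

    def class_masks(self) -> dict[float, np.ndarray]:
        return {float(c): self.labels == c for c in self.classes}

    def responses_for(self, label: float) -> np.ndarray:
        return self.responses[self.labels == label]

    def subset_units(self, unit_indices: Sequence[int]) -> "ResponseDataset":
        idx = np.asarray(unit_indices, dtype=int)
        return replace(
            self,
            responses=self.responses[:, idx].copy(),
            unit_ids=tuple(self.unit_ids[j] for j in idx),
            baseline=None if self.baseline is None else self.baseline[:, idx].copy(),
        )

    def copy(self) -> "ResponseDataset":
        return replace(
            self,
            responses=self.responses.copy(),
            labels=self.labels.copy(),
            baseline=None if self.baseline is None else self.baseline.copy(),
        )


@dataclass
class ErrorDistribution:
    """Multiset of absolute azimuth prediction errors in degrees."""

    errors: np.ndarray
    provenance: str = "observed"
    grid: AzimuthGrid = field(default_factory=AzimuthGrid)

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors, dtype=float)
        if self.errors.ndim != 1 or self.errors.size == 0:
            raise ValueError("errors must be a non-empty 1-D collection")
        step = self.grid.step
        span = self.grid.angles[-1] - self.grid.angles[0]
        ok = (
            (self.errors >= -_LABEL_TOL)
            & (self.errors <= span + _LABEL_TOL)
            & (np.abs(np.round(self.errors / step) * step - self.errors) < _LABEL_TOL)
        )
        if not np.all(ok):
            raise ValueError(
                f"error {self.errors[~ok][0]!r} is not a multiple of the grid step"
            )
        if self.provenance not in ("observed", "surrogate", "chance"):
            raise ValueError("provenance must be observed | surrogate | chance")

    @property
    def n(self) -> int:
        return int(self.errors.size)

    @property
    def median(self) -> float:
        return float(np.median(self.errors))


#: kernel families in the order used for deterministic tie-breaking
KERNELS = ("uniform", "epanechnikov", "gaussian", "triangular")


@dataclass
class AnalysisConfig:
    """Plumbing knobs shared by the pipeline stages.

    ``bandwidth`` is either the string ``"silverman"`` (per-class, per-unit
    rule-of-thumb bandwidth) or a positive float interpreted as a multiple
    of each unit's training-fold response standard deviation.
    """

    seed: int = 0
    alpha: float = 0.05
    kernel: str = "gaussian"
    bandwidth: str | float = "silverman"
    knn_k: int = 5
    chi2_bins: int = 10
    n_surrogates: int = 20
    density_floor: float = 1e-300

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "silverman":
                raise ValueError("bandwidth must be 'silverman' or a positive float")
        elif self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        for name in ("knn_k", "chi2_bins", "n_surrogates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.density_floor <= 0:
            raise ValueError("density_floor must be positive")


def read_dataset(
    path: str | Path,
    schema: str = "azimuth",
    modality: str = "imaging",
    grid: AzimuthGrid | None = None,
) -> ResponseDataset:
    """Read a trial table from CSV.

    Expected columns: ``trial_id``, ``label`` and one column per unit.
    Trial order on disk is preserved (the experimental delivery order).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("trial_id", "label"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    unit_cols = [c for c in df.columns if c not in ("trial_id", "label")]
    if not unit_cols:
        raise ValueError(f"no unit columns found in {path}")
    grid = grid or DEFAULT_GRID
    labels = df["label"].to_numpy(dtype=float)
    if schema == "azimuth":
        for t, lab in enumerate(labels):
            if not grid.contains(lab):
                raise ValueError(
                    f"trial {df['trial_id'].iloc[t]!r}: label {lab!r} "
                    "is not on the azimuth grid"
                )
    return ResponseDataset(
        responses=df[unit_cols].to_numpy(dtype=float),
        labels=labels,
        unit_ids=tuple(unit_cols),
        modality=modality,
        block=schema,
        grid=grid,
    )


def write_dataset(dataset: ResponseDataset, path: str | Path) -> None:
    """Write a trial table as CSV, re-readable by :func:`read_dataset`.

    Numeric values are serialized with ``repr`` precision so that a
    round-trip reproduces them exactly; two writes of the same dataset
    yield byte-identical files.
    """
    if dataset.n_units == 0:
        raise ValueError("nothing to serialize: dataset has no units")
    df = pd.DataFrame(dataset.responses, columns=list(dataset.unit_ids))
    df.insert(0, "label", dataset.labels)
    df.insert(0, "trial_id", np.arange(1, dataset.n_trials + 1))
    df.to_csv(Path(path), index=False)
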