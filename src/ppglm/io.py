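"""Spike-time data containers and readers/writers.

Spike inputs are 2- or 3-column delimited text (CSV or TSV, auto-detected):
``neuron_id, time_seconds[, region_label]``.  Neuron ids are relabeled to a
dense 0-based internal index preserving first-appearance order; the original
labels (and user-facing 1..N numbering) are kept in metadata.  Fitted models
round-trip through a self-describing JSON document bit-exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpikePopulation",
    "FittedModel",
    "read_spikes",
    "write_spikes",
    "read_model",
    "write_model",
]

_ESTIMATOR_TAGS = ("mc", "pa-c", "pa-d", "db", "hybrid", "exact")


@dataclass
class SpikePopulation:
    """Per-neuron sorted spike times plus recording duration.

    ``spike_times`` holds one strictly increasing array of times (seconds,
    within ``[0, duration]``) per neuron.  ``labels`` are the original neuron
    identifiers, ``regions`` optional anatomical labels used by the
    connectivity-screening report.
    """

    spike_times: list
    duration: float
    labels: list | None = None
    regions: list | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.spike_times = [np.asarray(t, dtype=float) for t in self.spike_times]
        if len(self.spike_times) < 1:
            raise ValueError("population needs at least one neuron")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        for n, t in enumerate(self.spike_times):
            if t.size and (t.min() < 0 or t.max() > self.duration):
                raise ValueError(f"neuron {n}: spike times outside [0, T]")
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"neuron {n}: spike times must be strictly increasing "
                                 "(duplicates rejected)")
        if self.labels is not None and len(self.labels) != self.n_neurons:
            raise ValueError("labels length mismatch")
        if self.regions is not None and len(self.regions) != self.n_neurons:
            raise ValueError("regions length mismatch")
        self._merged_cache = None

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.spike_times))

    def counts(self) -> np.ndarray:
        """Spike count per neuron (the S_n of the sufficient statistics)."""
        return np.array([t.size for t in self.spike_times], dtype=int)

    def merged(self):
        """Globally time-sorted spikes as ``(times, neuron_index)`` arrays."""
        if self._merged_cache is None:
            times = np.concatenate(self.spike_times) if self.n_spikes else np.empty(0)
            ids = np.concatenate(
                [np.full(t.size, n, dtype=np.int64) for n, t in enumerate(self.spike_times)]
            ) if self.n_spikes else np.empty(0, dtype=np.int64)
            order = np.argsort(times, kind="stable")
            self._merged_cache = (times[order], ids[order])
        return self._merged_cache

    def time_slice(self, t0: float, t1: float) -> "SpikePopulation":
        """Sub-recording on ``[t0, t1)``, times shifted to start at 0."""
        if not (0 <= t0 < t1 <= self.duration):
            raise ValueError("invalid slice bounds")
        new = [t[(t >= t0) & (t < t1)] - t0 for t in self.spike_times]
        return SpikePopulation(new, t1 - t0, labels=self.labels, regions=self.regions,
                               metadata=dict(self.metadata, sliced=(t0, t1)))


def read_spikes(path, duration: float | None = None, sep=None) -> SpikePopulation:
    """Read a delimited spike table (``neuron_id, time_seconds[, region]``).

    A header row is auto-detected (a non-numeric value in the time column).
    Neurons are re-indexed densely preserving first-appearance order of ids;
    if ``duration`` is omitted it defaults to the last spike time, with the
    rule recorded in metadata and a warning issued.
    """
    df = pd.read_csv(path, sep=sep, engine="python", header=None, dtype=str,
                     comment="#", skip_blank_lines=True)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty spike file")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 columns (neuron_id, time_seconds)")
    # header detection: first row's time column not parseable as float
    try:
        float(df.iloc[0, 1])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
        if df.shape[0] == 0:
            raise ValueError(f"{path}: no data rows")
    ids = df.iloc[:, 0].astype(str).to_numpy()
    try:
        times = df.iloc[:, 1].astype(float).to_numpy()
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric spike time: {e}") from e
    bad = np.flatnonzero(times < 0)
    if bad.size:
        raise ValueError(f"{path}: negative spike time at row {bad[0] + 1}")
    if duration is not None:
        over = np.flatnonzero(times > duration)
        if over.size:
            raise ValueError(
                f"{path}: spike time {times[over[0]]} at row {over[0] + 1} exceeds "
                f"duration {duration}"
            )
    region_col = df.iloc[:, 2].astype(str).to_numpy() if df.shape[1] >= 3 else None

    labels = list(pd.unique(ids))  # first-appearance order
    index = {lab: n for n, lab in enumerate(labels)}
    per_neuron = [np.sort(times[ids == lab]) for lab in labels]
    regions = None
    if region_col is not None:
        regions = [region_col[ids == lab][0] for lab in labels]
    meta = {"source": str(path)}
    if duration is None:
        duration = float(times.max())
        meta["duration_rule"] = "max_spike_time"
        warnings.warn("duration not supplied; using last spike time", stacklevel=2)
    else:
        meta["duration_rule"] = "supplied"
    for lab, t in zip(labels, per_neuron):
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(f"duplicate spike time for neuron {lab!r}")
    pop = SpikePopulation(per_neuron, float(duration), labels=labels, regions=regions,
                          metadata=meta)
    return pop


def write_spikes(pop: SpikePopulation, path, sep=",") -> None:
    """Write a population back to delimited text (times at full precision)."""
    times, ids = pop.merged()
    labels = pop.labels or [str(n + 1) for n in range(pop.n_neurons)]
    with open(path, "w") as fh:
        cols = ["neuron_id", "time_seconds"] + (["region"] if pop.regions else [])
        fh.write(sep.join(cols) + "\n")
        for t, n in zip(times, ids):
            row = [str(labels[n]), repr(float(t))]
            if pop.regions:
                row.append(str(pop.regions[n]))
            fh.write(sep.join(row) + "\n")


@dataclass
class FittedModel:
    """A fitted coupling model for one postsynaptic target neuron.

    ``params`` is a :class:`ppglm.core.PPGLMParams` (weights ``(N, J)`` plus
    intercept); ``basis`` the serialized basis descriptor; ``estimator`` one
    of ``mc / pa-c / pa-d / db / hybrid / exact``.
    """

    params: object
    estimator: str
    basis: dict
    target: int | None = None
    seed: int | None = None
    n_iter: int | None = None
    final_objective: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.estimator not in _ESTIMATOR_TAGS:
            raise ValueError(f"unknown estimator tag {self.estimator!r}")
        n, j = self.params.w.shape
        if n * j + 1 != self.params.n_params:
            raise ValueError("inconsistent weight dimensionality")

    def filter_weights(self, pre: int) -> np.ndarray:
        return self.params.w[pre]


def write_model(model: FittedModel, path) -> None:
    """Serialize a fitted model to JSON.  Floats round-trip bit-exactly."""
    doc = {
        "weights": [[float(v) for v in row] for row in model.params.w],
        "intercept": float(model.params.w0),
        "link": model.params.link,
        "basis": model.basis,
        "estimator": model.estimator,
        "target": model.target,
        "seed": model.seed,
        "n_iter": model.n_iter,
        "final_objective": model.final_objective,
        "metadata": _jsonable(model.metadata),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_model(path) -> FittedModel:
    from .core import PPGLMParams  # deferred to avoid import cycle at module load

    with open(path) as fh:
        doc = json.load(fh)
    for key in ("weights", "intercept", "basis", "estimator"):
        if key not in doc:
            raise ValueError(f"{path}: model document missing {key!r}")
    params = PPGLMParams(
        w=np.array(doc["weights"], dtype=float),
        w0=float(doc["intercept"]),
        link=doc.get("link", "exp"),
    )
    return FittedModel(
        params=params,
        estimator=doc["estimator"],
        basis=doc["basis"],
        target=doc.get("target"),
        seed=doc.get("seed"),
        n_iter=doc.get("n_iter"),
        final_objective=doc.get("final_objective"),
        metadata=doc.get("metadata", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
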