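"""Core data containers: gene indices, trajectories, transition pairs.

All expression values live on a common gene axis whose order is fixed for a
session (the *gene index*).  Matrices follow the convention
``A[i, j] = effect of gene j on gene i`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "check_gene_index",
    "Trajectory",
    "TransitionPair",
    "as_transition_pairs",
]


def check_gene_index(names: Sequence[str]) -> list[str]:
    """Validate a gene index: unique, non-empty string identifiers.

    Returns the index as a plain list. The order is canonical for every
    matrix and vector built against it.
    """
    names = list(names)
    if len(names) == 0:
        raise ValueError("gene index must be non-empty")
    if len(set(names)) != len(names):
        dupes = sorted({g for g in names if names.count(g) > 1})
        raise ValueError(f"gene index contains duplicates: {dupes[:5]}")
    return names


@dataclass
class Trajectory:
    """An ordered series of expression states for one unit of observation.

    Parameters
    ----------
    times : (T,) array
        Strictly increasing observation times (arbitrary units).
    values : (T, n) array
        Expression state at each time; nominally in [0, 1] but values outside
        that range (e.g. after additive noise) are accepted.
    genes : list of str, optional
        Gene index; purely annotational here, shapes are what is validated.
    """

    times: np.ndarray
    values: np.ndarray
    genes: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.values.ndim != 2 or self.values.shape[0] != self.times.size:
            raise ValueError(
                f"values must be (len(times), n); got {self.values.shape} "
                f"for {self.times.size} times"
            )
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise ValueError("times and values must be finite")
        if self.genes is not None:
            self.genes = check_gene_index(self.genes)
            if len(self.genes) != self.values.shape[1]:
                raise ValueError("gene index length does not match values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return self.times.size


@dataclass
class TransitionPair:
    """Two consecutive expression vectors with their times.

    The atomic training example for (pseudo)time-course data: the model is
    asked to integrate from ``g0`` at ``t0`` and land on ``g1`` at ``t1``.
    """

    t0: float
    t1: float
    g0: np.ndarray
    g1: np.ndarray

    def __post_init__(self) -> None:
        self.t0 = float(self.t0)
        self.t1 = float(self.t1)
        self.g0 = np.asarray(self.g0, dtype=float).ravel()
        self.g1 = np.asarray(self.g1, dtype=float).ravel()
        if not self.t0 < self.t1:
            raise ValueError(f"need t0 < t1, got {self.t0} >= {self.t1}")
        if self.g0.shape != self.g1.shape:
            raise ValueError("g0 and g1 must have the same length")
        if not (np.all(np.isfinite(self.g0)) and np.all(np.isfinite(self.g1))):
            raise ValueError("expression vectors must be finite")

    @property
    def duration(self) -> float:
        return self.t1 - self.t0

    @property
    def n_genes(self) -> int:
        return self.g0.size


def as_transition_pairs(data) -> list[TransitionPair]:
    """Normalize training input to a flat list of transition pairs.

    Accepts a single :class:`Trajectory`, a list of trajectories, a list of
    :class:`TransitionPair`, or a mix. Each trajectory contributes one pair
    per consecutive time step.
    """
    if isinstance(data, (Trajectory, TransitionPair)):
        data = [data]
    pairs: list[TransitionPair] = []
    for item in data:
        if isinstance(item, TransitionPair):
            pairs.append(item)
        elif isinstance(item, Trajectory):
            for k in range(len(item) - 1):
                pairs.append(
                    TransitionPair(
                        item.times[k], item.times[k + 1],
                        item.values[k], item.values[k + 1],
                    )
                )
        else:
            raise TypeError(f"cannot interpret {type(item).__name__} as training data")
    n_set = {p.n_genes for p in pairs}
    if len(n_set) > 1:
        raise ValueError(f"inconsistent gene counts across pairs: {sorted(n_set)}")
    return pairs
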