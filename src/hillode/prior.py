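"""Signed prior network model and the linear prior predictor (A - I) g.

The prior is an adjacency matrix ``A`` with entries in {-1, 0, +1},
``A[i, j]`` = putative signed effect of gene j on gene i (e.g. from a
promoter motif map). Its velocity prediction is the simple linear feedback
model ``P*(g) = (A - I) g``, used as a soft constraint during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PriorModel", "prior_predict", "sample_ghost_vectors"]


@dataclass
class PriorModel:
    """Signed prior adjacency; entries restricted to {-1, 0, +1}."""

    A: np.ndarray
    genes: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        if not np.isin(self.A, (-1.0, 0.0, 1.0)).all():
            raise ValueError("prior adjacency entries must be in {-1, 0, +1}")
        if self.genes is not None and len(self.genes) != self.A.shape[0]:
            raise ValueError("gene index length does not match A")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        off = self.A.copy()
        np.fill_diagonal(off, 0.0)
        return int(np.count_nonzero(off))


def prior_predict(gamma, prior: PriorModel) -> np.ndarray:
    """Linear prior velocity ``(A - I) gamma``; batched over leading axes."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape[-1] != prior.n:
        raise ValueError(
            f"gamma has {gamma.shape[-1]} genes, prior expects {prior.n}"
        )
    return gamma @ (prior.A - np.eye(prior.n)).T


def sample_ghost_vectors(K: int, n: int, seed) -> np.ndarray:
    """Draw K i.i.d. Uniform(0,1)^n ghost expression vectors, shape (K, n).

    Ghost vectors are the random states at which the model's velocity is
    compared to the prior's prediction inside the regularized loss.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=(K, n))
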