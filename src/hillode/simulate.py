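"""In-silico benchmark: ground-truth signed GRNs and noisy trajectories.

Generates a directed signed regulatory network with heavy-tailed out-degrees
(a minority of hub TFs), defines Hill-kinetics ODE dynamics on it, integrates
noiseless expression trajectories from uniform initial states, and adds
i.i.d. Gaussian measurement noise. Defaults emulate a scarce time-series
design: 160 trajectories observed at t = {0, 2, 3, 7, 9}, a range that
covers the transition from initial condition to steady state, with noise
sigma in {0, 1/40, 1/20, 1/10} (roughly 0/5/10/20% of the mean signal).

The per-gene dynamics are a feedback process

    dg_i/dt = r_i * mean_{j in act(i)} H(g_j; a_ij, k_ij)
                  * prod_{j in rep(i)} (1 - H(g_j; a_ij, k_ij))  -  g_i

with Hill curves ``H(P) = P^a / (k^a + P^a)``, activator factor 1 when a
gene has no activators, and ``dg_i/dt = 0`` for root genes (no regulators
at all), which therefore stay at their initial value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .types import Trajectory

__all__ = [
    "SimConfig",
    "SyntheticGRN",
    "generate_grn",
    "hill",
    "true_velocity",
    "simulate_trajectories",
    "add_noise",
    "split_trajectories",
]

DEFAULT_TIMES = (0.0, 2.0, 3.0, 7.0, 9.0)
NOISE_LEVELS = (0.0, 1.0 / 40.0, 1.0 / 20.0, 1.0 / 10.0)


@dataclass
class SimConfig:
    """Benchmark protocol parameters (defaults are the study conditions)."""

    n_genes: int
    n_edges: int
    n_trajectories: int = 160
    times: tuple = DEFAULT_TIMES
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if not 1 <= self.n_edges <= self.n_genes * (self.n_genes - 1):
            raise ValueError(
                f"n_edges must be in [1, {self.n_genes * (self.n_genes - 1)}]"
            )
        t = np.asarray(self.times, dtype=float)
        if t[0] != 0.0 or (t.size >= 2 and not np.all(np.diff(t) > 0)):
            raise ValueError("times must start at 0 and increase strictly")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SyntheticGRN:
    """Ground-truth network plus the kinetic coefficients of its ODEs.

    ``adjacency[i, j]`` in {-1, 0, +1} is the signed effect of gene j on
    gene i; ``alpha``/``kappa`` hold per-edge Hill exponents and thresholds
    (zero where there is no edge); ``max_rate`` is the per-gene maximal
    production rate r_i.
    """

    adjacency: np.ndarray
    alpha: np.ndarray
    kappa: np.ndarray
    max_rate: np.ndarray
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if np.any(np.diag(A) != 0):
            raise ValueError("self-edges are not allowed")
        if not np.isin(A, (-1, 0, 1)).all():
            raise ValueError("adjacency entries must be in {-1, 0, +1}")
        edge = A != 0
        if np.any((self.alpha[edge] < 1) | (self.alpha[edge] > 4)):
            raise ValueError("hill exponents must lie in [1, 4]")
        if np.any((self.kappa[edge] <= 0) | (self.kappa[edge] >= 1)):
            raise ValueError("hill thresholds must lie in (0, 1)")
        if np.any(self.max_rate <= 0):
            raise ValueError("max rates must be positive")
        if not self.genes:
            self.genes = [f"G{i}" for i in range(A.shape[0])]

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency))


def generate_grn(cfg: SimConfig) -> SyntheticGRN:
    """Sample a ground-truth signed GRN under `cfg.seed`.

    Edges are placed one at a time with the source drawn with probability
    proportional to (current out-degree + 1) — preferential attachment, so
    out-degrees are heavy-tailed and a minority of hub regulators emerges.
    Targets are uniform; self-edges and duplicates are excluded. Each edge
    is activating or repressive with equal probability. Kinetic
    coefficients: per-edge exponent alpha ~ Uniform{1,2,3,4}, threshold
    kappa ~ Uniform(0.3, 0.7); per-gene max rate r ~ Uniform(0.5, 1.5).
    """
    rng = np.random.default_rng(cfg.seed)
    n, E = cfg.n_genes, cfg.n_edges
    A = np.zeros((n, n), dtype=int)
    out_deg = np.zeros(n)
    placed = 0
    while placed < E:
        w = out_deg + 1.0
        src = rng.choice(n, p=w / w.sum())
        free = np.flatnonzero((A[:, src] == 0) & (np.arange(n) != src))
        if free.size == 0:
            # source saturated; fall back to a uniformly random open slot
            open_t, open_s = np.nonzero(
                (A == 0) & ~np.eye(n, dtype=bool)
            )
            k = rng.integers(open_t.size)
            tgt, src = open_t[k], open_s[k]
        else:
            tgt = rng.choice(free)
        A[tgt, src] = 1 if rng.random() < 0.5 else -1
        out_deg[src] += 1
        placed += 1
    edge = A != 0
    alpha = np.where(edge, rng.integers(1, 5, size=(n, n)), 0.0)
    kappa = np.where(edge, rng.uniform(0.3, 0.7, size=(n, n)), 0.0)
    rate = rng.uniform(0.5, 1.5, size=n)
    return SyntheticGRN(A, alpha.astype(float), kappa, rate)


def hill(P, alpha, kappa):
    """Hill-Langmuir occupancy ``P^a / (k^a + P^a)``; P clipped at 0."""
    P = np.clip(P, 0.0, None)
    Y = (P / kappa) ** alpha
    return Y / (1.0 + Y)


def true_velocity(g, grn: SyntheticGRN) -> np.ndarray:
    """Ground-truth derivative at state ``g``; batched over leading axes.

    Bounded per gene: dg_i/dt in [-g_i, r_i - g_i]. Root genes (no
    regulators) get exactly zero.
    """
    g = np.asarray(g, dtype=float)
    A = grn.adjacency
    act = A > 0
    rep = A < 0
    edge = A != 0
    has_reg = edge.any(axis=1)
    # H[..., i, j] = occupancy of regulator j on target i's edge;
    # dummy coefficients on non-edges avoid 0/0, then get masked out
    kappa = np.where(edge, grn.kappa, 0.5)
    alpha = np.where(edge, grn.alpha, 1.0)
    H = hill(g[..., None, :], alpha, kappa) * edge
    n_act = act.sum(axis=1)
    act_mean = np.where(
        n_act > 0,
        (H * act).sum(axis=-1) / np.maximum(n_act, 1),
        1.0,
    )
    rep_prod = np.where(rep, 1.0 - H, 1.0).prod(axis=-1)
    f = grn.max_rate * act_mean * rep_prod
    return np.where(has_reg, f - g, 0.0)


def simulate_trajectories(grn: SyntheticGRN, cfg: SimConfig) -> list[Trajectory]:
    """Integrate noiseless trajectories from i.i.d. Uniform(0,1)^n starts.

    All trajectories are stacked into one flat ODE system and integrated
    with an adaptive RK45 solver (rtol 1e-6, atol 1e-8). Deterministic
    under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    times = np.asarray(cfg.times, dtype=float)
    B, n = cfg.n_trajectories, grn.n
    G0 = rng.uniform(0.0, 1.0, size=(B, n))
    if times.size == 1:
        return [Trajectory(times, G0[k][None, :], genes=grn.genes) for k in range(B)]

    def rhs(t, y):
        return true_velocity(y.reshape(B, n), grn).ravel()

    sol = solve_ivp(
        rhs, (times[0], times[-1]), G0.ravel(),
        method="RK45", t_eval=times, rtol=1e-6, atol=1e-8,
    )
    if not sol.success:
        raise RuntimeError(f"trajectory integration failed: {sol.message}")
    Y = sol.y.T.reshape(times.size, B, n)
    return [Trajectory(times, Y[:, k, :], genes=grn.genes) for k in range(B)]


def add_noise(trajs: list[Trajectory], sigma: float, seed) -> list[Trajectory]:
    """Add i.i.d. N(0, sigma^2) noise to every observed value (t = 0 too).

    Values are not clamped to [0, 1]; downstream code accepts out-of-range
    expression.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for tr in trajs:
        noisy = tr.values + rng.normal(0.0, sigma, size=tr.values.shape) if sigma > 0 else tr.values.copy()
        out.append(Trajectory(tr.times.copy(), noisy, genes=tr.genes))
    return out


def split_trajectories(trajs: list[Trajectory], counts=(140, 10, 10), seed=0):
    """Disjoint random partition into (train, val, test) with exact counts."""
    counts = tuple(int(c) for c in counts)
    if sum(counts) != len(trajs):
        raise ValueError(
            f"counts {counts} sum to {sum(counts)} but there are {len(trajs)} trajectories"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trajs))
    a, b = counts[0], counts[0] + counts[1]
    pick = lambda idx: [trajs[i] for i in idx]
    return pick(order[:a]), pick(order[a:b]), pick(order[b:])
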