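"""Hill-kinetics neural-ODE derivative network.

The local derivative (RNA velocity) of an ``n``-gene expression state ``g``
is modeled as a feedback process

    dg/dt = ReLU(v) * ( W_combine [c_sum(g) ; c_prod(g)] - g )

with two single-layer blocks capturing additive and multiplicative
co-regulation:

    c_sum(g)  = W_sum  phi_sum(g)  + b_sum
    c_prod(g) = exp( W_prod phi_prod(g) + b_prod )

The activations emulate Hill-Langmuir occupancy curves
``H(P) = P^a / (k^a + P^a)``, which — after centering at the middle of the
normalized expression range — resemble the softsign function:

    phi_sum(x)  = (x - 0.5) / (1 + |x - 0.5|)
    phi_prod(x) = log( phi_sum(x) + 1 )

The log-scale block composed with an elementwise ``exp`` lets sums in the
hidden layer represent products of Hill terms. The per-gene gate ``ReLU(v)``
lets the model represent genes with no upstream regulators exactly
(``v_i <= 0`` freezes gene ``i``).

The system is autonomous: the derivative has no explicit time dependence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .types import Trajectory

__all__ = [
    "phi_sum",
    "phi_prod",
    "HillODEParams",
    "SolverConfig",
    "SolverError",
    "init_params",
    "block_outputs",
    "velocity",
    "solve",
    "solve_batch",
    "analytic_jacobian",
    "save_params",
    "load_params",
]

CHECKPOINT_FORMAT = "hillode-params-v1"


def _check_finite(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")
    return x


def phi_sum(x) -> np.ndarray:
    """Shifted softsign activation, elementwise.

    ``phi_sum(x) = (x - 0.5) / (1 + |x - 0.5|)``; odd-symmetric about 0.5,
    with range (-1, 1) and ``phi_sum(0.5) = 0``.
    """
    x = _check_finite(x, "phi_sum input")
    u = x - 0.5
    return u / (1.0 + np.abs(u))


def phi_prod(x) -> np.ndarray:
    """Log-scale Hill-like activation, elementwise.

    ``phi_prod(x) = log(phi_sum(x) + 1)``; the log argument lies in (0, 2)
    because the shifted softsign is bounded in (-1, 1).
    """
    x = _check_finite(x, "phi_prod input")
    return np.log(phi_sum(x) + 1.0)


def _softsign_deriv(x: np.ndarray) -> np.ndarray:
    # two-sided subgradient 1 at the kink x = 0.5
    return 1.0 / (1.0 + np.abs(x - 0.5)) ** 2


@dataclass
class HillODEParams:
    """Trainable parameters theta of the derivative network.

    Shapes for ``n`` genes and hidden width ``m``:

    - ``W_sum``, ``W_prod``: (m, n); ``b_sum``, ``b_prod``: (m,)
    - ``W_combine``: (n, 2m) acting on the concatenation [c_sum ; c_prod]
    - ``v``: (n,) per-gene gate, applied through ReLU
    """

    W_sum: np.ndarray
    b_sum: np.ndarray
    W_prod: np.ndarray
    b_prod: np.ndarray
    W_combine: np.ndarray
    v: np.ndarray
    genes: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        for name in ("W_sum", "b_sum", "W_prod", "b_prod", "W_combine", "v"):
            setattr(self, name, _check_finite(getattr(self, name), name))
        m, n = self.W_sum.shape
        if self.W_prod.shape != (m, n):
            raise ValueError("W_prod shape inconsistent with W_sum")
        if self.b_sum.shape != (m,) or self.b_prod.shape != (m,):
            raise ValueError("bias shapes inconsistent with hidden width")
        if self.W_combine.shape != (n, 2 * m):
            raise ValueError(
                f"W_combine must be (n, 2m) = ({n}, {2 * m}), got {self.W_combine.shape}"
            )
        if self.v.shape != (n,):
            raise ValueError("v must have length n")

    @property
    def n(self) -> int:
        return self.W_sum.shape[1]

    @property
    def m(self) -> int:
        return self.W_sum.shape[0]

    @property
    def W_comb_sum(self) -> np.ndarray:
        """Slice of W_combine acting on the additive block output."""
        return self.W_combine[:, : self.m]

    @property
    def W_comb_prod(self) -> np.ndarray:
        """Slice of W_combine acting on the multiplicative block output."""
        return self.W_combine[:, self.m :]

    def copy(self) -> "HillODEParams":
        return HillODEParams(
            self.W_sum.copy(), self.b_sum.copy(),
            self.W_prod.copy(), self.b_prod.copy(),
            self.W_combine.copy(), self.v.copy(),
            genes=None if self.genes is None else list(self.genes),
        )

    def arrays(self) -> dict[str, np.ndarray]:
        return {
            "W_sum": self.W_sum, "b_sum": self.b_sum,
            "W_prod": self.W_prod, "b_prod": self.b_prod,
            "W_combine": self.W_combine, "v": self.v,
        }


@dataclass
class SolverConfig:
    """Adaptive-step integrator settings for inference-time solves."""

    method: str = "RK45"
    rtol: float = 1e-5
    atol: float = 1e-7
    max_steps: int = 100_000

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("rtol and atol must be positive")
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")


class SolverError(RuntimeError):
    """Raised when numerical integration fails; carries the failing interval."""

    def __init__(self, message: str, t_span=None):
        super().__init__(message)
        self.t_span = t_span


def init_params(
    n: int,
    m: int | None = None,
    rng: np.random.Generator | int | None = 0,
    weight_scale: float = 0.1,
    genes: list[str] | None = None,
) -> HillODEParams:
    """Random initialization: small weights, zero biases, open gates (v = 1).

    With small weights the initial field is close to pure decay
    ``dg/dt ~ -g``, a stable starting point for optimization.
    """
    if m is None:
        m = n
    rng = np.random.default_rng(rng)
    s = weight_scale / np.sqrt(n)
    return HillODEParams(
        W_sum=rng.normal(0.0, s, size=(m, n)),
        b_sum=np.zeros(m),
        W_prod=rng.normal(0.0, s, size=(m, n)),
        b_prod=np.zeros(m),
        W_combine=rng.normal(0.0, weight_scale / np.sqrt(2 * m), size=(n, 2 * m)),
        v=np.ones(n),
        genes=genes,
    )


def block_outputs(g, theta: HillODEParams):
    """Additive and multiplicative block outputs ``(c_sum, c_prod)``.

    ``g`` may be a single state ``(n,)`` or a batch ``(..., n)``; the block
    outputs have matching leading shape with trailing dimension ``m``.
    ``c_prod`` is strictly positive (image of exp).
    """
    g = _check_finite(g, "expression state")
    if g.shape[-1] != theta.n:
        raise ValueError(f"state has {g.shape[-1]} genes, parameters expect {theta.n}")
    c_sum = phi_sum(g) @ theta.W_sum.T + theta.b_sum
    c_prod = np.exp(phi_prod(g) @ theta.W_prod.T + theta.b_prod)
    return c_sum, c_prod


def velocity(g, theta: HillODEParams) -> np.ndarray:
    """Model derivative dg/dt at state ``g`` (single state or batch).

    Genes with ``v_i <= 0`` have exactly zero velocity.
    """
    c_sum, c_prod = block_outputs(g, theta)
    h = c_sum @ theta.W_comb_sum.T + c_prod @ theta.W_comb_prod.T
    g = np.asarray(g, dtype=float)
    return np.maximum(theta.v, 0.0) * (h - g)


def _integrate(y0: np.ndarray, times: np.ndarray, rhs, cfg: SolverConfig) -> np.ndarray:
    """solve_ivp wrapper returning states at the requested times (T, dim)."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("times must be a non-empty 1-D array")
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if times.size == 1:
        return y0[None, :].copy()

    budget = {"nfev": 0}
    limit = 10 * cfg.max_steps  # RHS evaluations, not solver steps

    def counted(t, y):
        budget["nfev"] += 1
        if budget["nfev"] > limit:
            raise SolverError(
                f"integration exceeded {cfg.max_steps} steps on "
                f"[{times[0]}, {times[-1]}]",
                t_span=(times[0], times[-1]),
            )
        return rhs(t, y)

    sol = solve_ivp(
        counted, (times[0], times[-1]), y0,
        method=cfg.method, t_eval=times, rtol=cfg.rtol, atol=cfg.atol,
    )
    if not sol.success:
        raise SolverError(
            f"solver failed on [{times[0]}, {times[-1]}]: {sol.message}",
            t_span=(times[0], times[-1]),
        )
    return sol.y.T


def solve(g0, times, theta: HillODEParams, cfg: SolverConfig | None = None) -> Trajectory:
    """Integrate the model from ``g0`` over ``times`` with an adaptive solver.

    ``times[0]`` is the time of ``g0``; the returned trajectory starts with
    ``g0`` exactly. Deterministic given ``(g0, theta, cfg)``. Because the
    system is autonomous, shifting all times by a constant leaves the
    returned states unchanged.
    """
    cfg = cfg or SolverConfig()
    g0 = _check_finite(g0, "g0").ravel()
    states = _integrate(g0, np.asarray(times, float), lambda t, y: velocity(y, theta), cfg)
    return Trajectory(times=np.asarray(times, float), values=states, genes=theta.genes)


def solve_batch(G0, times, theta: HillODEParams, cfg: SolverConfig | None = None) -> np.ndarray:
    """Integrate a batch of initial states jointly; returns (T, B, n).

    The batch is stacked into one flat ODE system so the adaptive solver
    amortizes step-size control across trajectories.
    """
    cfg = cfg or SolverConfig()
    G0 = _check_finite(G0, "G0")
    if G0.ndim != 2:
        raise ValueError("G0 must be (B, n)")
    B, n = G0.shape

    def rhs(t, y):
        return velocity(y.reshape(B, n), theta).ravel()

    states = _integrate(G0.ravel(), np.asarray(times, float), rhs, cfg)
    return states.reshape(-1, B, n)


def analytic_jacobian(g, theta: HillODEParams) -> np.ndarray:
    """Closed-form Jacobian ``J[i, j] = d velocity_i / d g_j`` at state ``g``.

    Chain rule through the two activation blocks:

        J = ReLU(v)[:, None] * ( (Wc_sum @ W_sum) * phi_sum'(g)
                                 + (Wc_prod @ (c_prod[:, None] * W_prod)) * phi_prod'(g)
                                 - I )

    where ``phi_prod'(g) = phi_sum'(g) / (phi_sum(g) + 1)``. At the softsign
    kink ``g_j = 0.5`` the two-sided derivative 1 is used. Rows with
    ``v_i <= 0`` are identically zero.
    """
    g = _check_finite(g, "expression state").ravel()
    if g.size != theta.n:
        raise ValueError("state length does not match parameters")
    _, c_prod = block_outputs(g, theta)
    sp = _softsign_deriv(g)                      # (n,)
    pp = sp / (phi_sum(g) + 1.0)                 # (n,)
    lin = (theta.W_comb_sum @ theta.W_sum) * sp[None, :]
    mul = (theta.W_comb_prod @ (c_prod[:, None] * theta.W_prod)) * pp[None, :]
    relu_v = np.maximum(theta.v, 0.0)
    return relu_v[:, None] * (lin + mul - np.eye(theta.n))


def save_params(theta: HillODEParams, path) -> None:
    """Write a versioned plain-text (JSON) checkpoint of the six arrays."""
    payload = {
        "format": CHECKPOINT_FORMAT,
        "n": theta.n,
        "m": theta.m,
        "genes": theta.genes,
        "arrays": {k: v.tolist() for k, v in theta.arrays().items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_params(path) -> HillODEParams:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != CHECKPOINT_FORMAT:
        raise ValueError(f"unrecognized checkpoint format: {payload.get('format')!r}")
    arrs = {k: np.asarray(v, dtype=float) for k, v in payload["arrays"].items()}
    return HillODEParams(
        arrs["W_sum"], arrs["b_sum"], arrs["W_prod"], arrs["b_prod"],
        arrs["W_combine"], arrs["v"], genes=payload.get("genes"),
    )
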