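"""Hand-written reverse-mode differentiation for the derivative network.

Provides vector-Jacobian products of `velocity` w.r.t. both the state and
the parameters, backpropagation through a fixed-step classical RK4
integrator (differentiate-through-the-steps), and a plain Adam optimizer.
Everything is batched: states are (B, n) arrays.
"""

from __future__ import annotations

import numpy as np

from .model import HillODEParams

PARAM_KEYS = ("W_sum", "b_sum", "W_prod", "b_prod", "W_combine", "v")


def zero_grads(theta: HillODEParams) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in theta.arrays().items()}


def velocity_forward(G: np.ndarray, theta: HillODEParams):
    """Batched velocity with a cache of intermediates for the backward pass."""
    U = G - 0.5
    D = 1.0 + np.abs(U)
    S = U / D                                   # phi_sum(G)
    P = np.log(S + 1.0)                         # phi_prod(G)
    A = S @ theta.W_sum.T + theta.b_sum         # c_sum, (B, m)
    C = np.exp(P @ theta.W_prod.T + theta.b_prod)  # c_prod, (B, m)
    H = A @ theta.W_comb_sum.T + C @ theta.W_comb_prod.T
    R = np.maximum(theta.v, 0.0)
    V = R * (H - G)
    cache = (G, D, S, P, A, C, H, R)
    return V, cache


def velocity_vjp(cache, theta: HillODEParams, gbar: np.ndarray,
                 grads: dict[str, np.ndarray]) -> np.ndarray:
    """Accumulate d<gbar, velocity>/d theta into `grads`; return d/dG."""
    G, D, S, P, A, C, H, R = cache
    mask = theta.v > 0.0
    grads["v"] += np.where(mask, (gbar * (H - G)).sum(axis=0), 0.0)
    W = gbar * R                                # (B, n)
    grads["W_combine"][:, : theta.m] += W.T @ A
    grads["W_combine"][:, theta.m :] += W.T @ C
    gA = W @ theta.W_comb_sum                   # (B, m)
    gC = W @ theta.W_comb_prod
    gQ = gC * C                                 # through exp
    grads["b_prod"] += gQ.sum(axis=0)
    grads["W_prod"] += gQ.T @ P
    gP = gQ @ theta.W_prod
    grads["b_sum"] += gA.sum(axis=0)
    grads["W_sum"] += gA.T @ S
    gS = gA @ theta.W_sum + gP / (S + 1.0)
    return gS / D**2 - W


def rk4_forward(G0: np.ndarray, duration: float, n_steps: int,
                theta: HillODEParams):
    """Classical RK4 over `n_steps` equal steps; returns final state + tape."""
    h = duration / n_steps
    G = G0
    tape = []
    for _ in range(n_steps):
        K1, _ = velocity_forward(G, theta)
        K2, _ = velocity_forward(G + 0.5 * h * K1, theta)
        K3, _ = velocity_forward(G + 0.5 * h * K2, theta)
        K4, _ = velocity_forward(G + h * K3, theta)
        tape.append((G, K1, K2, K3))
        G = G + (h / 6.0) * (K1 + 2.0 * K2 + 2.0 * K3 + K4)
    return G, (tape, h)


def rk4_backward(tape_h, Gbar: np.ndarray, theta: HillODEParams,
                 grads: dict[str, np.ndarray]) -> np.ndarray:
    """Backpropagate a cotangent on the final state through the RK4 tape."""
    tape, h = tape_h
    for G, K1, K2, K3 in reversed(tape):
        bK1 = (h / 6.0) * Gbar
        bK2 = (h / 3.0) * Gbar
        bK3 = (h / 3.0) * Gbar
        bK4 = (h / 6.0) * Gbar
        bG = Gbar.copy()
        # stage inputs are recomputed from the stored slopes
        _, c4 = velocity_forward(G + h * K3, theta)
        g4 = velocity_vjp(c4, theta, bK4, grads)
        bG += g4
        bK3 = bK3 + h * g4
        _, c3 = velocity_forward(G + 0.5 * h * K2, theta)
        g3 = velocity_vjp(c3, theta, bK3, grads)
        bG += g3
        bK2 = bK2 + 0.5 * h * g3
        _, c2 = velocity_forward(G + 0.5 * h * K1, theta)
        g2 = velocity_vjp(c2, theta, bK2, grads)
        bG += g2
        bK1 = bK1 + 0.5 * h * g2
        _, c1 = velocity_forward(G, theta)
        g1 = velocity_vjp(c1, theta, bK1, grads)
        Gbar = bG + g1
    return Gbar


class Adam:
    """Minimal Adam over the parameter dict of a HillODEParams."""

    def __init__(self, theta: HillODEParams, lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.theta = theta
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = zero_grads(theta)
        self.s = zero_grads(theta)
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        arrays = self.theta.arrays()
        for k in PARAM_KEYS:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.s[k] = b2 * self.s[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            shat = self.s[k] / (1 - b2**self.t)
            arrays[k] -= self.lr * mhat / (np.sqrt(shat) + self.eps)
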