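"""Prior-regularized training of the Hill neural ODE.

The modified loss combines a data term (match observed transitions by
integrating the model) and a prior term (match the linear prior velocity
``(A - I) g`` at randomly sampled *ghost* expression vectors):

    L_mod = (1 - lambda_prior) * L_data + lambda_prior * L_prior

Both terms are mean-squared errors. Training differentiates through the
steps of a fixed-step RK4 integrator (hand-written reverse mode) and
updates parameters with Adam. ``HillODE`` is a scikit-learn-style
estimator; :func:`fit`, :func:`loss_mod` and :func:`tune_lambda` are thin
functional wrappers over it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from . import _autograd as ag
from .model import HillODEParams, SolverConfig, init_params, solve, velocity
from .prior import PriorModel, prior_predict, sample_ghost_vectors
from .types import TransitionPair, as_transition_pairs

__all__ = [
    "TrainConfig",
    "FitResult",
    "HillODE",
    "loss_mod",
    "fit",
    "tune_lambda",
    "split_transition_pairs",
]


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``lambda_prior`` is the weight on the prior term (the data term gets
    ``1 - lambda_prior``); ``K`` is the number of ghost vectors drawn per
    epoch; ``steps_per_unit`` sets the fixed RK4 step density used for the
    differentiable solve during training (the adaptive solver in
    ``solver`` is used for inference-time prediction).
    """

    lambda_prior: float = 0.0
    K: int = 32
    epochs: int = 300
    learning_rate: float = 1e-2
    batch_size: int | None = None
    seed: int = 0
    solver: SolverConfig = field(default_factory=SolverConfig)
    steps_per_unit: int = 4
    n_hidden: int | None = None
    weight_scale: float = 0.1
    lr_patience: int = 20
    lr_factor: float = 0.5
    min_lr: float = 1e-4

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_prior <= 1.0:
            raise ValueError("lambda_prior must lie in [0, 1]")
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass
class FitResult:
    """Outcome of one training run.

    ``theta`` is the parameter set with the best monitored loss seen during
    training (validation data-loss when a validation set was supplied,
    training loss otherwise).
    """

    theta: HillODEParams
    train_loss_history: np.ndarray
    val_loss_history: np.ndarray | None
    lambda_prior_used: float


def _group_pairs(pairs: list[TransitionPair]):
    """Batch pairs by duration (the system is autonomous, so only the
    interval length matters for the solve)."""
    groups: dict[float, list[TransitionPair]] = {}
    for p in pairs:
        groups.setdefault(round(p.duration, 12), []).append(p)
    return {
        d: (np.stack([p.g0 for p in ps]), np.stack([p.g1 for p in ps]))
        for d, ps in groups.items()
    }


def _data_loss(groups, theta, steps_per_unit, grads=None, weight=1.0):
    """Mean squared transition error; optionally accumulate weighted grads."""
    n_pairs = sum(G0.shape[0] for G0, _ in groups.values())
    n = theta.n
    total = 0.0
    for dur, (G0, G1) in groups.items():
        n_steps = max(1, math.ceil(dur * steps_per_unit))
        pred, tape = ag.rk4_forward(G0, dur, n_steps, theta)
        res = pred - G1
        total += float(np.sum(res**2))
        if grads is not None and weight > 0:
            ag.rk4_backward(tape, (2.0 * weight / (n_pairs * n)) * res, theta, grads)
    return total / (n_pairs * n)


def _prior_loss(ghosts, theta, prior, grads=None, weight=1.0):
    """Mean squared mismatch between model velocity and (A - I) gamma."""
    V, cache = ag.velocity_forward(ghosts, theta)
    res = V - prior_predict(ghosts, prior)
    K, n = ghosts.shape
    if grads is not None and weight > 0:
        ag.velocity_vjp(cache, theta, (2.0 * weight / (K * n)) * res, grads)
    return float(np.mean(res**2))


class HillODE(BaseEstimator):
    """Hill-kinetics neural ODE for gene-regulatory dynamics.

    Parameters mirror :class:`TrainConfig`; ``n_hidden=None`` uses one
    hidden unit per gene per block (m = n). Call :meth:`fit` with a list of
    :class:`~hillode.types.Trajectory` or
    :class:`~hillode.types.TransitionPair` (and optionally a signed prior),
    then :meth:`predict` to integrate from new initial states.

    Attributes (after fit)
    ----------------------
    params_ : HillODEParams
        Fitted derivative-network parameters (best monitored epoch).
    loss_history_ : ndarray
        Combined training loss per epoch.
    val_loss_history_ : ndarray or None
        Pure data loss on the validation set per epoch.
    n_genes_, n_hidden_ : int
    """

    def __init__(
        self,
        lambda_prior: float = 0.0,
        K: int = 32,
        epochs: int = 300,
        learning_rate: float = 1e-2,
        batch_size: int | None = None,
        steps_per_unit: int = 4,
        n_hidden: int | None = None,
        weight_scale: float = 0.1,
        lr_patience: int = 20,
        lr_factor: float = 0.5,
        min_lr: float = 1e-4,
        solver_rtol: float = 1e-5,
        solver_atol: float = 1e-7,
        random_state: int = 0,
    ):
        self.lambda_prior = lambda_prior
        self.K = K
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.steps_per_unit = steps_per_unit
        self.n_hidden = n_hidden
        self.weight_scale = weight_scale
        self.lr_patience = lr_patience
        self.lr_factor = lr_factor
        self.min_lr = min_lr
        self.solver_rtol = solver_rtol
        self.solver_atol = solver_atol
        self.random_state = random_state

    # -- core API -----------------------------------------------------

    def fit(self, X, y=None, *, prior: PriorModel | None = None, validation=None):
        """Fit the derivative network to transition data.

        Parameters
        ----------
        X : Trajectory | TransitionPair | list thereof
            Training data; trajectories are decomposed into transition pairs.
        prior : PriorModel, optional
            Signed prior adjacency. Required when ``lambda_prior > 0``.
        validation : same shapes as X, optional
            Held-out transitions; their pure data loss is monitored for
            learning-rate decay and best-parameter selection.
        """
        if not 0.0 <= self.lambda_prior <= 1.0:
            raise ValueError("lambda_prior must lie in [0, 1]")
        pairs = as_transition_pairs(X)
        if len(pairs) == 0:
            raise ValueError("need at least one training pair")
        n = pairs[0].n_genes
        if self.lambda_prior > 0 and prior is None:
            raise ValueError("lambda_prior > 0 requires a prior model")
        if prior is not None and prior.n != n:
            raise ValueError("prior dimension does not match data")
        val_groups = None
        if validation is not None:
            vpairs = as_transition_pairs(validation)
            if vpairs:
                val_groups = _group_pairs(vpairs)

        m = self.n_hidden or n
        rng = np.random.default_rng(self.random_state)
        theta = init_params(n, m, rng, self.weight_scale)
        opt = ag.Adam(theta, lr=self.learning_rate)
        lam_p = float(self.lambda_prior)
        lam_d = 1.0 - lam_p

        all_groups = _group_pairs(pairs)
        train_hist, val_hist = [], []
        best = math.inf
        best_theta = theta.copy()
        wait = 0
        for epoch in range(self.epochs):
            if self.batch_size is not None and self.batch_size < len(pairs):
                idx = rng.choice(len(pairs), size=self.batch_size, replace=False)
                groups = _group_pairs([pairs[i] for i in idx])
            else:
                groups = all_groups
            grads = ag.zero_grads(theta)
            d_loss = (
                _data_loss(groups, theta, self.steps_per_unit, grads, weight=lam_d)
                if lam_d > 0
                else _data_loss(groups, theta, self.steps_per_unit)
            )
            p_loss = 0.0
            if lam_p > 0:
                ghosts = sample_ghost_vectors(self.K, n, rng)
                p_loss = _prior_loss(ghosts, theta, prior, grads, weight=lam_p)
            loss = lam_d * d_loss + lam_p * p_loss
            if not math.isfinite(loss):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            opt.step(grads)
            train_hist.append(loss)
            if val_groups is not None:
                v = _data_loss(val_groups, theta, self.steps_per_unit)
                val_hist.append(v)
                monitored = v
            else:
                monitored = loss
            if monitored < best:
                best = monitored
                best_theta = theta.copy()
                wait = 0
            else:
                wait += 1
                if wait >= self.lr_patience and opt.lr > self.min_lr:
                    opt.lr = max(self.min_lr, opt.lr * self.lr_factor)
                    wait = 0

        self.params_ = best_theta
        self.n_genes_ = n
        self.n_hidden_ = m
        self.loss_history_ = np.asarray(train_hist)
        self.val_loss_history_ = np.asarray(val_hist) if val_hist else None
        return self

    def predict(self, g0, times):
        """Integrate the fitted model from ``g0`` over ``times`` (adaptive solver)."""
        self._check_fitted()
        cfg = SolverConfig(rtol=self.solver_rtol, atol=self.solver_atol)
        return solve(g0, times, self.params_, cfg)

    def velocity(self, g):
        """Fitted derivative (RNA velocity) at state(s) ``g``."""
        self._check_fitted()
        return velocity(g, self.params_)

    def score(self, X, y=None):
        """Negative mean squared transition error on ``X`` (higher is better)."""
        self._check_fitted()
        groups = _group_pairs(as_transition_pairs(X))
        return -_data_loss(groups, self.params_, self.steps_per_unit)

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted; call fit() first")


# -- functional wrappers ----------------------------------------------


def _estimator_from_config(cfg: TrainConfig) -> HillODE:
    return HillODE(
        lambda_prior=cfg.lambda_prior,
        K=cfg.K,
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        steps_per_unit=cfg.steps_per_unit,
        n_hidden=cfg.n_hidden,
        weight_scale=cfg.weight_scale,
        lr_patience=cfg.lr_patience,
        lr_factor=cfg.lr_factor,
        min_lr=cfg.min_lr,
        solver_rtol=cfg.solver.rtol,
        solver_atol=cfg.solver.atol,
        random_state=cfg.seed,
    )


def fit(data, prior: PriorModel | None, cfg: TrainConfig, validation=None) -> FitResult:
    """Train a model under ``cfg``; see :class:`HillODE` for details."""
    est = _estimator_from_config(cfg).fit(data, prior=prior, validation=validation)
    return FitResult(
        theta=est.params_,
        train_loss_history=est.loss_history_,
        val_loss_history=est.val_loss_history_,
        lambda_prior_used=cfg.lambda_prior,
    )


def data_loss(pairs, theta: HillODEParams, cfg: TrainConfig | None = None) -> float:
    """Pure data loss: mean squared error of integrated transitions."""
    cfg = cfg or TrainConfig()
    pairs = as_transition_pairs(pairs)
    if not pairs:
        raise ValueError("need at least one pair")
    return _data_loss(_group_pairs(pairs), theta, cfg.steps_per_unit)


def loss_mod(pairs, theta: HillODEParams, prior: PriorModel | None,
             cfg: TrainConfig, ghosts: np.ndarray | None = None) -> float:
    """Combined loss (1 - lambda_prior) * L_data + lambda_prior * L_prior.

    Ghost vectors default to ``K`` uniform draws under ``cfg.seed``.
    Nonnegative; equals the pure data loss at ``lambda_prior = 0`` and the
    pure prior loss at ``lambda_prior = 1``.
    """
    pairs = as_transition_pairs(pairs)
    if not pairs:
        raise ValueError("need at least one pair")
    lam_p = cfg.lambda_prior
    total = 0.0
    if lam_p < 1.0:
        total += (1.0 - lam_p) * _data_loss(_group_pairs(pairs), theta, cfg.steps_per_unit)
    if lam_p > 0.0:
        if prior is None:
            raise ValueError("lambda_prior > 0 requires a prior model")
        if ghosts is None:
            ghosts = sample_ghost_vectors(cfg.K, theta.n, cfg.seed)
        total += lam_p * _prior_loss(ghosts, theta, prior)
    return total


def tune_lambda(train, val, prior: PriorModel | None, cfg: TrainConfig,
                candidate_lambdas, fit_fn=None, return_details: bool = False):
    """Select lambda_prior by validation data-loss over a candidate grid.

    Each candidate is trained on ``train`` and scored by the pure L2 loss
    on the validation transitions (no prior term). Ties break toward the
    larger lambda (more prior weight, sparser dynamics). ``fit_fn`` can
    replace the training routine (signature ``fit_fn(train, prior, cfg) ->
    FitResult``) — useful for testing the selection rule in isolation.
    """
    candidates = [float(c) for c in candidate_lambdas]
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    fit_fn = fit_fn or fit
    val_pairs = as_transition_pairs(val)
    best_lam, best_mse, details = None, math.inf, {}
    for lam in candidates:
        res = fit_fn(train, prior, replace(cfg, lambda_prior=lam), validation=val)
        mse = data_loss(val_pairs, res.theta, cfg)
        details[lam] = mse
        if mse < best_mse or (mse == best_mse and (best_lam is None or lam > best_lam)):
            best_lam, best_mse = lam, mse
    if return_details:
        return best_lam, details
    return best_lam


def split_transition_pairs(data, fractions=(0.86, 0.07, 0.07), seed=0):
    """Randomly partition transition pairs into (train, val, test).

    Counts follow the fractions by largest-remainder rounding, so e.g. 46
    pairs at (40/46, 3/46, 3/46) give exactly (40, 3, 3). A positive
    fraction that rounds to zero pairs is an error.
    """
    pairs = as_transition_pairs(data)
    fr = np.asarray(fractions, dtype=float)
    if fr.size != 3 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be three nonnegative values summing to 1")
    N = len(pairs)
    raw = fr * N
    counts = np.floor(raw).astype(int)
    rem = N - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for k in range(rem):
        counts[order[k]] += 1
    if np.any((fr > 0) & (counts == 0)):
        raise ValueError(
            f"{N} pairs cannot honor fractions {tuple(fr)}: some split would be empty"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    a, b = counts[0], counts[0] + counts[1]
    pick = lambda idx: [pairs[i] for i in idx]
    return pick(perm[:a]), pick(perm[a:b]), pick(perm[b:])
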