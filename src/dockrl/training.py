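"""Asynchronous advantage actor-critic training over a stream of boxes.

Each episode cuts a fresh box around a record's true site, drops the ligand
at a random start, and rolls the policy out; every ``t_max`` steps (or at
episode end) n-step returns are formed, standard A3C losses are computed
and plain-SGD updates are applied to the shared parameters. Workers run
independent episodes and apply updates without mutual ordering guarantees;
with ``num_workers=1`` a run is bit-reproducible given its seed.
"""

from __future__ import annotations

import math
import threading
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .env import DockingEnv, EnvConfig
from .metrics import rmsd
from .networks import PolicyNetwork, ValueNetwork
from .structures import ChannelMap, ComplexRecord
from .voxel import BoxPlacementError, BoxSpec

__all__ = ["Adam", "SGD", "TrainConfig", "compute_losses", "make_optimizer", "n_step_returns", "train"]


@dataclass(frozen=True)
class TrainConfig:
    """Rollout and optimization hyperparameters.

    Defaults follow the single-atom configuration: actor learning rate
    5e-5, critic 1e-7, updates every ``t_max=10`` steps, discount 1.
    The sulfate variant prints actor 5e-6 (same critic rate).
    """

    episodes: int = 100
    gamma: float = 1.0
    t_max: int = 10
    lr_actor: float = 5e-5
    lr_critic: float = 1e-7
    entropy_coef: float = 0.01
    grad_clip: float = 40.0
    optimizer: str = "sgd"  # sgd | adam
    momentum: float = 0.0
    normalize_advantage: bool = False
    num_workers: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.lr_actor <= 0 or self.lr_critic <= 0:
            raise ValueError("learning rates must be positive")


def n_step_returns(rewards, bootstrap: float, gamma: float) -> np.ndarray:
    """Backward recursion ``G_i = R_i + γ·G_{i+1}`` with ``G`` past the
    buffer equal to ``bootstrap`` (0 at terminal, else the critic value of
    the successor state)."""
    rewards = np.asarray(rewards, dtype=float)
    out = np.empty_like(rewards)
    g = float(bootstrap)
    for i in range(len(rewards) - 1, -1, -1):
        g = rewards[i] + gamma * g
        out[i] = g
    return out


def compute_losses(
    actor: PolicyNetwork,
    critic: ValueNetwork,
    states: np.ndarray,
    actions,
    returns: np.ndarray,
    entropy_coef: float = 0.0,
    normalize_advantage: bool = False,
):
    """A3C losses and gradients for one rollout buffer.

    Advantages ``A_i = G_i - V(s_i)`` are treated as constants in the
    policy term; with ``normalize_advantage`` they are standardized per
    buffer (zero mean, unit variance), which rescales the exponential
    reward's small magnitudes for fixed-step SGD in short desk-scale runs.
    Returns ``(policy_loss, value_loss, entropy, actor_grads, critic_grads)``.
    """
    returns = np.asarray(returns, dtype=float)
    value_loss, critic_grads = critic.loss_and_grads(states, returns)
    values = critic._last  # forward pass just ran inside loss_and_grads
    advantages = returns - values
    if normalize_advantage:
        advantages = advantages - advantages.mean()
        std = advantages.std()
        if std > 1e-12:
            advantages = advantages / std
    policy_loss, entropy, actor_grads = actor.loss_and_grads(
        states, actions, advantages, entropy_coef
    )
    return policy_loss, value_loss, entropy, actor_grads, critic_grads


class SGD:
    """Stochastic gradient descent with global-norm gradient clipping,
    updating parameter arrays in place (shared across worker clones).

    Plain SGD by default; optional heavy-ball momentum for short
    desk-scale runs where the exponential reward's small magnitudes give
    per-update gradients too weak for a fixed step size.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float,
        grad_clip: float | None = None,
        momentum: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.grad_clip = grad_clip
        self.momentum = momentum
        self._velocity = (
            {k: np.zeros_like(v) for k, v in params.items()} if momentum > 0 else None
        )

    def step(self, grads: dict[str, np.ndarray]) -> None:
        if self.grad_clip is not None:
            norm = math.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if norm > self.grad_clip:
                scale = self.grad_clip / norm
                grads = {k: g * scale for k, g in grads.items()}
        if self._velocity is None:
            for k, g in grads.items():
                self.params[k] -= self.lr * g
        else:
            for k, g in grads.items():
                v = self._velocity[k]
                v *= self.momentum
                v += g
                self.params[k] -= self.lr * v


class Adam:
    """Adam optimizer (Kingma & Ba) with the same clipping contract as
    :class:`SGD`. Optional alternative for short desk-scale runs: its
    per-parameter step normalization balances the very different gradient
    scales of the convolution trunk and the dense head."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float,
        grad_clip: float | None = None,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.grad_clip = grad_clip
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = {k: np.zeros_like(v) for k, v in params.items()}
        self._v = {k: np.zeros_like(v) for k, v in params.items()}
        self._t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        if self.grad_clip is not None:
            norm = math.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if norm > self.grad_clip:
                grads = {k: g * (self.grad_clip / norm) for k, g in grads.items()}
        self._t += 1
        b1c = 1.0 - self.beta1**self._t
        b2c = 1.0 - self.beta2**self._t
        for k, g in grads.items():
            m, v = self._m[k], self._v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            self.params[k] -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def make_optimizer(config: TrainConfig, params: dict[str, np.ndarray], lr: float):
    if config.optimizer == "adam":
        return Adam(params, lr, config.grad_clip)
    if config.optimizer == "sgd":
        return SGD(params, lr, config.grad_clip, config.momentum)
    raise ValueError(f"unknown optimizer: {config.optimizer!r}")


def _run_episode(
    record: ComplexRecord,
    actor: PolicyNetwork,
    critic: ValueNetwork,
    cfg: TrainConfig,
    channel_map: ChannelMap,
    box_spec: BoxSpec,
    env_cfg: EnvConfig,
    rng: np.random.Generator,
    opt_actor: SGD,
    opt_critic: SGD,
    update_lock: threading.Lock | None,
) -> dict:
    env = DockingEnv(record, channel_map, box_spec, env_cfg, seed=rng)
    obs = env.reset()
    start_rmsd = rmsd(env.true_pose, env.pose)
    states, actions, rewards = [], [], []
    n_updates = 0
    totals = {"policy_loss": 0.0, "value_loss": 0.0, "entropy": 0.0}
    done = False
    while not done:
        action = actor.sample_action(obs, rng)
        next_obs, reward, done, info = env.step(action)
        states.append(obs)
        actions.append(action)
        rewards.append(reward)  # stored post-doubling
        if next_obs is not None:
            obs = next_obs
        if len(states) == cfg.t_max or done:
            bootstrap = 0.0 if done else critic.value(obs)
            returns = n_step_returns(rewards, bootstrap, cfg.gamma)
            batch = np.stack(states)
            p_loss, v_loss, ent, a_grads, c_grads = compute_losses(
                actor, critic, batch, actions, returns,
                cfg.entropy_coef, cfg.normalize_advantage,
            )
            if update_lock is None:
                opt_actor.step(a_grads)
                opt_critic.step(c_grads)
            else:
                with update_lock:
                    opt_actor.step(a_grads)
                    opt_critic.step(c_grads)
            totals["policy_loss"] += p_loss
            totals["value_loss"] += v_loss
            totals["entropy"] += ent
            n_updates += 1
            states, actions, rewards = [], [], []
    final_rmsd = rmsd(env.true_pose, env.pose)
    return {
        "steps": env.step_count,
        "final_rmsd": final_rmsd,
        "improvement_rate": (start_rmsd - final_rmsd) / start_rmsd if start_rmsd > 0 else np.nan,
        "n_updates": n_updates,
        **totals,
    }


def train(
    records: list[ComplexRecord],
    actor: PolicyNetwork,
    critic: ValueNetwork,
    config: TrainConfig,
    channel_map: ChannelMap,
    box_spec: BoxSpec | None = None,
    env_config: EnvConfig | None = None,
    log_path=None,
    checkpoint_dir=None,
    checkpoint_every: int | None = None,
) -> pd.DataFrame:
    """Run A3C training and return the per-episode log.

    Each episode draws a record at random, builds a fresh box (skipping and
    logging placement failures) and performs ``ceil(steps / t_max)``
    gradient updates. The log has one row per episode with the final RMSD
    and improvement rate (the learning-curve series), plus loss totals.
    """
    if not records:
        raise ValueError("dataset is empty")
    box_spec = box_spec or BoxSpec()
    env_config = env_config or EnvConfig()
    opt_actor = make_optimizer(config, actor.params(), config.lr_actor)
    opt_critic = make_optimizer(config, critic.params(), config.lr_critic)

    log_rows: list[dict] = []
    log_lock = threading.Lock()
    seed_seq = np.random.SeedSequence(config.seed)

    def worker(worker_id: int, episode_ids: list[int], w_actor, w_critic, update_lock):
        rng = np.random.default_rng(seed_seq.spawn(config.num_workers)[worker_id])
        for ep in episode_ids:
            record = records[rng.integers(len(records))]
            try:
                row = _run_episode(
                    record, w_actor, w_critic, config, channel_map, box_spec,
                    env_config, rng, opt_actor, opt_critic, update_lock,
                )
            except BoxPlacementError as exc:
                row = {"steps": 0, "final_rmsd": np.nan, "improvement_rate": np.nan,
                       "n_updates": 0, "policy_loss": np.nan, "value_loss": np.nan,
                       "entropy": np.nan, "skipped": str(exc)}
            row["episode"] = ep
            row["worker"] = worker_id
            with log_lock:
                log_rows.append(row)

    if config.num_workers <= 1:
        # Single-worker fast path: bit-reproducible, no locking.
        rng = np.random.default_rng(seed_seq.spawn(1)[0])
        for ep in range(config.episodes):
            record = records[rng.integers(len(records))]
            try:
                row = _run_episode(
                    record, actor, critic, config, channel_map, box_spec,
                    env_config, rng, opt_actor, opt_critic, None,
                )
            except BoxPlacementError as exc:
                row = {"steps": 0, "final_rmsd": np.nan, "improvement_rate": np.nan,
                       "n_updates": 0, "policy_loss": np.nan, "value_loss": np.nan,
                       "entropy": np.nan, "skipped": str(exc)}
            row["episode"] = ep
            row["worker"] = 0
            log_rows.append(row)
            if checkpoint_dir and checkpoint_every and (ep + 1) % checkpoint_every == 0:
                _save_checkpoints(actor, critic, checkpoint_dir, ep + 1)
    else:
        update_lock = threading.Lock()
        chunks = [list(range(w, config.episodes, config.num_workers)) for w in range(config.num_workers)]
        threads = []
        for w, chunk in enumerate(chunks):
            threads.append(
                threading.Thread(
                    target=worker,
                    args=(w, chunk, actor.clone_shared(), critic.clone_shared(), update_lock),
                )
            )
        for t in threads:
            t.start()
        for t in threads:
            t.join()
        log_rows.sort(key=lambda r: r["episode"])

    log = pd.DataFrame(log_rows)
    if checkpoint_dir:
        _save_checkpoints(actor, critic, checkpoint_dir, config.episodes)
    if log_path is not None:
        log.to_csv(log_path, index=False)
    return log


def _save_checkpoints(actor, critic, checkpoint_dir, episode: int) -> None:
    from pathlib import Path

    d = Path(checkpoint_dir)
    d.mkdir(parents=True, exist_ok=True)
    actor.save(d / f"actor_ep{episode}.npz")
    critic.save(d / f"critic_ep{episode}.npz")
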