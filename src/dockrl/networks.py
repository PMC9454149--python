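"""Actor and critic networks: parallel 3-D convolutions in pure NumPy.

Architecture (6 layers): input grid → one parallel block of three
independent same-extent 3-D convolutions (filter counts 4/8/8, edge
lengths 2/3/4 for the single-atom variant, 4/5/6 for sulfate) concatenated
on the channel axis → 3×3×3 max pooling (stride 3, remainder dropped) →
flatten → dense 256 + ReLU → head.  The policy head is one 6-way softmax
(single-atom) or two parallel 6-way softmaxes (translation + rotation);
the value head is a single tanh unit, so critic outputs live in (−1, 1).

No autodiff framework is available in the runtime, so every layer
implements its own float64 backward pass; gradients are validated against
finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CheckpointMismatchError",
    "PolicyNetwork",
    "TrunkConfig",
    "ValueNetwork",
    "filter_sizes",
    "load_policy",
    "load_value",
]


class CheckpointMismatchError(ValueError):
    """Checkpoint config/channel-map hash does not match the current run."""


def filter_sizes(variant: str) -> tuple[int, int, int]:
    """Edge lengths of the three parallel convolution filters per variant."""
    if variant == "single":
        return (2, 3, 4)
    if variant == "multi":
        return (4, 5, 6)
    raise ValueError(f"unknown variant: {variant!r}")


# ----------------------------------------------------------------- layers


class _Conv3DSame:
    """3-D convolution preserving spatial extent.

    "Same" padding puts the extra cell on the high side of each axis for
    even kernels: low pad = (k-1)//2, high pad = k-1-low.
    """

    def __init__(self, name, in_channels, filters, size, rng):
        self.name = name
        self.size = size
        fan_in = size**3 * in_channels
        limit = np.sqrt(6.0 / (fan_in + filters))
        self.W = rng.uniform(-limit, limit, size=(size, size, size, in_channels, filters))
        self.b = np.zeros(filters)
        self._cache = None

    def params(self):
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def forward(self, x):
        k = self.size
        lo = (k - 1) // 2
        hi = k - 1 - lo
        xp = np.pad(x, ((0, 0), (lo, hi), (lo, hi), (lo, hi), (0, 0)))
        B, D, H, W_, _ = x.shape
        out = np.broadcast_to(self.b, (B, D, H, W_, self.b.size)).copy()
        for i in range(k):
            for j in range(k):
                for m in range(k):
                    out += xp[:, i : i + D, j : j + H, m : m + W_, :] @ self.W[i, j, m]
        self._cache = (xp, x.shape, lo)
        return out

    def backward(self, dout, grads):
        xp, x_shape, lo = self._cache
        B, D, H, W_, C = x_shape
        k = self.size
        dW = np.zeros_like(self.W)
        dxp = np.zeros_like(xp)
        dflat = dout.reshape(-1, dout.shape[-1])
        for i in range(k):
            for j in range(k):
                for m in range(k):
                    sl = xp[:, i : i + D, j : j + H, m : m + W_, :]
                    dW[i, j, m] = sl.reshape(-1, C).T @ dflat
                    dxp[:, i : i + D, j : j + H, m : m + W_, :] += dout @ self.W[i, j, m].T
        grads[f"{self.name}.W"] = dW
        grads[f"{self.name}.b"] = dout.sum(axis=(0, 1, 2, 3))
        return dxp[:, lo : lo + D, lo : lo + H, lo : lo + W_, :]


class _ParallelConv3D:
    """Three independent same-extent convolutions, concatenated channelwise."""

    def __init__(self, in_channels, sizes, counts, rng):
        self.paths = [
            _Conv3DSame(f"conv{i}", in_channels, f, k, rng)
            for i, (k, f) in enumerate(zip(sizes, counts))
        ]
        self.out_channels = sum(counts)

    def params(self):
        out = {}
        for p in self.paths:
            out.update(p.params())
        return out

    def forward(self, x):
        return np.concatenate([p.forward(x) for p in self.paths], axis=-1)

    def backward(self, dout, grads):
        dx = None
        start = 0
        for p in self.paths:
            f = p.b.size
            d = p.backward(dout[..., start : start + f], grads)
            dx = d if dx is None else dx + d
            start += f
        return dx


class _MaxPool3D:
    """3×3×3 max pooling, stride 3; trailing cells that do not fill a
    window are dropped (18³ → 6³, 8³ → 2³)."""

    def __init__(self, pool=3):
        self.p = pool
        self._cache = None

    def forward(self, x):
        p = self.p
        B, D, H, W_, C = x.shape
        d, h, w = D // p, H // p, W_ // p
        xc = x[:, : d * p, : h * p, : w * p, :]
        xr = (
            xc.reshape(B, d, p, h, p, w, p, C)
            .transpose(0, 1, 3, 5, 7, 2, 4, 6)
            .reshape(B, d, h, w, C, p**3)
        )
        am = np.argmax(xr, axis=-1)
        out = np.take_along_axis(xr, am[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, am)
        return out

    def backward(self, dout, grads):
        p = self.p
        (B, D, H, W_, C), am = self._cache
        d, h, w = D // p, H // p, W_ // p
        dxr = np.zeros((B, d, h, w, C, p**3))
        np.put_along_axis(dxr, am[..., None], dout[..., None], axis=-1)
        dxc = (
            dxr.reshape(B, d, h, w, C, p, p, p)
            .transpose(0, 1, 5, 2, 6, 3, 7, 4)
            .reshape(B, d * p, h * p, w * p, C)
        )
        dx = np.zeros((B, D, H, W_, C))
        dx[:, : d * p, : h * p, : w * p, :] = dxc
        return dx


class _Flatten:
    def __init__(self):
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout, grads):
        return dout.reshape(self._shape)


class _Dense:
    """Affine layer. Output heads use ``zero_init`` so the initial policy is
    exactly uniform and the initial value estimate is 0 — keeps early
    bootstraps and advantages free of initialization noise."""

    def __init__(self, name, n_in, n_out, rng, zero_init=False):
        self.name = name
        if zero_init:
            self.W = np.zeros((n_in, n_out))
        else:
            limit = np.sqrt(6.0 / (n_in + n_out))
            self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self._x = None

    def params(self):
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout, grads):
        grads[f"{self.name}.W"] = self._x.T @ dout
        grads[f"{self.name}.b"] = dout.sum(axis=0)
        return dout @ self.W.T


class _ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout, grads):
        return dout * self._mask


# ------------------------------------------------------------------ trunk


@dataclass(frozen=True)
class TrunkConfig:
    """Shared trunk hyperparameters. ``filter_sizes=None`` selects the
    per-variant defaults; overrides are honored and recorded."""

    grid_extent: int = 18
    n_channels: int = 22
    variant: str = "single"  # single | multi
    filter_sizes: tuple[int, int, int] | None = None
    filter_counts: tuple[int, int, int] = (4, 8, 8)
    hidden: int = 256
    pool: int = 3

    def resolved_filter_sizes(self) -> tuple[int, int, int]:
        return tuple(self.filter_sizes) if self.filter_sizes else filter_sizes(self.variant)

    def to_json(self) -> str:
        d = {
            "grid_extent": self.grid_extent,
            "n_channels": self.n_channels,
            "variant": self.variant,
            "filter_sizes": list(self.resolved_filter_sizes()),
            "filter_counts": list(self.filter_counts),
            "hidden": self.hidden,
            "pool": self.pool,
        }
        return json.dumps(d, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "TrunkConfig":
        d = json.loads(text)
        return TrunkConfig(
            grid_extent=d["grid_extent"],
            n_channels=d["n_channels"],
            variant=d["variant"],
            filter_sizes=tuple(d["filter_sizes"]),
            filter_counts=tuple(d["filter_counts"]),
            hidden=d["hidden"],
            pool=d["pool"],
        )


class _Trunk:
    def __init__(self, cfg: TrunkConfig, rng):
        sizes = cfg.resolved_filter_sizes()
        self.block = _ParallelConv3D(cfg.n_channels, sizes, cfg.filter_counts, rng)
        self.pool = _MaxPool3D(cfg.pool)
        self.flat = _Flatten()
        side = cfg.grid_extent // cfg.pool
        self.n_flat = side**3 * self.block.out_channels
        self.dense = _Dense("dense", self.n_flat, cfg.hidden, rng)
        self.relu = _ReLU()
        self.layers = [self.block, self.pool, self.flat, self.dense, self.relu]

    def params(self):
        out = {}
        out.update(self.block.params())
        out.update(self.dense.params())
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout, grads):
        for layer in reversed(self.layers):
            dout = layer.backward(dout, grads)
        return dout


class _Network:
    """Common parameter plumbing for actor/critic."""

    kind = "network"

    def __init__(self, cfg: TrunkConfig, seed: int, channel_map_hash: str = ""):
        self.cfg = cfg
        self.seed = seed
        self.channel_map_hash = channel_map_hash
        rng = np.random.default_rng(seed)
        self.trunk = _Trunk(cfg, rng)
        self._build_head(rng)

    def _build_head(self, rng):  # pragma: no cover - overridden
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params().values()))

    def set_params(self, values: dict[str, np.ndarray]) -> None:
        params = self.params()
        if set(values) != set(params):
            raise ValueError("parameter name mismatch")
        for k, v in values.items():
            if params[k].shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            params[k][...] = v

    def _check_input(self, x):
        x = np.asarray(x, dtype=float)
        if x.ndim == 4:
            x = x[None]
        e, c = self.cfg.grid_extent, self.cfg.n_channels
        if x.shape[1:] != (e, e, e, c):
            raise ValueError(f"expected grid of shape ({e},{e},{e},{c}), got {x.shape[1:]}")
        return x

    def _param_layers(self) -> list:
        raise NotImplementedError

    def clone_shared(self):
        """A new instance *sharing* this network's parameter arrays but with
        independent forward caches — one clone per asynchronous worker.
        In-place optimizer updates through any clone are visible to all."""
        twin = type(self)(self.cfg, self.seed, self.channel_map_hash)
        for mine, theirs in zip(self._param_layers(), twin._param_layers()):
            theirs.W = mine.W
            theirs.b = mine.b
        return twin

    def save(self, path) -> None:
        meta = json.dumps(
            {
                "kind": self.kind,
                "config": self.cfg.to_json(),
                "seed": self.seed,
                "channel_map_hash": self.channel_map_hash,
            }
        )
        np.savez(path, __meta__=np.array(meta), **self.params())


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _log_softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


class PolicyNetwork(_Network):
    """Actor π_θ(a|s): maps a density grid to action probabilities.

    ``variant="single"`` → one 6-way softmax; ``variant="multi"`` → two
    parallel 6-way softmax heads (translation, rotation).
    """

    kind = "policy"

    def _build_head(self, rng):
        self.head_t = _Dense("head_t", self.cfg.hidden, 6, rng, zero_init=True)
        self.head_r = (
            _Dense("head_r", self.cfg.hidden, 6, rng, zero_init=True)
            if self.cfg.variant == "multi"
            else None
        )

    def _param_layers(self):
        layers = [*self.trunk.block.paths, self.trunk.dense, self.head_t]
        if self.head_r is not None:
            layers.append(self.head_r)
        return layers

    def params(self):
        out = self.trunk.params()
        out.update(self.head_t.params())
        if self.head_r is not None:
            out.update(self.head_r.params())
        return out

    def forward(self, x):
        """Action distribution(s): (B, 6) for single, a pair of (B, 6) for
        multi. Deterministic given parameters and input."""
        x = self._check_input(x)
        feats = self.trunk.forward(x)
        z_t = self.head_t.forward(feats)
        probs_t = _softmax(z_t)
        self._last = (feats, z_t)
        if self.head_r is None:
            return probs_t
        z_r = self.head_r.forward(feats)
        self._last = (feats, z_t, z_r)
        return probs_t, _softmax(z_r)

    @staticmethod
    def _head_grad(logits, actions, advantages, entropy_coef):
        # log-probs via log-softmax: finite even when the policy saturates
        B = logits.shape[0]
        probs = _softmax(logits)
        logp = _log_softmax(logits)
        ent = -np.where(probs > 0, probs * logp, 0.0).sum(axis=1)
        onehot = np.zeros_like(probs)
        onehot[np.arange(B), actions] = 1.0
        dlogits = (probs - onehot) * advantages[:, None]
        dlogits += entropy_coef * probs * (logp + ent[:, None])
        pg = -(logp[np.arange(B), actions] * advantages).sum()
        return dlogits, pg, ent.sum()

    def loss_and_grads(self, states, actions, advantages, entropy_coef=0.0):
        """Policy-gradient loss ``-Σ log π(a|s)·A - β·H(π)`` and its
        parameter gradients (advantages treated as constants).

        ``actions`` is an int array (B,) for single or (B, 2) for multi
        (translation index, rotation index). Returns
        ``(loss, entropy, grads)``.
        """
        states = self._check_input(states)
        advantages = np.asarray(advantages, dtype=float)
        grads: dict[str, np.ndarray] = {}
        self.forward(states)
        if self.head_r is None:
            feats, z_t = self._last
            actions = np.asarray(actions, dtype=int).reshape(-1)
            dlog_t, pg, ent = self._head_grad(z_t, actions, advantages, entropy_coef)
            dfeats = self.head_t.backward(dlog_t, grads)
        else:
            feats, z_t, z_r = self._last
            actions = np.asarray(actions, dtype=int).reshape(-1, 2)
            dlog_t, pg_t, ent_t = self._head_grad(z_t, actions[:, 0], advantages, entropy_coef)
            dlog_r, pg_r, ent_r = self._head_grad(z_r, actions[:, 1], advantages, entropy_coef)
            pg, ent = pg_t + pg_r, ent_t + ent_r
            dfeats = self.head_t.backward(dlog_t, grads) + self.head_r.backward(dlog_r, grads)
        self.trunk.backward(dfeats, grads)
        loss = pg - entropy_coef * ent
        return float(loss), float(ent), grads

    def sample_action(self, grid, rng: np.random.Generator):
        """Draw an action from π(·|s) for a single state."""
        out = self.forward(np.asarray(grid)[None])
        if self.head_r is None:
            return int(rng.choice(6, p=out[0]))
        pt, pr = out
        return (int(rng.choice(6, p=pt[0])), int(rng.choice(6, p=pr[0])))

    def greedy_action(self, grid):
        """Argmax action; ties broken toward the lowest index."""
        out = self.forward(np.asarray(grid)[None])
        if self.head_r is None:
            return int(np.argmax(out[0]))
        pt, pr = out
        return (int(np.argmax(pt[0])), int(np.argmax(pr[0])))


class ValueNetwork(_Network):
    """Critic V_ω(s): scalar tanh output in (−1, 1)."""

    kind = "value"

    def _build_head(self, rng):
        self.head = _Dense("head_v", self.cfg.hidden, 1, rng, zero_init=True)

    def _param_layers(self):
        return [*self.trunk.block.paths, self.trunk.dense, self.head]

    def params(self):
        out = self.trunk.params()
        out.update(self.head.params())
        return out

    def forward(self, x):
        x = self._check_input(x)
        feats = self.trunk.forward(x)
        v = np.tanh(self.head.forward(feats))[:, 0]
        self._last = v
        return v

    def value(self, grid) -> float:
        return float(self.forward(np.asarray(grid)[None])[0])

    def loss_and_grads(self, states, targets):
        """Squared-error value loss ``Σ (G - V(s))²`` and its gradients."""
        states = self._check_input(states)
        targets = np.asarray(targets, dtype=float)
        grads: dict[str, np.ndarray] = {}
        v = self.forward(states)
        loss = float(((targets - v) ** 2).sum())
        dv = 2.0 * (v - targets)
        dz = (dv * (1.0 - v**2))[:, None]
        dfeats = self.head.backward(dz, grads)
        self.trunk.backward(dfeats, grads)
        return loss, grads


def _load(path, cls, expected_hash: str | None):
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta["kind"] != cls.kind:
            raise CheckpointMismatchError(f"checkpoint is a {meta['kind']}, expected {cls.kind}")
        if expected_hash is not None and meta["channel_map_hash"] != expected_hash:
            raise CheckpointMismatchError(
                "channel map hash mismatch: checkpoint "
                f"{meta['channel_map_hash']!r} vs current {expected_hash!r}"
            )
        cfg = TrunkConfig.from_json(meta["config"])
        net = cls(cfg, seed=meta["seed"], channel_map_hash=meta["channel_map_hash"])
        net.set_params({k: data[k] for k in data.files if k != "__meta__"})
    return net


def load_policy(path, expected_channel_map_hash: str | None = None) -> PolicyNetwork:
    """Load a policy checkpoint, refusing on config/channel-map mismatch."""
    return _load(path, PolicyNetwork, expected_channel_map_hash)


def load_value(path, expected_channel_map_hash: str | None = None) -> ValueNetwork:
    return _load(path, ValueNetwork, expected_channel_map_hash)
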