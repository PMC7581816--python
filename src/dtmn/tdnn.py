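"""Time-delay neural network over prior hidden states and present features.

The network predicts the present hidden state ``q_t`` from a window of prior
hidden states ``q_{t-K}..q_{t-1}`` (encoded as one-hot indicator vectors; an
absent state at the start of a sequence is an all-zero vector) plus the
present feature vector ``f_t``:

* Layer-1: a position-wise affine + batch-norm + ReLU applied to the state
  indicator at every offset of the network context (weights untied across
  offsets).
* Layer-2: affine + batch-norm + ReLU over the concatenated Layer-1 outputs
  at the sub-sampled offset set.
* Layer-3: concatenation of the Layer-2 output with the learned affine
  feature transform ``beta(f_t)``.
* Layer-4: fully connected affine + batch-norm + ReLU of hidden width H.
* Layer-5: affine to the C state classes followed by a softmax.

Layer-1's transform is tied (shared) across temporal positions. The
``tdnn1``..``tdnn6`` presets are all the five-layer network with the
published context sets; ``eq2`` is the literal shallow model
``softmax(W_q a(q_{t-1}) + W_f beta(f_t) + b)`` with no hidden layers.

Everything is plain numpy with manual gradients; training is mini-batch SGD
with momentum on the mean cross-entropy, deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import DomainError, StructuralError
from .data import ABSENT

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


# ---------------------------------------------------------------------------
# contexts


@dataclass(frozen=True)
class ContextSpec:
    """Temporal context specification.

    ``network_context`` lists the prior-state offsets the network consumes,
    ascending (e.g. ``(-5, -4, -3, -2, -1)``); ``layer2_context`` is the
    sub-sampled subset spliced by Layer-2. ``layer1_context`` and
    ``layer3_context`` record the per-layer receptive structure for display.
    ``shallow`` selects the single-affine softmax variant.
    """

    name: str
    network_context: tuple[int, ...]
    layer1_context: tuple[int, ...]
    layer2_context: tuple[int, ...]
    layer3_context: tuple[int, ...] = (-1,)
    shallow: bool = False

    def __post_init__(self) -> None:
        for off in self.network_context + self.layer2_context:
            if off >= 0:
                raise DomainError(f"context offsets must be negative, got {off}")
        if tuple(sorted(self.network_context)) != self.network_context:
            raise DomainError("network_context must be sorted ascending")
        if not set(self.layer2_context) <= set(self.network_context):
            raise DomainError(
                f"layer2 context {self.layer2_context} not within "
                f"network context {self.network_context}"
            )
        if -1 not in self.layer3_context:
            raise DomainError("layer-3 context must include offset -1")

    @property
    def window(self) -> int:
        """Number of prior states consumed (window length K)."""
        return len(self.network_context)


def _rng_ctx(lo: int) -> tuple[int, ...]:
    return tuple(range(lo, 0))


#: The six published context variants (all the five-layer network, per the
#: layerwise-context table) plus "eq2", the literal single-affine softmax
#: model, and the default (= tdnn4 structure).
CONTEXT_PRESETS: dict[str, ContextSpec] = {
    "tdnn1": ContextSpec("tdnn1", (-1,), (-1,), (-1,)),
    "eq2": ContextSpec("eq2", (-1,), (-1,), (-1,), (-1,), shallow=True),
    "tdnn2": ContextSpec("tdnn2", (-2, -1), (-2, -1), (-1,)),
    "tdnn3": ContextSpec("tdnn3", _rng_ctx(-3), (-2, -1), (-2, -1)),
    "tdnn4": ContextSpec("tdnn4", _rng_ctx(-5), _rng_ctx(-3), (-3, -1)),
    "tdnn5": ContextSpec("tdnn5", _rng_ctx(-7), _rng_ctx(-3), (-5, -3, -1)),
    "tdnn6": ContextSpec("tdnn6", _rng_ctx(-9), _rng_ctx(-5), (-9, -5, -1)),
}

DEFAULT_CONTEXT = "tdnn4"


def context_preset(name: str) -> ContextSpec:
    key = name.lower().replace("-", "")
    if key not in CONTEXT_PRESETS:
        raise DomainError(
            f"unknown context preset {name!r}; choose from {sorted(CONTEXT_PRESETS)}"
        )
    return CONTEXT_PRESETS[key]


@dataclass(frozen=True)
class TrainConfig:
    """SGD hyperparameters.

    The ``refine_*`` fields control the recursive-consistency rounds run
    after the teacher-forced phase (see :func:`dtmn.model.fit_tdnn_stage`):
    each round re-decodes the training sequences with the current network,
    aggregates the self-generated context windows with the teacher-forced
    ones, and continues SGD at a decayed learning rate.
    """

    batch_size: int = 256
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 30
    seed: int = 0
    tie_break: str = "smallest"
    refine_rounds: int = 6
    refine_epochs: int = 8
    refine_lr: float = 0.005
    refine_lr_decay: float = 0.8

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise DomainError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise DomainError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise DomainError("epochs must be >= 1")
        if self.tie_break != "smallest":
            raise DomainError("only the 'smallest' tie-break rule is supported")
        if self.refine_rounds < 0 or self.refine_epochs < 0:
            raise DomainError("refinement rounds/epochs must be >= 0")


# ---------------------------------------------------------------------------
# primitive ops


def alpha_encode(q: int, N: int) -> np.ndarray:
    """Binary indicator encoding of a hidden state (1-based); the absent
    marker (pre-sequence boundary) encodes as the all-zero vector."""
    if q == ABSENT:
        return np.zeros(N)
    if not 1 <= q <= N:
        raise DomainError(f"hidden state {q} outside 1..{N}")
    v = np.zeros(N)
    v[q - 1] = 1.0
    return v


def _one_hot_windows(Q: np.ndarray, N: int) -> np.ndarray:
    """(B, K) int windows (0 = absent) -> (B, K, N) indicator stacks."""
    if np.any(Q < 0) or np.any(Q > N):
        bad = Q[(Q < 0) | (Q > N)].ravel()[0]
        raise DomainError(f"hidden state {bad} outside 0..{N}")
    B, K = Q.shape
    out = np.zeros((B, K, N))
    mask = Q > 0
    b, k = np.nonzero(mask)
    out[b, k, Q[mask] - 1] = 1.0
    return out


def _window_stack(Q: np.ndarray, N: int) -> np.ndarray:
    """Normalise context-window input to a (B, K, N) float stack.

    Accepts hard windows of 1-based state indices (B, K) — encoded one-hot
    with the all-zero vector for absent entries — or soft windows (B, K, N)
    of state distributions (e.g. fed-back posteriors), passed through.
    """
    Q = np.asarray(Q)
    if Q.ndim == 2:
        return _one_hot_windows(Q.astype(np.int64), N)
    if Q.ndim == 3:
        if Q.shape[2] != N:
            raise StructuralError(f"soft window depth {Q.shape[2]} != N={N}")
        return np.asarray(Q, dtype=np.float64)
    raise StructuralError(f"window array must be 2-D or 3-D, got ndim={Q.ndim}")


def softmax(Z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    Z = np.asarray(Z, dtype=np.float64)
    if not np.all(np.isfinite(Z)):
        raise DomainError("softmax input contains non-finite entries")
    Z = Z - Z.max(axis=-1, keepdims=True)
    e = np.exp(Z)
    return e / e.sum(axis=-1, keepdims=True)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _bn_forward(x, g, b, rm, rv, train: bool):
    """Batch norm over axis 0; updates running moments in place in train
    mode. Returns (out, cache)."""
    if train:
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        rm *= _BN_MOMENTUM
        rm += (1.0 - _BN_MOMENTUM) * mu
        rv *= _BN_MOMENTUM
        rv += (1.0 - _BN_MOMENTUM) * var
    else:
        mu, var = rm, rv
    invstd = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mu) * invstd
    return g * xhat + b, (xhat, invstd, g)


def _bn_backward(dout, cache):
    xhat, invstd, g = cache
    B = dout.shape[0]
    dg = (dout * xhat).sum(axis=0)
    db = dout.sum(axis=0)
    dxhat = dout * g
    dx = (invstd / B) * (
        B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
    )
    return dx, dg, db


# ---------------------------------------------------------------------------
# parameters


@dataclass
class TDNNParams:
    """All learnable weights, batch-norm statistics and shape metadata."""

    ctx: ContextSpec
    n_states: int
    feature_dim: int
    hidden_dim: int
    beta_dim: int
    arrays: dict[str, np.ndarray]
    loss_trace: list[float] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return self.n_states

    @classmethod
    def init(
        cls,
        ctx: ContextSpec,
        n_states: int,
        feature_dim: int,
        hidden_dim: int = 4000,
        beta_dim: Optional[int] = None,
        seed: int = 0,
    ) -> "TDNNParams":
        if n_states < 1:
            raise DomainError("need at least one hidden state class")
        if feature_dim < 1:
            raise DomainError("need feature_dim >= 1")
        N, D, H = n_states, feature_dim, hidden_dim
        db = feature_dim if beta_dim is None else beta_dim
        rng = np.random.default_rng(seed)

        def he(*shape):
            fan_in = shape[-1]
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        a: dict[str, np.ndarray] = {}
        # beta: near-identity affine feature transform
        Wb = np.zeros((db, D))
        Wb[: min(db, D), : min(db, D)] = np.eye(min(db, D))
        a["Wb"] = Wb + 0.01 * rng.normal(size=(db, D))
        a["bb"] = np.zeros(db)
        if ctx.shallow:
            a["Wq"] = he(N, N)
            a["Wf"] = he(N, db)
            a["b5"] = np.zeros(N)
        else:
            m = len(ctx.layer2_context)
            # layer-1 transform tied across temporal positions
            a["W1"] = rng.normal(0.0, np.sqrt(2.0 / N), size=(H, N))
            a["b1"] = np.zeros(H)
            a["g1"] = np.ones(H)
            a["be1"] = np.zeros(H)
            a["rm1"] = np.zeros(H)
            a["rv1"] = np.ones(H)
            a["W2"] = he(H, m * H)
            a["b2"] = np.zeros(H)
            a["g2"] = np.ones(H)
            a["be2"] = np.zeros(H)
            a["rm2"] = np.zeros(H)
            a["rv2"] = np.ones(H)
            a["W4"] = he(H, H + db)
            a["b4"] = np.zeros(H)
            a["g4"] = np.ones(H)
            a["be4"] = np.zeros(H)
            a["rm4"] = np.zeros(H)
            a["rv4"] = np.ones(H)
            a["W5"] = he(N, H)
            a["b5"] = np.zeros(N)
        return cls(
            ctx=ctx,
            n_states=N,
            feature_dim=D,
            hidden_dim=H,
            beta_dim=db,
            arrays=a,
        )

    def trainable_keys(self) -> list[str]:
        return [k for k in self.arrays if not k.startswith(("rm", "rv"))]

    def to_dict(self) -> dict:
        return {
            "context": {
                "name": self.ctx.name,
                "network_context": list(self.ctx.network_context),
                "layer1_context": list(self.ctx.layer1_context),
                "layer2_context": list(self.ctx.layer2_context),
                "layer3_context": list(self.ctx.layer3_context),
                "shallow": self.ctx.shallow,
            },
            "n_states": self.n_states,
            "feature_dim": self.feature_dim,
            "hidden_dim": self.hidden_dim,
            "beta_dim": self.beta_dim,
            "loss_trace": list(self.loss_trace),
            "arrays": {k: v.tolist() for k, v in self.arrays.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TDNNParams":
        c = d["context"]
        ctx = ContextSpec(
            name=c["name"],
            network_context=tuple(c["network_context"]),
            layer1_context=tuple(c["layer1_context"]),
            layer2_context=tuple(c["layer2_context"]),
            layer3_context=tuple(c["layer3_context"]),
            shallow=c["shallow"],
        )
        return cls(
            ctx=ctx,
            n_states=d["n_states"],
            feature_dim=d["feature_dim"],
            hidden_dim=d["hidden_dim"],
            beta_dim=d["beta_dim"],
            arrays={k: np.array(v, dtype=np.float64) for k, v in d["arrays"].items()},
            loss_trace=list(d.get("loss_trace", [])),
        )


# ---------------------------------------------------------------------------
# forward / backward


def _forward(params: TDNNParams, Q: np.ndarray, F: np.ndarray, train: bool):
    """Batched forward pass. Q: (B, K) int windows, F: (B, D).

    Returns (probs, cache); cache is None in infer mode.
    """
    a = params.arrays
    ctx = params.ctx
    if Q.shape[1] != ctx.window:
        raise StructuralError(
            f"window length {Q.shape[1]} != context size {ctx.window}"
        )
    if F.shape[1] != params.feature_dim:
        raise StructuralError(
            f"feature dim {F.shape[1]} != model dim {params.feature_dim}"
        )
    A1 = _window_stack(Q, params.n_states)  # (B, K, N)
    bf = F @ a["Wb"].T + a["bb"]  # (B, db)
    if ctx.shallow:
        Z = A1[:, -1, :] @ a["Wq"].T + bf @ a["Wf"].T + a["b5"]
        P = softmax(Z)
        cache = (A1, bf, F) if train else None
        return P, cache

    B, K = A1.shape[:2]
    # tied position-wise transform: positions fold into the batch axis for
    # the affine and for the batch-norm statistics
    z1 = (A1.reshape(B * K, -1) @ a["W1"].T + a["b1"])
    z1n, c1 = _bn_forward(z1, a["g1"], a["be1"], a["rm1"], a["rv1"], train)
    h1 = _relu(z1n).reshape(B, K, -1)
    sel = [ctx.network_context.index(o) for o in ctx.layer2_context]
    x2 = h1[:, sel, :].reshape(B, -1)
    z2 = x2 @ a["W2"].T + a["b2"]
    z2n, c2 = _bn_forward(z2, a["g2"], a["be2"], a["rm2"], a["rv2"], train)
    h2 = _relu(z2n)
    x3 = np.concatenate([h2, bf], axis=1)
    z4 = x3 @ a["W4"].T + a["b4"]
    z4n, c4 = _bn_forward(z4, a["g4"], a["be4"], a["rm4"], a["rv4"], train)
    h4 = _relu(z4n)
    Z = h4 @ a["W5"].T + a["b5"]
    P = softmax(Z)
    cache = (A1, bf, h1, z1n, c1, sel, x2, z2n, c2, h2, x3, z4n, c4, h4, P, F)
    return P, (cache if train else None)


def _backward(params: TDNNParams, dZ: np.ndarray, cache) -> dict[str, np.ndarray]:
    a = params.arrays
    g: dict[str, np.ndarray] = {}
    if params.ctx.shallow:
        A1, bf, F = cache
        g["Wq"] = dZ.T @ A1[:, -1, :]
        g["Wf"] = dZ.T @ bf
        g["b5"] = dZ.sum(axis=0)
        dbf = dZ @ a["Wf"]
    else:
        (A1, bf, h1, z1n, c1, sel, x2, z2n, c2, h2, x3, z4n, c4, h4, _, F) = cache
        g["W5"] = dZ.T @ h4
        g["b5"] = dZ.sum(axis=0)
        dh4 = dZ @ a["W5"]
        dz4n = dh4 * (z4n > 0)
        dz4, g["g4"], g["be4"] = _bn_backward(dz4n, c4)
        g["W4"] = dz4.T @ x3
        g["b4"] = dz4.sum(axis=0)
        dx3 = dz4 @ a["W4"]
        H = h2.shape[1]
        dh2 = dx3[:, :H]
        dbf = dx3[:, H:]
        dz2n = dh2 * (z2n > 0)
        dz2, g["g2"], g["be2"] = _bn_backward(dz2n, c2)
        g["W2"] = dz2.T @ x2
        g["b2"] = dz2.sum(axis=0)
        dx2 = dz2 @ a["W2"]
        B, K, Hh = h1.shape
        dh1 = np.zeros_like(h1)
        dx2 = dx2.reshape(B, len(sel), Hh)
        for j, k in enumerate(sel):
            dh1[:, k, :] += dx2[:, j, :]
        dz1n = dh1.reshape(B * K, Hh) * (z1n > 0)
        dz1, g["g1"], g["be1"] = _bn_backward(dz1n, c1)
        g["W1"] = dz1.T @ A1.reshape(B * K, -1)
        g["b1"] = dz1.sum(axis=0)
        F = cache[-1]
    g["Wb"] = dbf.T @ F
    g["bb"] = dbf.sum(axis=0)
    return g


def tdnn_forward(
    params: TDNNParams,
    q_window: Sequence[int],
    f_t: np.ndarray,
    mode: str = "infer",
) -> np.ndarray:
    """Probability distribution over present hidden states for one example.

    ``q_window`` lists the prior states by ascending offset (oldest first,
    ``q_{t-1}`` last); ``ABSENT`` (0) marks pre-sequence positions. In infer
    mode batch-norm uses the frozen running moments.
    """
    Q = np.asarray(q_window, dtype=np.int64)[None, :]
    F = np.asarray(f_t, dtype=np.float64)[None, :]
    P, _ = _forward(params, Q, F, train=(mode == "train"))
    return P[0]


def tdnn_forward_batch(params: TDNNParams, Q: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Vectorised infer-mode forward over a batch of examples; ``Q`` may be
    hard (B, K) index windows or soft (B, K, N) distribution stacks."""
    P, _ = _forward(params, np.asarray(Q), np.asarray(F, dtype=np.float64),
                    train=False)
    return P


def sgd_epochs(
    params: TDNNParams,
    examples: tuple[np.ndarray, np.ndarray, np.ndarray],
    cfg: TrainConfig,
    epochs: Optional[int] = None,
    learning_rate: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> TDNNParams:
    """Run mini-batch SGD epochs on ``params`` in place.

    ``examples`` is ``(Q, F, targets)``; ``Q`` is either hard (n, K) index
    windows or soft (n, K, N) stacks. Appends per-epoch mean losses to
    ``params.loss_trace`` and returns ``params``.
    """
    Q, F, tgt = examples
    Q = np.asarray(Q)
    F = np.asarray(F, dtype=np.float64)
    tgt = np.asarray(tgt, dtype=np.int64)
    n = Q.shape[0]
    if n == 0:
        raise DomainError("no training examples")
    if np.any(tgt < 1) or np.any(tgt > params.n_classes):
        raise DomainError(f"targets must lie in 1..{params.n_classes}")
    epochs = cfg.epochs if epochs is None else epochs
    lr = cfg.learning_rate if learning_rate is None else learning_rate
    rng = rng or np.random.default_rng(cfg.seed + 1)
    vel = {k: np.zeros_like(params.arrays[k]) for k in params.trainable_keys()}
    t0 = tgt - 1
    for _ in range(epochs):
        perm = rng.permutation(n)
        total, count = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            qb, fb, tb = Q[idx], F[idx], t0[idx]
            P, cache = _forward(params, qb, fb, train=True)
            B = len(idx)
            p_true = np.maximum(P[np.arange(B), tb], 1e-300)
            total += -float(np.sum(np.log(p_true)))
            count += B
            dZ = P.copy()
            dZ[np.arange(B), tb] -= 1.0
            dZ /= B
            grads = _backward(params, dZ, cache)
            for k, gr in grads.items():
                v = vel[k]
                v *= cfg.momentum
                v -= lr * gr
                params.arrays[k] += v
        params.loss_trace.append(total / count)
    return params


def train_tdnn(
    examples: tuple[np.ndarray, np.ndarray, np.ndarray],
    ctx: ContextSpec,
    cfg: TrainConfig,
    n_states: int,
    hidden_dim: int = 4000,
    beta_dim: Optional[int] = None,
) -> TDNNParams:
    """Fit the network by mini-batch SGD on the mean cross-entropy.

    ``examples`` is ``(Q, F, targets)`` with ``Q`` of shape (n, K) holding
    prior-state windows (0 = absent), ``F`` the (n, D) feature rows and
    ``targets`` the 1-based present states. The per-epoch mean loss trace is
    stored on the returned parameters.
    """
    Q, F, tgt = examples
    Q = np.asarray(Q)
    F = np.asarray(F, dtype=np.float64)
    if Q.shape[0] == 0:
        raise DomainError("no training examples")
    if Q.shape[1] != ctx.window:
        raise StructuralError(
            f"window length {Q.shape[1]} != context size {ctx.window}"
        )
    params = TDNNParams.init(
        ctx, n_states, F.shape[1], hidden_dim=hidden_dim, beta_dim=beta_dim,
        seed=cfg.seed,
    )
    return sgd_epochs(params, (Q, F, tgt), cfg)
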