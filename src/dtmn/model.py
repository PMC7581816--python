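"""The deep time-delay Markov network: model and results objects.

Training runs in two phases. Phase one fits a categorical-emission HMM to
the label sequences by Baum-Welch and posterior-decodes a hidden-state path
for every step. Phase two trains the TDNN to predict each step's decoded
hidden state from the window of prior decoded states plus the step's feature
vector; recursive-consistency rounds then re-decode the training sequences
with the current network and continue SGD on the self-generated context
windows, so the network also learns to act on its own (uncertain) feedback.
Prediction reverses the pipeline: the TDNN is rolled forward over an
unlabeled feature sequence, feeding back its own argmax state into the
context window (optionally the full posterior, ``feedback="soft"``), and
the label posterior at each step is the emission-weighted mixture

    P(y_t = i | f) = sum_j E[j, i] P(q_t = j | f)

with the TDNN softmax output standing in for P(q_t = j | f); the fed-back
value is hard, the Eq.-style label mixture always uses the soft posterior.

Usage follows the statsmodels convention::

    model = DTMN(train_set, n_hidden=10, context="tdnn4", hidden_dim=64)
    res = model.fit(seed=0)          # -> DTMNResults
    pred = res.predict(features)     # -> PredictionResult
    report = res.evaluate(test_set)  # -> EvalReport
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from . import hmm as hmm_mod
from .data import ABSENT, EmotionAlphabet, LabeledSequence, SequenceSet
from .exceptions import DomainError, StructuralError
from .tdnn import (
    ContextSpec,
    TDNNParams,
    TrainConfig,
    _window_stack,
    context_preset,
    sgd_epochs,
    tdnn_forward_batch,
    train_tdnn,
)

FORMAT_VERSION = 1


@dataclass
class PredictionResult:
    """Per-step outputs of the recursive decoder for one sequence."""

    labels: np.ndarray            # (T,) 1-based predicted labels
    label_posterior: np.ndarray   # (T, L)
    hidden_path: np.ndarray       # (T,) 1-based fed-back states
    hidden_posterior: np.ndarray  # (T, N)

    def __post_init__(self) -> None:
        # Eq.-level conservation: posteriors are distributions and the
        # reported argmaxes match them (smallest index on ties).
        assert np.allclose(self.hidden_posterior.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(self.label_posterior.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(self.labels, np.argmax(self.label_posterior, axis=1) + 1)


@dataclass
class HMMStage:
    """Phase-one artifacts: the fitted HMM and the decoded hidden targets."""

    hmm: hmm_mod.HMMParams
    loglik_trace: list[float]
    hidden_paths: dict[str, np.ndarray]
    alphabet: EmotionAlphabet
    seed: int


def _require_labeled(data: SequenceSet) -> None:
    if len(data) == 0:
        raise DomainError("need at least one training sequence")
    for s in data:
        bad = np.flatnonzero(s.y == ABSENT)
        if bad.size:
            raise DomainError(
                f"sequence {s.id!r} has an unlabeled step at t={int(bad[0]) + 1}"
            )


def fit_hmm_stage(
    data: SequenceSet,
    n_hidden: int = 80,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
    refine: bool = True,
) -> HMMStage:
    """Baum-Welch over the label sequences, then posterior-decode a hidden
    path per sequence (the TDNN's training targets).

    By default the EM fit is followed by segmental refinement
    (:func:`dtmn.hmm.segmental_refine`), which makes the emission rows
    consistent with the decoded hard paths and splits label-mixed states;
    with an over-complete state count this keeps the decoded targets
    label-informative even when the label sequences carry little temporal
    structure.
    """
    _require_labeled(data)
    params0 = hmm_mod.init_random(n_hidden, data.alphabet.size, seed=seed)
    params, trace = hmm_mod.baum_welch(
        params0, data.label_sequences(), max_iter=max_iter, tol=tol
    )
    if refine:
        params = hmm_mod.segmental_refine(params, data.label_sequences())
    paths = {s.id: hmm_mod.posterior_decode(params, s.y) for s in data}
    return HMMStage(
        hmm=params, loglik_trace=trace, hidden_paths=paths,
        alphabet=data.alphabet, seed=seed,
    )


def _window_matrix(path: np.ndarray, offsets: tuple[int, ...]) -> np.ndarray:
    """(T, K) windows of prior states along ``path`` with 0 (absent) padding
    before the sequence start. offsets ascend, e.g. (-5, ..., -1)."""
    T = path.shape[0]
    W = np.zeros((T, len(offsets)), dtype=np.int64)
    t = np.arange(T)
    for k, off in enumerate(offsets):
        src = t + off
        ok = src >= 0
        W[ok, k] = path[src[ok]]
    return W


def make_training_examples(
    data: SequenceSet, stage: HMMStage, ctx: ContextSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack (prior-state window, feature, target state) triples over all
    sequences; windows never cross sequence boundaries."""
    Qs, Fs, Ts = [], [], []
    for s in data:
        path = stage.hidden_paths[s.id]
        Qs.append(_window_matrix(path, ctx.network_context))
        Fs.append(s.f)
        Ts.append(path)
    return np.concatenate(Qs), np.concatenate(Fs), np.concatenate(Ts)


def _decode(
    params: TDNNParams,
    ctx: ContextSpec,
    feature_seqs: list[np.ndarray],
    feedback: str = "hard",
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Free-running recursive decode.

    At each step the network sees the fed-back representation of its own
    prior decisions: with ``feedback="hard"`` the one-hot argmax state (ties
    toward the smaller index), with ``"soft"`` the full posterior. Returns
    per-sequence context-window stacks (T, K, N) and hidden-state posteriors
    (T, N); time steps are batched across sequences.
    """
    if feedback not in ("hard", "soft"):
        raise DomainError(f"unknown feedback mode {feedback!r}")
    offsets = np.asarray(ctx.network_context)
    K = len(offsets)
    N = params.n_classes
    lengths = [f.shape[0] for f in feature_seqs]
    hist = [np.zeros((T, N)) for T in lengths]
    fed = [np.zeros((T, N)) for T in lengths]
    wins = [np.zeros((T, K, N)) for T in lengths]
    for t in range(max(lengths)):
        active = [i for i, T in enumerate(lengths) if t < T]
        A1 = np.zeros((len(active), K, N))
        F = np.empty((len(active), params.feature_dim))
        src = t + offsets
        ok = src >= 0
        for row, i in enumerate(active):
            A1[row, ok] = fed[i][src[ok]]
            F[row] = feature_seqs[i][t]
        P = tdnn_forward_batch(params, A1, F)
        for row, i in enumerate(active):
            hist[i][t] = P[row]
            wins[i][t] = A1[row]
            if feedback == "hard":
                fed[i][t, int(np.argmax(P[row]))] = 1.0
            else:
                fed[i][t] = P[row]
    return wins, hist


def fit_tdnn_stage(
    data: SequenceSet,
    stage: HMMStage,
    ctx: ContextSpec,
    cfg: TrainConfig,
    hidden_dim: int = 4000,
    beta_dim: Optional[int] = None,
    feedback: str = "hard",
) -> TDNNParams:
    """Phase two: teacher-forced SGD on the decoded hidden targets, then
    recursive-consistency refinement.

    Each refinement round free-runs the decoder over the training sequences
    (same feedback mode as prediction), aggregates the self-generated
    context windows with the teacher-forced ones (targets unchanged), and
    continues SGD at a learning rate decayed per round. This closes the gap
    between the teacher-forced contexts seen in training and the imperfect
    fed-back decisions seen at prediction time, which otherwise compound.
    """
    Q, F, tgt = make_training_examples(data, stage, ctx)
    params = train_tdnn(
        (Q, F, tgt), ctx, cfg, n_states=stage.hmm.N,
        hidden_dim=hidden_dim, beta_dim=beta_dim,
    )
    if cfg.refine_rounds > 0 and cfg.refine_epochs > 0:
        feature_seqs = [s.f for s in data]
        agg_W = [_window_stack(Q, stage.hmm.N)]
        rng = np.random.default_rng(cfg.seed + 2)
        for r in range(cfg.refine_rounds):
            wins, _ = _decode(params, ctx, feature_seqs, feedback=feedback)
            agg_W.append(np.concatenate(wins))
            k = len(agg_W)
            sgd_epochs(
                params,
                (np.concatenate(agg_W), np.tile(F, (k, 1)), np.tile(tgt, k)),
                cfg,
                epochs=cfg.refine_epochs,
                learning_rate=cfg.refine_lr * cfg.refine_lr_decay**r,
                rng=rng,
            )
    return params


class DTMN:
    """Deep time-delay Markov network bound to a fully labeled training set.

    Parameters
    ----------
    data : SequenceSet
        Fully labeled training sequences.
    n_hidden : int
        Number of HMM hidden states (published setting: 80).
    context : str or ContextSpec
        TDNN temporal-context preset (``tdnn1``..``tdnn6``) or an explicit
        spec; the default ``tdnn4`` is the published layer structure.
    hidden_dim : int
        Width of the TDNN hidden layers (published setting: 4000).
    """

    def __init__(
        self,
        data: SequenceSet,
        n_hidden: int = 80,
        context: Union[str, ContextSpec] = "tdnn4",
        hidden_dim: int = 4000,
        beta_dim: Optional[int] = None,
        hmm_max_iter: int = 100,
        hmm_tol: float = 1e-4,
        train_config: Optional[TrainConfig] = None,
        feedback: str = "hard",
    ) -> None:
        _require_labeled(data)
        if feedback not in ("hard", "soft"):
            raise DomainError(f"unknown feedback mode {feedback!r}")
        self.data = data
        self.n_hidden = int(n_hidden)
        self.ctx = context_preset(context) if isinstance(context, str) else context
        self.hidden_dim = int(hidden_dim)
        self.beta_dim = beta_dim
        self.hmm_max_iter = int(hmm_max_iter)
        self.hmm_tol = float(hmm_tol)
        self.train_config = train_config or TrainConfig()
        self.feedback = feedback

    def fit(self, seed: int = 0) -> "DTMNResults":
        """Run both training phases; ``seed`` controls HMM initialisation and
        the TDNN's initialisation/shuffling (overriding ``train_config.seed``)."""
        stage = fit_hmm_stage(
            self.data, self.n_hidden, self.hmm_max_iter, self.hmm_tol, seed=seed
        )
        cfg = replace(self.train_config, seed=seed)
        tdnn = fit_tdnn_stage(
            self.data, stage, self.ctx, cfg, self.hidden_dim, self.beta_dim,
            feedback=self.feedback,
        )
        return DTMNResults(
            hmm=stage.hmm,
            tdnn=tdnn,
            ctx=self.ctx,
            alphabet=self.data.alphabet,
            loglik_trace=stage.loglik_trace,
            seed=seed,
            feedback=self.feedback,
            config={
                "n_hidden": self.n_hidden,
                "hidden_dim": self.hidden_dim,
                "beta_dim": self.beta_dim,
                "hmm_max_iter": self.hmm_max_iter,
                "hmm_tol": self.hmm_tol,
                "context": self.ctx.name,
                "train_config": {
                    "batch_size": cfg.batch_size,
                    "learning_rate": cfg.learning_rate,
                    "momentum": cfg.momentum,
                    "epochs": cfg.epochs,
                    "seed": cfg.seed,
                    "tie_break": cfg.tie_break,
                },
            },
        )


@dataclass
class DTMNResults:
    """Fitted DTMN: bundled HMM + TDNN with training diagnostics."""

    hmm: hmm_mod.HMMParams
    tdnn: TDNNParams
    ctx: ContextSpec
    alphabet: EmotionAlphabet
    loglik_trace: list[float]
    seed: int
    feedback: str = "hard"
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tdnn.n_classes != self.hmm.N:
            raise StructuralError(
                f"TDNN classes ({self.tdnn.n_classes}) != HMM states ({self.hmm.N})"
            )
        if self.alphabet.size != self.hmm.L:
            raise StructuralError(
                f"alphabet size ({self.alphabet.size}) != HMM labels ({self.hmm.L})"
            )

    # -- prediction ---------------------------------------------------------

    def predict(self, features: np.ndarray) -> PredictionResult:
        """Recursive decoding of one unlabeled feature sequence (T, D)."""
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if features.shape[0] == 0:
            raise DomainError("empty feature sequence")
        return self.predict_many([features])[0]

    def predict_many(self, feature_seqs: list[np.ndarray]) -> list[PredictionResult]:
        """Recursive decoding of several sequences, batched per time step."""
        if not feature_seqs:
            return []
        seqs = [np.atleast_2d(np.asarray(f, dtype=np.float64)) for f in feature_seqs]
        for f in seqs:
            if f.shape[0] == 0:
                raise DomainError("empty feature sequence")
            if f.shape[1] != self.tdnn.feature_dim:
                raise StructuralError(
                    f"feature dim {f.shape[1]} != model dim {self.tdnn.feature_dim}"
                )
        _, hidden_post = _decode(self.tdnn, self.ctx, seqs, feedback=self.feedback)
        out = []
        for hp in hidden_post:
            lp = hp @ self.hmm.E  # (T, L); rows stay normalised
            out.append(
                PredictionResult(
                    labels=np.argmax(lp, axis=1) + 1,
                    label_posterior=lp,
                    hidden_path=np.argmax(hp, axis=1) + 1,
                    hidden_posterior=hp,
                )
            )
        return out

    def predict_set(self, data: SequenceSet) -> dict[str, "PredictionResult"]:
        preds = self.predict_many([s.f for s in data])
        return {s.id: p for s, p in zip(data, preds)}

    def evaluate(self, data: SequenceSet):
        """PER and confusion on a fully labeled evaluation set; see
        :func:`dtmn.evaluate.evaluate_model`."""
        from .evaluate import evaluate_model

        return evaluate_model(self, data)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Deep Time-delay Markov Network",
            "=" * 46,
            f"{'hidden states (N)':<28}{self.hmm.N}",
            f"{'label alphabet (L)':<28}{self.hmm.L}",
            f"{'feature dim (D)':<28}{self.tdnn.feature_dim}",
            f"{'context preset':<28}{self.ctx.name}",
            f"{'network context':<28}{list(self.ctx.network_context)}",
            f"{'hidden width (H)':<28}{self.tdnn.hidden_dim}",
            f"{'seed':<28}{self.seed}",
            "-" * 46,
            f"{'Baum-Welch iterations':<28}{len(self.loglik_trace)}",
            f"{'final log-likelihood':<28}{self.loglik_trace[-1]:.4f}",
        ]
        if self.tdnn.loss_trace:
            lines += [
                f"{'TDNN epochs':<28}{len(self.tdnn.loss_trace)}",
                f"{'final TDNN loss':<28}{self.tdnn.loss_trace[-1]:.4f}",
            ]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "kind": "dtmn_model",
            "alphabet": list(self.alphabet.labels),
            "seed": self.seed,
            "feedback": self.feedback,
            "config": self.config,
            "loglik_trace": list(self.loglik_trace),
            "hmm": self.hmm.to_dict(),
            "tdnn": self.tdnn.to_dict(),
        }

    def save(self, path) -> str:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)
        return str(path)

    @classmethod
    def from_dict(cls, d: dict) -> "DTMNResults":
        if d.get("kind") != "dtmn_model":
            raise StructuralError("not a DTMN model file")
        if d.get("format_version") != FORMAT_VERSION:
            raise StructuralError(
                f"unsupported model format version {d.get('format_version')}"
            )
        tdnn = TDNNParams.from_dict(d["tdnn"])
        return cls(
            hmm=hmm_mod.HMMParams.from_dict(d["hmm"]),
            tdnn=tdnn,
            ctx=tdnn.ctx,
            alphabet=EmotionAlphabet(tuple(d["alphabet"])),
            loglik_trace=list(d["loglik_trace"]),
            seed=d["seed"],
            feedback=d.get("feedback", "hard"),
            config=d.get("config", {}),
        )

    @classmethod
    def load(cls, path) -> "DTMNResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# functional surface


def train_dtmn(
    data: SequenceSet,
    n_hidden: int = 80,
    ctx: Union[str, ContextSpec] = "tdnn4",
    hmm_cfg: Optional[dict] = None,
    tdnn_cfg: Optional[TrainConfig] = None,
    hidden_dim: int = 4000,
    seed: int = 0,
) -> DTMNResults:
    """Two-phase training; thin functional wrapper over :class:`DTMN`."""
    hmm_cfg = hmm_cfg or {}
    model = DTMN(
        data,
        n_hidden=n_hidden,
        context=ctx,
        hidden_dim=hidden_dim,
        hmm_max_iter=hmm_cfg.get("max_iter", 100),
        hmm_tol=hmm_cfg.get("tol", 1e-4),
        train_config=tdnn_cfg,
    )
    return model.fit(seed=seed)


def predict_labels(model: DTMNResults, features: np.ndarray) -> PredictionResult:
    """Recursive label prediction for one unlabeled feature sequence."""
    return model.predict(features)
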