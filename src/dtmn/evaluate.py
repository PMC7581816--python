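"""Metrics, the memoryless comparator, and the two ablation sweeps.

The prediction error rate (PER) is the percentage of time steps whose
predicted emotion label differs from the true label, pooled over all
evaluated steps (micro-average). The memoryless baseline is a single
softmax layer on the present feature vector, trained with the same SGD
machinery as the TDNN but blind to all temporal context — it isolates how
much of the network's accuracy comes from the prior-state window.
"""

from __future__ import annotations

import hashlib
import json
import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .data import ABSENT, SequenceSet, train_test_split
from .exceptions import DomainError, StructuralError
from .tdnn import ContextSpec, TDNNParams, TrainConfig, tdnn_forward_batch, train_tdnn

# ---------------------------------------------------------------------------
# metrics


def _pool(y) -> np.ndarray:
    if isinstance(y, np.ndarray) and y.ndim == 1:
        return y.astype(np.int64)
    if len(y) and np.isscalar(y[0]):
        return np.asarray(y, dtype=np.int64)
    return np.concatenate([np.asarray(s, dtype=np.int64) for s in y])


def per(y_true, y_pred) -> float:
    """Prediction error rate in percent, pooled over steps.

    Accepts single sequences or lists of sequences; corresponding sequences
    must align stepwise.
    """
    if not (isinstance(y_true, np.ndarray) and y_true.ndim == 1) and len(y_true) and not np.isscalar(y_true[0]):
        if len(y_true) != len(y_pred):
            raise StructuralError(
                f"{len(y_true)} true sequences vs {len(y_pred)} predicted"
            )
        for i, (a, b) in enumerate(zip(y_true, y_pred)):
            if len(a) != len(b):
                raise StructuralError(f"sequence {i}: length {len(a)} vs {len(b)}")
    t, p = _pool(y_true), _pool(y_pred)
    if t.shape != p.shape:
        raise StructuralError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise DomainError("no steps to evaluate")
    return float(100.0 * np.mean(t != p))


def confusion(y_true, y_pred, n_labels: int) -> np.ndarray:
    """(L, L) count matrix, rows = true label, columns = predicted."""
    t, p = _pool(y_true) - 1, _pool(y_pred) - 1
    if t.shape != p.shape:
        raise StructuralError("length mismatch")
    C = np.zeros((n_labels, n_labels), dtype=np.int64)
    np.add.at(C, (t, p), 1)
    return C


def per_from_confusion(C: np.ndarray) -> float:
    total = C.sum()
    return float(100.0 * (total - np.trace(C)) / total)


@dataclass
class EvalReport:
    """Pooled PER, the confusion matrix, per-sequence PERs and run metadata."""

    per: float
    confusion: np.ndarray
    per_sequence: dict[str, float]
    n_steps: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.per <= 100.0:
            raise DomainError("PER outside [0, 100]")
        if int(self.confusion.sum()) != self.n_steps:
            raise StructuralError("confusion totals != evaluated steps")

    def to_dict(self) -> dict:
        return {
            "per": self.per,
            "confusion": self.confusion.tolist(),
            "per_sequence": self.per_sequence,
            "n_steps": self.n_steps,
            "metadata": self.metadata,
        }


def evaluate_model(results, data: SequenceSet) -> EvalReport:
    """Run the recursive decoder on every sequence of a fully labeled set and
    score it. ``results`` is a :class:`dtmn.model.DTMNResults`."""
    for s in data:
        if not s.fully_labeled:
            raise DomainError(f"sequence {s.id!r} is not fully labeled")
    preds = results.predict_set(data)
    y_true = [s.y for s in data]
    y_pred = [preds[s.id].labels for s in data]
    C = confusion(y_true, y_pred, data.alphabet.size)
    model_hash = hashlib.md5(
        json.dumps(results.to_dict(), sort_keys=True).encode()
    ).hexdigest()
    return EvalReport(
        per=per(y_true, y_pred),
        confusion=C,
        per_sequence={s.id: per(s.y, preds[s.id].labels) for s in data},
        n_steps=int(C.sum()),
        metadata={
            "seed": results.seed,
            "config": results.config,
            "model_hash": model_hash,
        },
    )


# ---------------------------------------------------------------------------
# memoryless baseline

_BASELINE_CTX = ContextSpec("baseline", (-1,), (-1,), (-1,), shallow=True)


@dataclass
class MemorylessBaseline:
    """Softmax-on-features classifier; ignores all temporal context."""

    params: TDNNParams
    n_labels: int

    def posterior(self, features: np.ndarray) -> np.ndarray:
        F = np.atleast_2d(np.asarray(features, dtype=np.float64))
        Q = np.zeros((F.shape[0], 1), dtype=np.int64)  # no prior-state input
        return tdnn_forward_batch(self.params, Q, F)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.argmax(self.posterior(features), axis=1) + 1

    def evaluate(self, data: SequenceSet) -> EvalReport:
        y_true = [s.y for s in data]
        y_pred = [self.predict(s.f) for s in data]
        C = confusion(y_true, y_pred, data.alphabet.size)
        return EvalReport(
            per=per(y_true, y_pred),
            confusion=C,
            per_sequence={
                s.id: per(s.y, p) for s, p in zip(data, y_pred)
            },
            n_steps=int(C.sum()),
            metadata={"model": "memoryless_baseline"},
        )


def train_memoryless_baseline(
    data: SequenceSet, cfg: Optional[TrainConfig] = None
) -> MemorylessBaseline:
    """Fit the feature-only softmax classifier with the shared SGD trainer.

    Implemented as the shallow network with an all-absent state window, so
    the state-weight path contributes nothing and only ``W_f beta(f_t) + b``
    drives the logits; classes are the labels themselves.
    """
    cfg = cfg or TrainConfig()
    L = data.alphabet.size
    F = np.concatenate([s.f for s in data])
    y = np.concatenate([s.y for s in data])
    if np.any(y == ABSENT):
        raise DomainError("baseline training requires fully labeled data")
    Q = np.zeros((F.shape[0], 1), dtype=np.int64)
    params = train_tdnn((Q, F, y), _BASELINE_CTX, cfg, n_states=L,
                        hidden_dim=0)
    return MemorylessBaseline(params=params, n_labels=L)


# ---------------------------------------------------------------------------
# ablations


@dataclass
class AblationResult:
    """One record per swept setting, each holding the PER of every repeat."""

    mode: str
    records: list[dict]
    repeats: int
    seed: int

    def __post_init__(self) -> None:
        for r in self.records:
            for v in r["pers"]:
                if not 0.0 <= v <= 100.0:
                    raise DomainError("PER outside [0, 100]")

    def to_table(self) -> str:
        lines = ["setting\tmean_per\tstd_per\tpers"]
        for r in self.records:
            std = float(np.std(r["pers"])) if len(r["pers"]) > 1 else 0.0
            lines.append(
                f"{r['setting']}\t{r['mean_per']:.4f}\t{std:.4f}\t"
                + ",".join(f"{v:.4f}" for v in r["pers"])
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "repeats": self.repeats,
            "seed": self.seed,
            "records": self.records,
        }


def _split(data, eval_data, seed, holdout=0.2):
    if eval_data is not None:
        return data, eval_data
    return train_test_split(data, test_fraction=holdout, seed=seed)


def ablate_hidden_states(
    data: SequenceSet,
    Ns: Sequence[int],
    repeats: int = 5,
    seed: int = 0,
    eval_data: Optional[SequenceSet] = None,
    context: str = "tdnn4",
    hidden_dim: int = 64,
    train_config: Optional[TrainConfig] = None,
    hmm_max_iter: int = 100,
) -> AblationResult:
    """Sweep the HMM hidden-state count, training a full DTMN per setting and
    repeat (seeds ``seed..seed+repeats-1``). Uses the desk-scale hidden width
    by default."""
    from .model import DTMN

    if not Ns:
        raise DomainError("Ns must be nonempty")
    if repeats < 1:
        raise DomainError("repeats must be >= 1")
    train, test = _split(data, eval_data, seed)
    records = []
    for N in Ns:
        pers, lls = [], []
        for r in range(repeats):
            s = seed + r
            try:
                res = DTMN(
                    train, n_hidden=N, context=context, hidden_dim=hidden_dim,
                    hmm_max_iter=hmm_max_iter, train_config=train_config,
                ).fit(seed=s)
                pers.append(res.evaluate(test).per)
                lls.append(res.loglik_trace[-1])
            except Exception as exc:
                raise RuntimeError(
                    f"ablation run failed at n_hidden={N}, seed={s}: {exc}"
                ) from exc
        records.append(
            {
                "setting": N,
                "pers": pers,
                "mean_per": float(np.mean(pers)),
                "final_logliks": lls,
            }
        )
    return AblationResult(
        mode="hidden-states", records=records, repeats=repeats, seed=seed
    )


def ablate_contexts(
    data: SequenceSet,
    variants: Sequence[str],
    repeats: int = 5,
    seed: int = 0,
    eval_data: Optional[SequenceSet] = None,
    n_hidden: int = 10,
    hidden_dim: int = 64,
    train_config: Optional[TrainConfig] = None,
    hmm_max_iter: int = 100,
) -> AblationResult:
    """Sweep the TDNN context presets with the HMM stage shared within each
    repeat, isolating the temporal-context factor."""
    from dataclasses import replace as _replace

    from .model import DTMNResults, fit_hmm_stage, fit_tdnn_stage
    from .tdnn import context_preset

    ctxs = {v: context_preset(v) for v in variants}  # validates names
    if repeats < 1:
        raise DomainError("repeats must be >= 1")
    train, test = _split(data, eval_data, seed)
    cfg0 = train_config or TrainConfig()
    pers_by_variant: dict[str, list[float]] = {v: [] for v in variants}
    for r in range(repeats):
        s = seed + r
        stage = fit_hmm_stage(train, n_hidden=n_hidden, max_iter=hmm_max_iter, seed=s)
        for v in variants:
            cfg = _replace(cfg0, seed=s)
            tdnn = fit_tdnn_stage(train, stage, ctxs[v], cfg, hidden_dim=hidden_dim)
            res = DTMNResults(
                hmm=stage.hmm, tdnn=tdnn, ctx=ctxs[v],
                alphabet=train.alphabet, loglik_trace=stage.loglik_trace,
                seed=s, config={"n_hidden": n_hidden, "context": ctxs[v].name},
            )
            pers_by_variant[v].append(res.evaluate(test).per)
    records = [
        {
            "setting": v,
            "pers": pers_by_variant[v],
            "mean_per": float(np.mean(pers_by_variant[v])),
            "median_per": float(statistics.median(pers_by_variant[v])),
        }
        for v in variants
    ]
    return AblationResult(
        mode="contexts", records=records, repeats=repeats, seed=seed
    )


# ---------------------------------------------------------------------------
# paired comparisons on the synthetic study conditions


def dtmn_vs_baseline(
    preset_name: str,
    n_seeds: int = 5,
    seed: int = 0,
    n_hidden: int = 10,
    hidden_dim: int = 64,
    train_config: Optional[TrainConfig] = None,
    hmm_max_iter: int = 100,
) -> dict:
    """Paired DTMN / memoryless-baseline PERs over fresh datasets.

    For each of ``n_seeds`` seeds a new dataset is generated from the named
    preset, split 80/20 by sequence, and both models are trained on the same
    training fold and scored on the same test fold. Returns per-seed PERs and
    the medians.
    """
    from .model import DTMN
    from .simulate import generate, preset

    dtmn_pers, base_pers = [], []
    for k in range(n_seeds):
        s = seed + k
        data, _ = generate(preset(preset_name, seed=s))
        train, test = train_test_split(data, test_fraction=0.2, seed=s)
        res = DTMN(
            train, n_hidden=n_hidden, context="tdnn4", hidden_dim=hidden_dim,
            hmm_max_iter=hmm_max_iter, train_config=train_config,
        ).fit(seed=s)
        dtmn_pers.append(res.evaluate(test).per)
        from dataclasses import replace as _replace

        cfg = _replace(train_config or TrainConfig(), seed=s)
        base = train_memoryless_baseline(train, cfg)
        base_pers.append(base.evaluate(test).per)
    return {
        "preset": preset_name,
        "dtmn_pers": dtmn_pers,
        "baseline_pers": base_pers,
        "median_dtmn": float(statistics.median(dtmn_pers)),
        "median_baseline": float(statistics.median(base_pers)),
    }
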