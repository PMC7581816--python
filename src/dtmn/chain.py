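"""Finite Markov chain over the emotion states.

The chain is estimated from label sequences (true or predicted) by counting
consecutive within-sequence transitions and normalising each row; rows with
no observed outgoing transitions are filled by a configurable rule so the
matrix stays row-stochastic. Transitions are never counted across sequence
boundaries — consecutive utterances are unrelated conversations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np

from .data import ABSENT, EmotionAlphabet, SequenceSet
from .exceptions import DomainError


@dataclass
class ChainModel:
    """Estimated transition structure: raw counts and the row-stochastic
    transition matrix ``P`` with ``P[i, j] = P(X_{t+1} = x_j | X_t = x_i)``."""

    alphabet: EmotionAlphabet
    counts: np.ndarray
    P: np.ndarray
    group: Optional[str] = None
    source: str = "labels"  # "labels" or "predictions"

    def __post_init__(self) -> None:
        n = self.alphabet.size
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.counts.shape != (n, n) or self.P.shape != (n, n):
            raise DomainError(f"chain matrices must be {n}x{n}")
        if np.any(self.counts < 0):
            raise DomainError("negative transition count")
        if np.any(self.P < 0) or not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-12):
            raise DomainError("P must be row-stochastic within 1e-12")

    @property
    def n(self) -> int:
        return self.alphabet.size

    def to_dict(self) -> dict:
        return {
            "alphabet": list(self.alphabet.labels),
            "group": self.group,
            "source": self.source,
            "counts": self.counts.tolist(),
            "P": self.P.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChainModel":
        return cls(
            alphabet=EmotionAlphabet(tuple(d["alphabet"])),
            counts=np.array(d["counts"]),
            P=np.array(d["P"]),
            group=d.get("group"),
            source=d.get("source", "labels"),
        )


def _as_index_sequences(
    seqs: Union[SequenceSet, Iterable[Sequence[int]]], alphabet: EmotionAlphabet
) -> list[np.ndarray]:
    if isinstance(seqs, SequenceSet):
        seqs = seqs.label_sequences()
    out = []
    for y in seqs:
        y = np.asarray(y, dtype=np.int64).ravel()
        if np.any(y == ABSENT):
            raise DomainError("chain estimation requires fully labeled sequences")
        if np.any(y < 1) or np.any(y > alphabet.size):
            raise DomainError(f"label index outside 1..{alphabet.size}")
        out.append(y)
    return out


def estimate_chain(
    seqs: Union[SequenceSet, Iterable[Sequence[int]]],
    alphabet: Optional[EmotionAlphabet] = None,
    zero_row_rule: str = "uniform",
    smoothing: float = 0.0,
    group: Optional[str] = None,
    source: str = "labels",
) -> ChainModel:
    """Maximum-likelihood transition-matrix estimate from label sequences.

    ``zero_row_rule`` fills rows with no observed transitions: ``"uniform"``
    (default) or ``"self_loop"``. ``smoothing`` adds k to every count
    (add-k smoothing, off by default so structural zeros stay zero).
    """
    if isinstance(seqs, SequenceSet) and alphabet is None:
        alphabet = seqs.alphabet
    if alphabet is None:
        raise DomainError("alphabet required when passing raw index sequences")
    if zero_row_rule not in ("uniform", "self_loop"):
        raise DomainError(f"unknown zero_row_rule {zero_row_rule!r}")
    if smoothing < 0:
        raise DomainError("smoothing must be >= 0")
    index_seqs = _as_index_sequences(seqs, alphabet)
    n = alphabet.size
    counts = np.zeros((n, n), dtype=np.int64)
    n_trans = 0
    for y in index_seqs:
        if len(y) < 2:
            continue
        np.add.at(counts, (y[:-1] - 1, y[1:] - 1), 1)
        n_trans += len(y) - 1
    if n_trans == 0:
        raise DomainError("no transitions: every sequence has length < 2")
    work = counts + smoothing
    sums = work.sum(axis=1, keepdims=True)
    P = np.zeros((n, n))
    nonzero = sums.ravel() > 0
    P[nonzero] = work[nonzero] / sums[nonzero]
    for i in np.flatnonzero(~nonzero):
        if zero_row_rule == "uniform":
            P[i] = 1.0 / n
        else:
            P[i, i] = 1.0
    return ChainModel(
        alphabet=alphabet, counts=counts, P=P, group=group, source=source
    )


def _state_index(model: ChainModel, s: Union[int, str]) -> int:
    if isinstance(s, str):
        return model.alphabet.index(s) - 1
    if not 1 <= int(s) <= model.n:
        raise DomainError(f"state {s} outside 1..{model.n}")
    return int(s) - 1


def transition_prob(model: ChainModel, i: Union[int, str], j: Union[int, str]) -> float:
    """P(X_{t+1} = j | X_t = i); states given 1-based or by label name."""
    return float(model.P[_state_index(model, i), _state_index(model, j)])


def stationary_distribution(model: ChainModel, atol: float = 1e-10) -> np.ndarray:
    """Unique left fixed vector of ``P`` for an irreducible aperiodic chain.

    Raises :class:`DomainError` if the chain (restricted to positive-
    probability edges) is reducible or periodic.
    """
    P = model.P
    G = nx.from_numpy_array(P > 0, create_using=nx.DiGraph)
    if not nx.is_strongly_connected(G):
        raise DomainError("chain is reducible: no unique stationary distribution")
    if not nx.is_aperiodic(G):
        raise DomainError("chain is periodic: stationary limit does not exist")
    n = model.n
    # solve pi (P - I) = 0 with sum(pi) = 1
    M = (P.T - np.eye(n)).copy()
    M[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(M, b)
    pi = np.maximum(pi, 0.0)
    pi = pi / pi.sum()
    if np.max(np.abs(pi @ P - pi)) > atol:
        raise DomainError("stationary solve did not converge to tolerance")
    return pi


def estimate_chains_by_group(
    data: SequenceSet,
    zero_row_rule: str = "uniform",
    smoothing: float = 0.0,
    source: str = "labels",
) -> dict[str, ChainModel]:
    """One chain per group tag (untagged sequences under ``"ungrouped"``)."""
    from .data import split_by_group

    return {
        g: estimate_chain(
            subset, zero_row_rule=zero_row_rule, smoothing=smoothing,
            group=g, source=source,
        )
        for g, subset in split_by_group(data).items()
    }


def format_chain_table(model: ChainModel, digits: int = 2) -> str:
    """Render the transition matrix as a labelled text table (rows = source
    state, columns = destination, canonical order)."""
    labels = model.alphabet.labels
    width = max(len(l) for l in labels) + 2
    num_w = digits + 4
    lines = []
    header = " " * width + "".join(f"{l:>{max(num_w, len(l) + 1)}}" for l in labels)
    lines.append(header)
    for i, l in enumerate(labels):
        cells = "".join(
            f"{model.P[i, j]:>{max(num_w, len(labels[j]) + 1)}.{digits}f}"
            for j in range(model.n)
        )
        lines.append(f"{l:<{width}}" + cells)
    return "\n".join(lines)
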