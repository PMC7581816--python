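"""Categorical-emission hidden Markov model over emotion-label sequences.

The chain has ``N`` hidden states and emits one of ``L`` labels per step.
Conventions: ``A[i, j] = P(q_t = j | q_{t-1} = i)`` (rows are source states,
so every row of ``A`` is a probability vector), ``E[j, i] = P(y_t = i |
q_t = j)``. All public label/state indices are 1-based; internal arrays are
0-based.

Forward-backward uses per-step scaling rather than log-space: the scaling
coefficients give the log-likelihood directly and the scaled alpha/beta
products are exactly the posteriors needed by the EM (Baum-Welch) updates,
so sequences of length 1000+ are handled without underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DomainError

#: Probability floor used when renormalising degenerate (all-zero) rows.
PROB_FLOOR = 1e-12


def _normalize_rows(M: np.ndarray) -> np.ndarray:
    """Rowwise normalisation; zero rows become uniform (floored)."""
    M = np.maximum(M, 0.0)
    sums = M.sum(axis=-1, keepdims=True)
    zero = (sums <= PROB_FLOOR).ravel()
    if M.ndim == 1:
        if sums.ravel()[0] <= PROB_FLOOR:
            return np.full_like(M, 1.0 / M.shape[-1])
        return M / sums
    out = np.where(sums > PROB_FLOOR, M / np.maximum(sums, PROB_FLOOR), 0.0)
    if zero.any():
        out[zero] = 1.0 / M.shape[-1]
    return out


@dataclass
class HMMParams:
    """HMM parameters: initial distribution ``pi`` (N,), transition matrix
    ``A`` (N, N) and emission matrix ``E`` (N, L)."""

    pi: np.ndarray
    A: np.ndarray
    E: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=np.float64).ravel()
        self.A = np.asarray(self.A, dtype=np.float64)
        self.E = np.asarray(self.E, dtype=np.float64)
        self.validate()

    @property
    def N(self) -> int:
        return self.pi.shape[0]

    @property
    def L(self) -> int:
        return self.E.shape[1]

    def validate(self, atol: float = 1e-9) -> None:
        N = self.pi.shape[0]
        if self.A.shape != (N, N):
            raise DomainError(f"A must be ({N},{N}), got {self.A.shape}")
        if self.E.shape[0] != N:
            raise DomainError(f"E must have {N} rows, got {self.E.shape}")
        for name, M in (("pi", self.pi[None, :]), ("A", self.A), ("E", self.E)):
            if np.any(M < -atol) or np.any(M > 1 + atol):
                raise DomainError(f"{name} entries outside [0, 1]")
            if not np.allclose(M.sum(axis=1), 1.0, atol=atol):
                raise DomainError(f"rows of {name} do not sum to 1 within {atol}")

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "E": self.E.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(
            pi=np.array(d["pi"]), A=np.array(d["A"]), E=np.array(d["E"])
        )


@dataclass
class PosteriorResult:
    """Per-step hidden-state posteriors ``gamma`` (T, N) and the sequence
    log-likelihood."""

    gamma: np.ndarray
    loglik: float


def init_random(N: int, L: int, seed: int = 0) -> HMMParams:
    """Random initialisation: entries uniform on (0, 1), rows normalised."""
    if N < 1:
        raise DomainError(f"need N >= 1 hidden states, got {N}")
    if L < 2:
        raise DomainError(f"need L >= 2 labels, got {L}")
    rng = np.random.default_rng(seed)
    pi = _normalize_rows(rng.uniform(size=N))
    A = _normalize_rows(rng.uniform(size=(N, N)))
    E = _normalize_rows(rng.uniform(size=(N, L)))
    return HMMParams(pi=pi, A=A, E=E)


def _check_labels(params: HMMParams, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.int64).ravel()
    if y.size == 0:
        raise DomainError("empty label sequence")
    if np.any(y < 1) or np.any(y > params.L):
        bad = y[(y < 1) | (y > params.L)][0]
        raise DomainError(f"label {bad} outside 1..{params.L}")
    return y - 1  # 0-based


def _scaled_forward_backward(params: HMMParams, y0: np.ndarray):
    """Scaled alpha/beta recursions. Returns (alpha_hat, beta_hat, c, B)
    where c are per-step scaling factors (loglik = sum log c) and
    B[t] = E[:, y_t] are per-step emission likelihood columns."""
    T = y0.shape[0]
    N = params.N
    B = params.E[:, y0].T  # (T, N)
    alpha = np.empty((T, N))
    c = np.empty(T)
    a = params.pi * B[0]
    c[0] = a.sum()
    if c[0] <= 0:
        # impossible first symbol under these parameters; floor to keep EM alive
        a = np.full(N, 1.0 / N)
        c[0] = PROB_FLOOR
    else:
        a = a / c[0]
    alpha[0] = a
    AT = params.A
    for t in range(1, T):
        a = (a @ AT) * B[t]
        c[t] = a.sum()
        if c[t] <= 0:
            a = np.full(N, 1.0 / N)
            c[t] = PROB_FLOOR
        else:
            a = a / c[t]
        alpha[t] = a
    beta = np.empty((T, N))
    b = np.ones(N)
    beta[T - 1] = b
    for t in range(T - 2, -1, -1):
        b = (AT @ (B[t + 1] * b)) / c[t + 1]
        beta[t] = b
    return alpha, beta, c, B


def forward_backward(params: HMMParams, y: Sequence[int]) -> PosteriorResult:
    """Posterior state marginals gamma[t, j] = P(q_t = j | y) and log P(y)."""
    y0 = _check_labels(params, y)
    alpha, beta, c, _ = _scaled_forward_backward(params, y0)
    gamma = _normalize_rows(alpha * beta)
    return PosteriorResult(gamma=gamma, loglik=float(np.sum(np.log(c))))


def baum_welch(
    params0: HMMParams,
    data: Iterable[Sequence[int]],
    max_iter: int = 100,
    tol: float = 1e-4,
) -> tuple[HMMParams, list[float]]:
    """EM re-estimation of (pi, A, E) from label sequences.

    Returns the fitted parameters and the per-iteration total log-likelihood
    trace (evaluated at the parameters entering each iteration); the trace is
    non-decreasing up to numerical slack. Stops after ``max_iter`` E-steps or
    when the improvement falls below ``tol``.
    """
    if max_iter < 1:
        raise DomainError("max_iter must be >= 1")
    seqs = [_check_labels(params0, y) for y in data]
    if not seqs:
        raise DomainError("no training sequences")
    params = params0
    N, L = params.N, params.L
    trace: list[float] = []
    for _ in range(max_iter):
        pi_acc = np.zeros(N)
        A_num = np.zeros((N, N))
        E_num = np.zeros((N, L))
        total_ll = 0.0
        for y0 in seqs:
            alpha, beta, c, B = _scaled_forward_backward(params, y0)
            total_ll += float(np.sum(np.log(c)))
            gamma = _normalize_rows(alpha * beta)
            pi_acc += gamma[0]
            T = y0.shape[0]
            if T > 1:
                # xi[t, i, j] proportional to alpha[t, i] A[i, j] B[t+1, j] beta[t+1, j]
                w = (B[1:] * beta[1:]) / c[1:, None]  # (T-1, N)
                A_num += params.A * (alpha[:-1].T @ w)
            np.add.at(E_num.T, y0, gamma)
        trace.append(total_ll)
        params = HMMParams(
            pi=_normalize_rows(pi_acc),
            A=_normalize_rows(A_num),
            E=_normalize_rows(E_num),
        )
        if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
            break
    return params, trace


def baum_welch_restarts(
    data: Iterable[Sequence[int]],
    N: int,
    L: int,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> tuple[HMMParams, list[float]]:
    """Baum-Welch from several random initialisations (seeds ``seed ..
    seed+n_restarts-1``), returning the fit with the highest final
    log-likelihood — the standard guard against poor EM local optima."""
    data = list(data)
    best: tuple[HMMParams, list[float]] | None = None
    for r in range(n_restarts):
        fit, trace = baum_welch(
            init_random(N, L, seed=seed + r), data, max_iter=max_iter, tol=tol
        )
        if best is None or trace[-1] > best[1][-1]:
            best = (fit, trace)
    assert best is not None
    return best


def posterior_decode(params: HMMParams, y: Sequence[int]) -> np.ndarray:
    """Stepwise MAP hidden path: q_t = argmax_j gamma[t, j], 1-based, ties
    broken toward the smallest state index."""
    post = forward_backward(params, y)
    return np.argmax(post.gamma, axis=1) + 1


def _hard_stats(params: HMMParams, seqs: list[np.ndarray]):
    """Counts from posterior-decoded hard paths: emission counts (N, L),
    transition counts (N, N), initial-state counts (N,). Labels 0-based in."""
    N, L = params.N, params.L
    cnt = np.zeros((N, L))
    A = np.zeros((N, N))
    pi = np.zeros(N)
    for y0 in seqs:
        q = np.argmax(forward_backward(params, y0 + 1).gamma, axis=1)
        pi[q[0]] += 1
        if q.shape[0] > 1:
            np.add.at(A, (q[:-1], q[1:]), 1)
        np.add.at(cnt, (q, y0), 1)
    return cnt, A, pi


def segmental_refine(
    params: HMMParams,
    data: Iterable[Sequence[int]],
    max_rounds: int = 4,
    mix_threshold: float = 0.2,
) -> HMMParams:
    """Segmental (hard-assignment) refinement of an EM fit.

    With many more hidden states than labels, Baum-Welch on sequences with
    weak temporal structure is unidentifiable: equally likely optima differ
    wildly in how cleanly decoded states separate the labels, and a mixed
    state makes the labels it absorbs indistinguishable downstream. This
    pass re-estimates (pi, A, E) from the posterior-decoded hard paths
    (segmental k-means style) and, when a state's decoded emission mass is
    split over two labels beyond ``mix_threshold`` while unused states
    remain, splits the minority label into a fresh state (halving the mixed
    state's incoming transition/initial mass). A final hard re-estimation
    leaves the parameters consistent with the decoded paths that downstream
    stages train on. Already well-separated fits pass through essentially
    unchanged.
    """
    seqs = [_check_labels(params, y) for y in data]
    N, L = params.N, params.L
    for r in range(max_rounds):
        cnt, Ac, pic = _hard_stats(params, seqs)
        tot = cnt.sum(axis=1)
        used = tot > 0
        E = _normalize_rows(cnt)
        A = _normalize_rows(Ac)
        pi = _normalize_rows(pic)
        changed = False
        for j in np.argsort(-tot):
            if tot[j] == 0:
                continue
            row = cnt[j] / tot[j]
            top2 = np.argsort(-row)[:2]
            if row[top2[1]] > mix_threshold:
                free = np.flatnonzero(~used)
                if free.size == 0:
                    # repurpose a redundant state: smallest label-pure state
                    # whose dominant label another state also covers
                    dom = cnt.argmax(axis=1)
                    mixing = 1.0 - cnt.max(axis=1) / np.maximum(tot, 1)
                    cand = [
                        k for k in np.argsort(tot)
                        if used[k] and k != j and mixing[k] <= mix_threshold
                        and np.sum((dom == dom[k]) & used & (mixing <= mix_threshold)) > 1
                    ]
                    if not cand:
                        continue
                    free = np.array([cand[0]])
                u, i2 = int(free[0]), int(top2[1])
                E[u] = PROB_FLOOR
                E[u, i2] = 1.0
                E[u] /= E[u].sum()
                E[j, i2] = PROB_FLOOR
                E[j] /= E[j].sum()
                A[u] = A[j]
                A[:, u] = A[:, j] / 2
                A[:, j] = A[:, j] / 2
                A = _normalize_rows(A)
                pi[u] = pi[j] / 2
                pi[j] /= 2
                pi = _normalize_rows(pi)
                used[u] = True
                changed = True
        params = HMMParams(pi=pi, A=A, E=E)
        if not changed and r > 0:
            break
    cnt, Ac, pic = _hard_stats(params, seqs)
    nonzero = cnt.sum(axis=1, keepdims=True) > 0
    E = np.where(nonzero, _normalize_rows(cnt), params.E)
    return HMMParams(
        pi=_normalize_rows(pic), A=_normalize_rows(Ac), E=_normalize_rows(E)
    )
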