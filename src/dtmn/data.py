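"""Sequence containers and tabular I/O.

The on-disk format is a tab-separated table with one row per time step:

    seq_id  group  t  label  feat_0 ... feat_{D-1}

``label`` may be empty for unlabeled steps; ``group`` may be empty. Time
indices are contiguous and 1-based within each sequence. Label indices are
1-based everywhere in the public interface; ``ABSENT`` (0) marks a missing
label.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .exceptions import DomainError, ParseError, StructuralError

#: Marker for a missing label / pre-sequence hidden state (1-based indexing).
ABSENT = 0

#: Canonical five-state emotion alphabet, in the row/column order used for
#: transition tables (angry first, soft last).
CANONICAL_LABELS = ("angry", "high_stress", "low_stress", "neutral", "soft")

#: Accepted input aliases, normalised on read.
LABEL_ALIASES = {"medium_stress": "low_stress"}

#: Reserved group key for sequences without a group tag.
UNGROUPED = "ungrouped"


@dataclass(frozen=True)
class EmotionAlphabet:
    """Ordered label alphabet; indices are 1-based in all interfaces."""

    labels: tuple[str, ...] = CANONICAL_LABELS

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise DomainError("alphabet needs at least 2 labels")
        if len(set(self.labels)) != len(self.labels):
            raise DomainError("alphabet labels must be unique")
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def size(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """1-based index of ``label`` (aliases accepted)."""
        label = LABEL_ALIASES.get(label, label)
        try:
            return self.labels.index(label) + 1
        except ValueError:
            raise DomainError(f"label {label!r} not in alphabet {self.labels}") from None

    def label(self, index: int) -> str:
        if not 1 <= index <= len(self.labels):
            raise DomainError(f"label index {index} outside 1..{len(self.labels)}")
        return self.labels[index - 1]


def canonical_alphabet() -> EmotionAlphabet:
    return EmotionAlphabet(CANONICAL_LABELS)


@dataclass
class LabeledSequence:
    """One utterance: labels ``y`` (1-based, ``ABSENT`` = unlabeled) and a
    ``(T, D)`` feature matrix ``f``, both indexed by time step 1..T."""

    id: str
    y: np.ndarray
    f: np.ndarray
    group: Optional[str] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        self.f = np.atleast_2d(np.asarray(self.f, dtype=np.float64))
        if self.y.ndim != 1:
            raise StructuralError(f"sequence {self.id}: labels must be 1-D")
        if self.f.shape[0] != self.y.shape[0]:
            raise StructuralError(
                f"sequence {self.id}: {self.y.shape[0]} labels vs "
                f"{self.f.shape[0]} feature rows"
            )
        if self.T == 0:
            raise StructuralError(f"sequence {self.id}: empty sequence")
        if np.any(self.y < 0):
            raise DomainError(f"sequence {self.id}: negative label index")

    @property
    def T(self) -> int:
        return int(self.y.shape[0])

    @property
    def D(self) -> int:
        return int(self.f.shape[1])

    @property
    def fully_labeled(self) -> bool:
        return bool(np.all(self.y != ABSENT))


@dataclass
class SequenceSet:
    """A collection of sequences sharing one alphabet and feature dimension."""

    alphabet: EmotionAlphabet
    sequences: list[LabeledSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        L = self.alphabet.size
        dims = {s.D for s in self.sequences}
        if len(dims) > 1:
            raise StructuralError(f"inconsistent feature dimensions {sorted(dims)}")
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise StructuralError("duplicate sequence ids")
        for s in self.sequences:
            if np.any(s.y > L):
                raise DomainError(
                    f"sequence {s.id}: label index exceeds alphabet size {L}"
                )

    @property
    def D(self) -> int:
        if not self.sequences:
            return 0
        return self.sequences[0].D

    @property
    def n_steps(self) -> int:
        return sum(s.T for s in self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def label_sequences(self) -> list[np.ndarray]:
        return [s.y for s in self.sequences]


_META_COLS = ("seq_id", "group", "t", "label")


def read_sequence_table(
    path, alphabet: Optional[EmotionAlphabet] = None
) -> SequenceSet:
    """Read a tab-separated sequence table into a :class:`SequenceSet`.

    When ``alphabet`` is omitted it is inferred from the observed labels,
    ordered canonically (known emotion labels first in canonical order,
    any others appended alphabetically).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise StructuralError(f"missing required columns: {missing}")
    feat_cols = [c for c in df.columns if c.startswith("feat_")]
    expected = [f"feat_{i}" for i in range(len(feat_cols))]
    if feat_cols != expected:
        raise StructuralError(
            f"feature columns must be feat_0..feat_{{D-1}} in order, got {feat_cols}"
        )
    if not feat_cols and len(df) > 0:
        raise StructuralError("no feature columns (feat_0..) found")

    feats = np.empty((len(df), len(feat_cols)), dtype=np.float64)
    for k, c in enumerate(feat_cols):
        try:
            # python float() parses correctly rounded, unlike pandas' fast path
            feats[:, k] = [float(v) for v in df[c]]
        except (ValueError, TypeError) as exc:
            raise ParseError(f"non-numeric value in column {c}: {exc}") from None

    raw_labels = [LABEL_ALIASES.get(v, v) for v in df["label"].tolist()]
    if alphabet is None:
        observed = sorted(set(v for v in raw_labels if v))
        known = [l for l in CANONICAL_LABELS if l in observed]
        extra = [l for l in observed if l not in CANONICAL_LABELS]
        inferred = tuple(known + extra)
        if len(inferred) < 2:
            # pad from the canonical list so the alphabet stays valid
            pad = [l for l in CANONICAL_LABELS if l not in inferred]
            inferred = tuple(list(inferred) + pad[: 2 - len(inferred)])
        alphabet = EmotionAlphabet(inferred)

    try:
        t_vals = df["t"].astype(int).to_numpy()
    except ValueError as exc:
        raise ParseError(f"non-integer time index: {exc}") from None

    sequences: list[LabeledSequence] = []
    order = []  # first-appearance order of seq ids
    seen = set()
    for sid in df["seq_id"]:
        if sid not in seen:
            seen.add(sid)
            order.append(sid)
    for sid in order:
        mask = (df["seq_id"] == sid).to_numpy()
        t = t_vals[mask]
        vals, counts = np.unique(t, return_counts=True)
        if np.any(counts > 1):
            dup = int(vals[counts > 1][0])
            raise StructuralError(f"sequence {sid!r}: duplicate time index {dup}")
        idx = np.argsort(t)
        t = t[idx]
        if not np.array_equal(t, np.arange(1, len(t) + 1)):
            raise StructuralError(
                f"sequence {sid!r}: time indices {t.tolist()} are not contiguous 1..T"
            )
        rows = np.flatnonzero(mask)[idx]
        y = np.empty(len(rows), dtype=np.int64)
        for j, r in enumerate(rows):
            lab = raw_labels[r]
            y[j] = ABSENT if lab == "" else alphabet.index(lab)
        groups = set(df["group"].to_numpy()[mask])
        if len(groups) > 1:
            raise StructuralError(f"sequence {sid!r}: inconsistent group tags {groups}")
        g = groups.pop()
        sequences.append(
            LabeledSequence(id=sid, y=y, f=feats[rows], group=g if g else None)
        )
    return SequenceSet(alphabet=alphabet, sequences=sequences)


def write_sequence_table(data: SequenceSet, path) -> str:
    """Write ``data`` as a TSV table; floats keep 17 significant digits so a
    read-back reproduces them bit-faithfully."""
    D = data.D if data.sequences else 0
    cols = list(_META_COLS) + [f"feat_{i}" for i in range(D)]
    buf = io.StringIO()
    buf.write("\t".join(cols) + "\n")
    for s in data.sequences:
        for t in range(s.T):
            lab = "" if s.y[t] == ABSENT else data.alphabet.label(int(s.y[t]))
            row = [s.id, s.group or "", str(t + 1), lab]
            row += [format(v, ".17g") for v in s.f[t]]
            buf.write("\t".join(row) + "\n")
    text = buf.getvalue()
    try:
        with open(path, "w") as fh:
            fh.write(text)
    except OSError as exc:
        raise StructuralError(f"cannot write {path}: {exc}") from exc
    return str(path)


def split_by_group(data: SequenceSet) -> dict[str, SequenceSet]:
    """Partition sequences by group tag; untagged sequences fall under the
    reserved key ``"ungrouped"``."""
    out: dict[str, list[LabeledSequence]] = {}
    for s in data.sequences:
        out.setdefault(s.group if s.group is not None else UNGROUPED, []).append(s)
    return {
        g: SequenceSet(alphabet=data.alphabet, sequences=seqs)
        for g, seqs in out.items()
    }


def subset(data: SequenceSet, ids: Iterable[str]) -> SequenceSet:
    wanted = set(ids)
    return SequenceSet(
        alphabet=data.alphabet,
        sequences=[s for s in data.sequences if s.id in wanted],
    )


def train_test_split(
    data: SequenceSet, test_fraction: float = 0.2, seed: int = 0
) -> tuple[SequenceSet, SequenceSet]:
    """Per-sequence holdout split (sequences are the sampling unit)."""
    if not 0 < test_fraction < 1:
        raise DomainError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(data.sequences)
    n_test = max(1, int(round(n * test_fraction)))
    if n_test >= n:
        raise DomainError("split would leave no training sequences")
    perm = rng.permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [s for i, s in enumerate(data.sequences) if i not in test_idx]
    test = [s for i, s in enumerate(data.sequences) if i in test_idx]
    return (
        SequenceSet(alphabet=data.alphabet, sequences=train),
        SequenceSet(alphabet=data.alphabet, sequences=test),
    )
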