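import numpy as np
import pytest

from dtmn import EmotionAlphabet, LabeledSequence, SequenceSet, TrainConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def fast_cfg():
    """Scaled-down SGD profile for unit tests (no refinement rounds)."""
    return TrainConfig(epochs=5, batch_size=64, refine_rounds=0)


@pytest.fixture
def tiny_set():
    """Two short fully-labeled sequences over the canonical alphabet."""
    alph = EmotionAlphabet()
    r = np.random.default_rng(42)
    seqs = [
        LabeledSequence(
            id=f"u{i}",
            y=r.integers(1, 6, size=12),
            f=r.normal(size=(12, 3)),
            group="M" if i % 2 == 0 else "F",
        )
        for i in range(4)
    ]
    return SequenceSet(alphabet=alph, sequences=seqs)


def random_sequence_set(seed, n_seqs=3, max_T=8, D=2, n_labels=5, with_groups=True):
    r = np.random.default_rng(seed)
    alph = EmotionAlphabet()
    seqs = []
    for i in range(n_seqs):
        T = int(r.integers(1, max_T + 1))
        y = r.integers(1, n_labels + 1, size=T)
        # sprinkle unlabeled steps
        y[r.random(T) < 0.2] = 0
        g = None
        if with_groups and r.random() < 0.7:
            g = str(r.choice(["M", "F"]))
        seqs.append(
            LabeledSequence(id=f"s{i}", y=y, f=r.normal(size=(T, D)), group=g)
        )
    return SequenceSet(alphabet=alph, sequences=seqs)
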