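# dtmn — deep time-delay Markov network for emotion-state sequences

`dtmn` predicts a speaker's emotional state over time and models how those
states change. It targets time series of utterance steps, each carrying a
speech-embedding feature vector `f_t` and (for training) one of five
emotion labels — *angry, high stress, low stress, neutral, soft* — and is
aimed at affective-computing researchers who want a state-transition-aware
predictor plus an interpretable transition model, without access to any
licensed speech corpus: a synthetic generator reproduces the relevant data
structure end to end.

## The model

The deep time-delay Markov network is a hybrid of a hidden Markov model and
a time-delay neural network (TDNN), trained in two phases:

1. **HMM phase.** A categorical-emission HMM with `N` hidden states (default
   80) is fitted to the label sequences `y_1..y_T` by Baum–Welch:

       A[i, j] = P(q_t = j | q_{t-1} = i),   E[j, i] = P(y_t = i | q_t = j)

   Posterior decoding (`q̂_t = argmax_j γ_t(j)`) yields a hidden-state path
   per sequence. A segmental refinement pass then re-estimates `(π, A, E)`
   from those hard paths and splits label-mixed states, keeping the decoded
   targets label-informative even when the state count is over-complete.
2. **TDNN phase.** A five-layer time-delay network learns
   `P(q_t | q_{t-5..t-1}, f_t)`: a tied position-wise transform of the
   one-hot prior states (layer 1), a sub-sampled splice of those outputs
   (layer 2), concatenation with the learned feature transform `β(f_t)`
   (layer 3), a fully connected hidden layer (layer 4), and a softmax over
   the `N` states (layer 5), trained by mini-batch SGD with batch
   normalization. Teacher-forced training is followed by
   recursive-consistency rounds on the network's own fed-back decisions.

Prediction rolls the TDNN forward over an unlabeled feature sequence,
feeding the argmax state back into the context window, and maps state
posteriors to label posteriors through the emissions:

    P(y_t = i | f) = Σ_j E[j, i] · P(q_t = j | f)

Finally, a finite Markov chain `P_ij = P(X_{t+1} = x_j | X_t = x_i)` over
the five emotion states is estimated per group (e.g. per gender) from
predicted or gold label sequences.

## Worked example

```python
import dtmn

# synthetic study conditions: persistent emotions, overlapping features
data, truth = dtmn.generate(dtmn.preset("persistent", seed=0))
train, test = dtmn.train_test_split(data, test_fraction=0.2, seed=0)

res = dtmn.DTMN(train, n_hidden=10, context="tdnn4", hidden_dim=64).fit(seed=0)
print(res.summary())
report = res.evaluate(test)
print(f"PER: {report.per:.2f}% over {report.n_steps} steps")

base = dtmn.train_memoryless_baseline(train, dtmn.TrainConfig(seed=0))
print(f"baseline PER: {base.evaluate(test).per:.2f}%")

chains = dtmn.estimate_chains_by_group(test)
print(dtmn.format_chain_table(chains["ungrouped"]))
```

prints

```
Deep Time-delay Markov Network
==============================================
hidden states (N)           10
label alphabet (L)          5
feature dim (D)             8
context preset              tdnn4
network context             [-5, -4, -3, -2, -1]
hidden width (H)            64
seed                        0
----------------------------------------------
Baum-Welch iterations       100
final log-likelihood        -3797.1051
TDNN epochs                 78
final TDNN loss             1.0177
PER: 29.10% over 2000 steps
baseline PER: 43.15%
              angry high_stress low_stress neutral  soft
angry          0.92        0.02       0.02    0.02  0.02
high_stress    0.03        0.90       0.01    0.03  0.02
low_stress     0.02        0.03       0.90    0.03  0.03
neutral        0.03        0.03       0.02    0.90  0.02
soft           0.03        0.03       0.03    0.03  0.88
```

The DTMN's 29.1% error rate versus the memoryless classifier's 43.2% is the
method's point: when emotions persist (here the true chain's diagonal is
0.9), conditioning on prior states recovers accuracy that per-step feature
classification cannot, and the estimated chain reproduces that persistence.

The same machinery drives the command line:

```sh
dtmn simulate --preset persistent --n 50 --length 200 --seed 0 --out synth.tsv
dtmn train --data synth.tsv --n-hidden 10 --hidden-dim 64 --holdout 0.2 --out model.json
dtmn predict --model model.json --data synth.tsv --out pred.tsv
dtmn chain --pred pred.tsv --out chains.json
dtmn ablate --data synth.tsv --mode contexts --variants tdnn1,tdnn4
```

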