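# Methods

## Problem and model

The package addresses stepwise prediction of a speaker's emotional state
from a time series of speech-embedding features, under the observation that
emotions — stress in particular — persist over short horizons, so the prior
states carry information that a per-step classifier discards. The predictor
is a hybrid of two components.

**Label-side HMM.** A hidden Markov chain `q_1..q_T` over `N` states links
the observed labels `y_t` (five emotion categories: angry, high stress, low
stress, neutral, soft) through a row-stochastic transition matrix
`A[i, j] = P(q_t = j | q_{t-1} = i)` and a categorical emission matrix
`E[j, i] = P(y_t = i | q_t = j)`. Parameters are fitted to the label
sequences alone by Baum–Welch (EM with scaled forward–backward recursions);
each step's hidden target is the posterior mode `q̂_t = argmax_j γ_t(j)`,
with ties resolved toward the smaller state index.

**Feature-side TDNN.** A time-delay network models
`P(q_t | q_{t-K..t-1}, f_t)`. Prior states enter as one-hot indicator
vectors (`α` encoding; an all-zero vector marks pre-sequence positions so
sequence starts are representable without leakage). Layer 1 applies one
affine + batch-norm + ReLU transform, tied across the `K` temporal
positions; layer 2 splices the layer-1 outputs at a sub-sampled offset set
(e.g. `{-3, -1}` out of `[-5, -1]`); layer 3 concatenates that with a
learned affine feature map `β(f_t)` (near-identity initialisation, output
width `D` by default); layer 4 is a fully connected hidden layer of width
`H`; layer 5 an affine projection to the `N` state classes followed by a
numerically stabilised softmax. The published layer-context table is not
internally consistent under any single splicing semantics (one variant's
layer-2 offsets fall outside its printed layer-1 positions), so the
implementation reads each preset as: layer 1 runs at every network-context
offset, layer 2 splices the subset in its printed column — a subset of the
network context in all six presets — and the layer-1 column is treated as
descriptive. The `tdnn1`–`tdnn6` presets encode the printed
network/layer-wise offset sets on this five-layer architecture; `eq2` is
additionally provided as the literal single-affine softmax
`softmax(W_q α(q_{t-1}) + W_f β(f_t) + b)`.

**Prediction.** The network is rolled forward over an unlabeled sequence:
at step `t` it sees the fed-back representation of its own prior decisions
(hard one-hot argmax states by default; the full posterior with
`feedback="soft"`) plus `f_t`, and outputs the state posterior
`P(q_t = j | f)`. Labels follow by marginalising over states,
`P(y_t = i | f) = Σ_j E[j, i] P(q_t = j | f)`; both posterior rows sum to
one by construction and are asserted on every prediction. The initial
distribution `π` plays no role at prediction time: decoding starts from an
all-absent context.

**Transition chain.** A finite Markov chain over the five emotion states is
estimated per group by counting consecutive within-sequence transitions and
normalising rows; transitions are never pooled across sequence boundaries,
which would fabricate transitions between unrelated conversations. Rows
with no observed transitions default to uniform (a `self_loop` rule is
available); add-k smoothing is off by default so structural zeros survive.
The stationary distribution is computed as the unique left fixed vector
after explicit irreducibility and aperiodicity checks — reducible or
periodic chains raise instead of silently falling back.

## Training procedure

Phase one runs Baum–Welch (default at most 100 iterations, stopping when
the total log-likelihood improves by less than 1e-4; rows that collapse to
zero mid-EM are re-normalised to uniform with a 1e-12 floor). Because the
state count is deliberately over-complete (published setting `N = 80` for
5 labels), EM on weakly structured label sequences is unidentifiable in the
emissions: equally likely optima differ in how cleanly decoded states
separate the labels, and a state that mixes two labels makes them
indistinguishable downstream. A segmental refinement pass therefore
follows: `(π, A, E)` are re-estimated from the posterior-decoded hard paths
(segmental k-means style, at most 4 rounds), and a state whose decoded
emission mass is split beyond 20% over a second label is split into an
unused state — repurposing a redundant duplicate state when none is free —
halving the mixed state's incoming transition and initial mass. On strongly
persistent data the pass is a near no-op (decode purity is already ≈ 1);
on temporally unstructured data it raises purity from ≈ 0.75–0.85 to
≈ 0.93–1.0. `baum_welch` itself remains pure EM with a provably
non-decreasing likelihood trace. A `baum_welch_restarts` helper runs EM
from several seeds and keeps the best final likelihood; parameter-recovery
studies use it because the likelihood reliably separates the good basin
from collapsed optima on well-separated simulated HMMs.

Phase two trains the TDNN by mini-batch SGD with momentum on the mean
cross-entropy of the decoded targets (teacher forcing), then runs
*recursive-consistency refinement*: each round free-runs the decoder over
the training sequences exactly as at prediction time, aggregates the
self-generated context windows with the teacher-forced ones (targets
unchanged — an aggregation scheme in the spirit of DAgger), and continues
SGD at a per-round decayed learning rate. This step is load-bearing. The
teacher-forced network only ever sees correct prior states; rolled out on
its own imperfect feedback it compounds errors badly (on the persistent
preset: ≈ 55% error versus the memoryless baseline's 43%). After
refinement the same architecture reaches ≈ 26–30%. An idealized-filter
calculation under the same conditions brackets what is achievable: exact
Bayes filtering attains 22% error, a filter restricted to hard single-state
feedback 49%, and a memoryless Bayes rule 41% — the refined network sits
between the hard-feedback bound and the exact filter because the multi-lag
window of hard decisions partially reconstructs the posterior.

Defaults and their reasons: batch size 256 and batch normalization after
each affine, before ReLU, in layers 1, 2 and 4 (published settings; the
paper states only that batch normalization is performed); hidden width
4000 (published; the scaled study profile uses 64, see below); learning
rate 0.01, momentum 0.9, 30 teacher-forced epochs (unstated in the source;
conventional SGD values); 6 refinement rounds of 8 epochs at learning rate
0.005 decaying ×0.8 per round (chosen so the free-run policy converges —
fewer rounds leave multi-lag variants under-trained on their own feedback).
All are exposed in `TrainConfig`, and everything is deterministic given the
fit seed (numpy Generator seeding; no threading).

## Synthetic data

The generator emulates the structure of a stress-speech corpus: per group
(e.g. two "gender" groups with distinct persistence), label paths are drawn
from a ground-truth 5×5 Markov chain and features from label-conditional
spherical Gaussians `N(μ_label, I)` in `D = 8` dimensions (the embedding
dimension of the real front end is unstated; 8 keeps the task
non-trivially high-dimensional at desk scale). The separation knob scales
`‖μ_i − μ_j‖` in units of the within-class standard deviation. Label noise,
when enabled, flips observed labels only — features follow the true label —
so annotation noise and feature overlap vary independently. Presets fix the
study conditions: `separable` (separation 4.0, mild persistence 0.5 —
centroid-separable by construction), `overlapping` (separation 1.2),
`persistent` (diagonal-0.9 chain, separation 1.2 — temporal context is
informative but features alone are not), and `iid` (uniform chain — no
temporal signal, a negative control). What the generator does **not**
emulate: utterance-length acoustic correlations, speaker effects, class
imbalance, or the anisotropic geometry of learned embeddings. Passing tests
therefore demonstrate correctness of the machinery and the direction of the
temporal-context effect under Markov-Gaussian conditions, not performance
on real speech.

## Evaluation

The prediction error rate (PER) is the percentage of steps whose predicted
label differs from the truth, pooled over all evaluated steps
(micro-average; the aggregation is unstated in the source and pooling
matches a time-step error rate). The internal comparator is a memoryless
softmax classifier on `f_t` trained by the same SGD machinery — it bounds
what present-time features alone achieve. Two ablations mirror the
published ones: a hidden-state-count sweep (full DTMN retrained per `N`)
and a context-variant sweep in which the HMM stage is shared within each
repeat so only the TDNN context varies. Repeats default to 5 with seeds
`seed..seed+4`; reports always carry per-repeat values and dispersion.

The study profile used by the acceptance script and the heavyweight tests
is 50 sequences × 200 steps, `N = 10` hidden states, hidden width 64,
an 80/20 per-sequence split, 5 seeds, with medians reported — sizes at
which every qualitative effect is measurable on a single CPU in minutes.
Corpus-specific published error rates are not reproduction targets: the
underlying corpus is license-restricted, so the package's claims are the
property-level ones above.

## Numerical choices and edge cases

- Forward–backward uses per-step scaling constants rather than log-space;
  the log-likelihood is the sum of log scaling factors, and an impossible
  first symbol floors the scale at 1e-12 instead of propagating NaNs.
- Softmax subtracts the row maximum before exponentiation.
- All argmax tie-breaks (posterior decode, fed-back states, label choice)
  resolve toward the smallest index, making every pipeline deterministic.
- Stationary distributions solve the balance equations by replacing one row
  with the normalisation constraint and verifying `‖πP − π‖∞ ≤ 1e-10`.
- Feature values serialize with 17 significant digits and are parsed with
  correctly rounded conversion, so table round-trips are bit-faithful.
- Sequences shorter than 2 contribute no chain transitions; estimating a
  chain from only such sequences is an error, not a silent uniform matrix.

## Known limitations

- With hard feedback the decoder is greedy; no beam or smoothing pass
  exists, and on weakly separated features the exact-filter optimum is out
  of reach by design.
- Hidden states are nuisance variables: with `N > L` their identity is
  meaningless and only the induced label posterior is interpreted.
- The segmental split heuristic repairs two-way label mixtures; a state
  mixing three labels with no spare capacity stays mixed.
- Batch-norm statistics are running averages frozen at the end of training;
  very short prediction batches rely on them being representative.
- The CLI holds models as JSON; at the published hidden width (4000) model
  files become large, and the scaled width is recommended for interactive
  use.
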