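# Methods

## Model

The generator is a character-level autoregressive model: two stacked
LSTM layers, 128 hidden units each, followed by a linear projection to
4 logits (one per nucleotide class A=1, C=2, G=3, T/U=4). T and U share
class 4, so one model architecture serves DNA and RNA; sampled indices
are rendered with T or U according to the configured alphabet. The loss
is the mean negative log-likelihood (natural log) of the observed next
character; its uniform-prediction baseline is ln 4 ≈ 1.3863, and the
default initialization (zero output projection, LSTM weights uniform in
[−0.08, 0.08], forget-gate bias 1) makes an untrained model sit at that
baseline *exactly*, which the tests exploit.

Training data — k binder sequences of fixed length S (default 20) — is
concatenated in file order with **no separator** into one stream of
N = k·S characters, split into B (default 50) contiguous sub-streams,
and cut into chunks of B×S characters. The 4-symbol alphabet is kept
pure: the prediction across a sequence boundary (last character of one
binder → first of the next) is accepted as training noise, one
character in S. The final character of each sub-stream takes the next
sub-stream's first character as its target; the last one wraps to the
start of the concatenation. Characters that do not fill a whole chunk
are dropped. The *last* max(1, ⌊0.05·n_chunks⌋) chunks are validation —
a deterministic split needing no seed; chunk order *within* training is
shuffled per epoch under the training seed.

Optimization is RMSProp (learning rate 2e-3, decay 0.95, ε=1e-8) with
global gradient-norm clipping at 5 — classic char-rnn-style settings,
all exposed in `TrainConfig`. Backpropagation through time is truncated
at the chunk: hidden state persists across the S timesteps of a chunk
and is reset between chunks. One checkpoint is stored per epoch; the
selection rule returns the minimum-*validation*-loss checkpoint
(earliest epoch on ties — lower overfitting risk). On the synthetic
fixtures validation loss typically bottoms out around epochs 10–25 and
rises afterwards while memorization (IU ratio) keeps growing, which is
exactly why selection is by loss, not by IU ratio. The per-epoch IU
probe is optional (`iu_probe_size`, default off in training, 10,000 is
a reasonable probe when enabled) since its absolute scale depends on
the probe-pool size.

Sampling starts from the maximum-entropy input (0.25, 0.25, 0.25,
0.25) with zero hidden state; each step draws one nucleotide from
softmax(z/T) (temperature T defaults to 1) by inverse-CDF against a
pre-drawn uniform. Every pooled sequence owns an RNG stream spawned
from the pool seed, so pools are reproducible and a pool of one equals
a single-sequence draw; batching is an implementation detail.

## Affinity and specificity

Each scorer is calibrated by its own empirical background: n (default
200,000) uniform-random sequences of the working length are scored and
sorted once; the affinity of a query is the fraction of background
scores ≤ its score (ties count in its favor, exactly as the percentile
definition reads), found by binary search. The tie rule biases
discrete-valued scorers toward 1 at tied values; this is documented
behavior, not corrected. A consequence worth knowing: a two-level PWM
(pure consensus/non-consensus columns) has only a handful of distinct
window scores, and its AF percentiles are coarse; the synthetic module
therefore offers `dirichlet_motif_matrix`, which perturbs columns the
way real transcription-factor PWMs vary, making random-sequence AF
uniform to within KS ≈ 0.01.

Specificity for target m contrasts AUC-weighted affinities:
SP = AF_m·AUC_m − mean_{k∈M^c}(AF_k·AUC_k), where M^c are the *other*
scorers sharing m's experiment type. A missing AUC weighs 1. With no
same-experiment competitor the mean is undefined and the call raises
rather than silently degrading to AF·AUC. |SP| is bounded by the
largest member AUC.

The shipped scorer is a log-odds PWM (pseudocount 0.5 against uniform
0.25 background) aggregated by max over forward-strand windows only —
candidate aptamers are single-stranded, so no reverse-complement scan.
JASPAR-style count files are read via Biopython.

## Pipeline

train → select checkpoint → generate pool → deduplicate → score → top-k
by SP (ties: higher target AF, then lexicographic — the published
selection is silent on ties, and reproducible top-k membership needs a
total order). Duplicates are removed before ranking: trained
generators emit a substantial duplicated fraction, and a ranked list of
identical strings is useless to an experimentalist. All sub-seeds
derive from one master seed; TSV artifacts are written with fixed float
formatting, so identical configurations give byte-identical files.

## Alignment profiling

Gotoh affine-gap global alignment; a gap of length L costs
open + L·extend (defaults 10 and 0.5, match +5 / mismatch −4,
EDNAFULL-like; pairs involving an ambiguity code score −2). End gaps
are free by default, emulating the EMBOSS needle default — necessary
for 20-mers against ~90-nt references. Traceback is deterministic:
diagonal > up > left on ties, gap-open preferred over gap-extend, and
with free end gaps the end cell ties resolve toward the bottom-right
corner. T/U normalization happens only inside alignment and motif
matching; stored sequences keep their native alphabet.

The cumulative specificity profile adds a candidate's SP at every
ungapped reference position covered by a non-gap query character. That
aggregation rule is this package's interpretation of the published
line-chart/heatmap displays (raw sums, no coverage normalization); it
is isolated in `build_profile` so match-only or normalized variants can
be swapped in. Coordinates are 0-based half-open internally, 1-based in
emitted tables.

## Synthetic data

The generator's test bed emulates a selection experiment's positive
pool: uniform background 20-mers with a motif instance *sampled from a
probability matrix* (consensus probability 0.85 per position by
default) planted at a uniform-random offset in a `plant_rate` fraction
(default 0.9) of sequences. Sampling from the matrix, rather than
pasting the consensus, forces the generator to learn a distribution.
Default fixture motifs are TTTCCA and GGGGGAATCCCC (well-known
NFATC1/NFKB1 binding consensi), so cross-motif specificity tests read
naturally. The cross-reactive variant plants both motifs at
non-overlapping offsets in a configurable fraction of sequences
(defaults 40% both / 50% target-only / 10% background) — the scenario
in which specificity ranking and affinity ranking genuinely disagree.

What this emulates — and what it does not: uniform background (no
genomic composition bias), independent sequences (no SELEX round
dynamics, PCR bias, or sequencing error), and a PWM ground truth (no
positional or structural binding effects). Passing tests show the
pipeline recovers planted sequence signal under these conditions; they
say nothing about binding of real proteins.

## Problem sizes and checks

The full-size verification runs train the 2×128 model for 50 epochs on
2,000 synthetic 20-mers (≈2.5 minutes on one CPU core) and generate
10,000-sequence pools; backgrounds use the full 200,000 sequences where
the quantity under test is AF calibration, 50,000 for ensemble tests.
Under these conditions the generated pool's median ground-truth AF is
≈0.996 (random: ≈0.5) and the planted-motif rate is enriched ~80× over
uniform sequences. For the specificity contrast, the affinity-only
comparator ranking breaks ties with a seeded random draw: affinity
saturates at 1.0 for thousands of pool sequences, and any
content-derived tie-break (e.g. lexicographic) would bias the motif
composition being measured.

Numerical choices: float64 throughout; softmax is max-shifted;
gradient checks compare per-tensor norms against central finite
differences (step 1e-5), where agreement is ~1e-7 — elementwise ratios
on near-zero entries are dominated by cancellation noise and are not
meaningful. Checkpoints are .npz archives with a JSON config; loading
restores bit-identical forward behavior.

## Known limitations

- The generator requires experimental training data; with none, it
  samples uniform noise.
- AF calibration assumes the scorer is meaningful on random sequences;
  a constant scorer yields AF = 1 everywhere (tie rule).
- Specificity requires at least two same-experiment scorers.
- No GPU path; the NumPy implementation targets desk-scale data
  (~10^4–10^5 short sequences), not genome-scale corpora.
- Free-end-gap alignment of very short queries can tile anywhere on a
  reference when scores tie; profiles from few candidates are noisy.
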