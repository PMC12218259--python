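# Methods

This note documents the statistical procedures implemented in `popcode`,
the assumptions behind them, the synthetic-data model used to validate
them, and the numerical choices that were genuinely open.

## Data model

All analyses operate on a binary event raster `X ∈ {0,1}^{N×T}` (N neurons,
T frames at 20 Hz; one frame = 50 ms) plus a frame-aligned annotation
carrying four label fields per frame: epoch, context, behavior and maze
arm. Frames are 0-based and all intervals are half-open `[start, end)`.
A social session consists of four conspecific-exposure epochs A–D, each
beginning 5 minutes (6,000 frames) before the first interaction bout and
ending at conspecific removal; a "static" day keeps one context for all
four epochs, a "dynamic" day switches context between A,B and C,D. An
anxiety session alternates 10-minute home-cage blocks with 10-minute maze
blocks (elevated zero maze, elevated plus maze, closed T-maze), with
per-frame arm labels inside mazes.

"Nonsocial" frames default to every non-interaction frame regardless of
conspecific presence; alone-only and present-but-not-interacting variants
are selectable, since the choice can matter for bout-adjacent dynamics.

## Event detection

dF/F traces are low-pass filtered with an equiripple FIR designed to a
0.5/0.65 passband/stopband edge (fractions of Nyquist), ≤ 1 dB passband
ripple and ≥ 25 dB stopband attenuation. The design frequencies are
interpreted as Nyquist fractions by default; a flag re-interprets them as
Hz because the convention is ambiguous in common acquisition toolchains.
The default single-pass filter compensates the FIR's constant group delay
so onset times stay aligned; forward–backward (zero-phase) filtering is
available.

Transients are detected where the first difference of the filtered trace
exceeds `derivative_min` (default 0.06 dF/F per frame); consecutive
candidate frames within 2 frames are merged into one onset. A candidate is
accepted when the deflection above a running-baseline — the 20th percentile
in a centered 30 s window, since slow baseline wander is generic in dF/F
data — reaches `amplitude_min` (default 0.15 dF/F) and its integrated area
until return-to-baseline reaches `auc_min` (default 0.4 dF/F·frames).
These defaults are matched to transients of 4–8× noise amplitude with a
0.5 s decay; real datasets should be tuned with `tune_detector`, which
grid-searches the three thresholds and maximizes min(sensitivity,
specificity), matching detected to true onsets within ±2 frames and scoring
specificity frame-wise outside the (jitter-dilated) true-event extents.

Event semantics: the default raster marks the full supra-baseline extent of
an accepted transient as active frames, because the downstream statistics
are built on "fraction of frames active"; an onset-only mode exists and is
what the tuner scores, since extent rasters fuse events that ride on a
preceding transient's tail.

## Modulation indices

For a scope (one epoch, a concatenated epoch pair, or a maze plus its
adjacent home-cage blocks) the neuron's scope-restricted row is circularly
shifted by offsets drawn uniformly with replacement from `{0,…,T−1}`
(offset 0 allowed; 10,000 shuffles by default, tests use fewer). The
statistic — mean activity inside a condition mask, or the difference in
mean activity between two masks — is recomputed at each shift, and the
index is the mid-rank percentile of the observed value:

    index = 100 · (#{null < obs} + ½·#{null = obs}) / n_shuffles.

The mid-rank convention was chosen so that a constant-activity neuron
(fully degenerate null) lands at 50 rather than 0 or 100. Because the rows
are binary, each per-shift statistic is a ratio of integer counts; the
all-shift count profile is a circular cross-correlation computed by FFT
and rounded back to exact integers, so sampled nulls, the exhaustive-
enumeration mode, and a brute-force oracle agree bit-exactly. Epoch pairs
are concatenated and shifted as one row (a per-epoch-shift variant exists);
whether shuffles should respect bout boundaries is unknowable from first
principles, so shifts run over the whole scope. Neurons with no events in
either mask are excluded (index NaN) rather than pinned to 50.

## Decoding

Single frames are samples, neurons are features, and the classifier is a
linear max-margin SVM (hinge loss, C = 1, no intercept scaling; pinned
`random_state` for determinism). Class imbalance is handled by
downsampling the majority class to the minority count independently in
each iteration (500 iterations with 25% hold-out for whole-session
decoding; 200 for transfer analyses by default). Transfer decoding trains
on all (balanced) frames of one scope and tests on disjoint scopes; test
sets are also balanced by equal random subsamples per class, which makes
50% the exact chance level — a deliberate choice, with a toggle, since
unbalanced testing shifts the no-information rate.

Chance is measured on degree-preserving surrogates: 2×2 checkerboard swaps
(two events trade corners when the opposite corners are empty), attempted
10× the event count, preserve every row and column sum exactly. Note the
surrogate preserves per-frame population counts; if a condition elevates
the total population rate, a linear readout can exploit that even in
surrogate data, so surrogate accuracy sits at, but not below, chance plus
that residual — the same behavior expected of any margin-preserving
control.

## Ensemble geometry

Two modulation-index vectors are compared by cosine similarity after
subtracting 50 from every index (the null expectation of a percentile), or
by Pearson correlation (mean-centering). Both are reported because
"centering" a percentile vector is ambiguous; on calibrated indices the
two rarely disagree. Significance uses an entry-permutation null (default
10,000 draws): the neuron assigned to each index value of one vector is
re-assigned uniformly. A pair is called orthogonal when the observed
similarity falls inside the central 95% of its permutation null.

Overlap analysis cross-tabulates neurons by strict thresholds (> 90
positive, < 10 negative, 10–90 middle) into 3×3 tables; two tables are
compared per cell by a 2×2 χ² (in-cell vs not × table A vs table B),
without continuity correction by default (toggleable).

## Synthetic sessions and what they do (not) show

The generator draws events as independent Bernoulli per neuron per frame:
baseline probability 0.01 per frame (≈ 0.2 Hz — chosen to produce sparse
rasters of the kind the analyses target; per-neuron event rates are not
published for such recordings, so this is a declared assumption),
multiplied by planted per-neuron gains — social (default 2.0 / 0.5 on
10% + 10% of neurons), context (same magnitudes, applied in every
non-reference context), and arm gains, composed multiplicatively and
clipped at 0.95. Remapping redraws the social ensemble per context;
`independent_context=False` reuses the social neurons for the context
ensemble with sign-matched modulation (in the first-minus-later index
convention), giving the correlated-plant fixture. Arm occupancy follows a
first-order Markov chain with geometric dwell (default mean 2 s). Traces
convolve events with an instant-rise kernel, `exp(−t/τ)`, τ = 0.5 s —
generic indicator kinetics, since none are specified for the pipeline's
purposes — with amplitudes uniform in 4–8× the white-noise SD (0.05 dF/F).
Drift, off by default, is a per-neuron geometric ramp of baseline rate.

What the generator does *not* emulate: within-bout temporal dynamics
(onset transients, adaptation), inter-neuron correlations beyond the
planted gains, bursting/refractoriness, movement artifacts, and spatial
crosstalk between sources. Passing recovery tests therefore shows the
estimators are unbiased and calibrated under the assumed event model, not
that they are robust to those real-data features; the circular-shift null
is specifically designed to be robust to slow autocorrelation, which the
generator exercises only via optional drift.

Determinism: one master seed; every stochastic step draws from spawned
child generators, so identical configuration + seed reproduces every
table byte-for-byte.

## Problem sizes

Default analysis parameters follow the study conditions (10,000 shuffles,
500/200 decoder iterations, 80-neuron sessions of ~48,000–70,000 frames).
The test suite runs the same estimators on reduced sessions (typically
13,600 frames, 300–2,000 shuffles, 10–30 decoder iterations) with
correspondingly widened Monte-Carlo tolerances; the acceptance checks use
50 neurons × 12,000 frames for detector tuning and 80 × 48,000 frames with
200 iterations for the surrogate chance-level benchmark.

## Known limitations

- Group-level inference (repeated-measures ANOVA, mixed-effects models,
  multi-stage FDR) is out of scope; the pipeline emits per-session tables
  plus simple tests (KS, χ², Pearson).
- The χ² overlap comparison fixes one specific 2×2 construction per cell;
  other constructions of the same question exist and would give slightly
  different statistics.
- Decoding uses raw binary frames; no temporal binning or smoothing.
- The surrogate swap chain is run with a fixed attempt budget rather than
  a mixing diagnostic; 10× the event count is far past empirical mixing
  for matrices of this sparsity, but extremely dense matrices would need
  more.
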