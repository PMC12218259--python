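# popcode

Population-coding analysis of calcium-imaging sessions: does a cortical
population encode a behavioral variable (social interaction, anxiety-related
maze exploration) with the *same* neurons across different environmental
contexts, or does the code remap?

The package is built for microendoscopic recordings of prefrontal cortex in
freely behaving mice — sparse binary event rasters of ~80 neurons over
10⁴–10⁵ frames at 20 Hz, with frame-aligned behavioral annotations — but the
machinery is generic: any neurons × frames raster with condition masks.

## What it computes

Given an event raster `X ∈ {0,1}^{N×T}` and condition masks:

- **Population activity vectors** — per-neuron mean activity over a
  condition's frames, `v_c[i] = mean_t∈c X[i,t]`, with pairwise Pearson
  similarity matrices, "highly active" (> 7.5% of frames) / silent-neuron
  summaries, and two-sample KS comparisons of activity distributions.
- **Modulation indices** — for each neuron, the observed condition statistic
  (mean in a mask, or difference in means between two masks) is ranked
  against a null distribution built by circularly shifting the neuron's
  scope-restricted activity row by uniform offsets (default 10,000 shifts).
  The index is the mid-rank percentile on 0–100: > 90 = positively
  modulated, < 10 = negatively modulated.
- **Balanced linear decoding** — a linear max-margin classifier (hinge loss,
  C = 1) on single frames, with per-iteration majority-class downsampling,
  hold-out testing, cross-epoch/cross-maze transfer, and precision / recall /
  F1 (`F1 = 2PR/(P+R)`). Chance level is measured on degree-preserving
  surrogate rasters: event neuron-identities are shuffled by checkerboard
  swaps so that every per-neuron and per-frame event count is unchanged.
- **Ensemble geometry** — similarity of two modulation-index vectors via
  zero-centered cosine (`cos θ = u·w / (||u|| ||w||)` after subtracting 50,
  the null midpoint) or Pearson correlation, with entry-permutation nulls;
  3×3 overlap tables of strongly modulated groups and per-cell 2×2 χ²
  comparisons between days.
- **Synthetic sessions** — a generator that plants per-neuron multiplicative
  social / context / arm gains (optionally remapped across contexts, or
  correlated between variables) on a Bernoulli event process, builds
  GCaMP-like dF/F traces (instant rise, exponential decay, white noise),
  and returns the ground truth for parameter-recovery testing.
- **Event detection** — equiripple FIR low-pass filtering followed by
  derivative / amplitude / area thresholding against a running-percentile
  baseline, with grid tuning to > 95% sensitivity and specificity against
  known onsets.

## Worked example

```python
import numpy as np
import popcode
from popcode.decoding import DecodeTask, surrogate_shuffle, train_eval
from popcode.modulation import behavior_modulation, context_modulation
from popcode.geometry import vector_similarity

# A dynamic-context day: epochs A,B in the home cage, C,D in a second arena,
# a planted social ensemble (gain 2.0 / 0.5 on 20% of neurons) shared
# across contexts, and an independent context ensemble.
spec = popcode.default_social_spec(seed=1, n_neurons=80, pre_frames=1000,
                                   n_bouts=6, bout_frames=500, gap_frames=200,
                                   baseline_frames=0)
session = popcode.generate_session(spec, popcode.TruthConfig())
ann = session.annotation

task = DecodeTask(ann.social_mask(), ann.nonsocial_mask(), n_iterations=100, seed=2)
real = train_eval(session.raster, task)
surr = train_eval(surrogate_shuffle(session.raster, seed=3),
                  DecodeTask(ann.social_mask(), ann.nonsocial_mask(),
                             n_iterations=100, seed=4))
print(f"decoder accuracy: real {100*real.accuracy_mean:.1f}%  "
      f"surrogate {100*surr.accuracy_mean:.1f}%")

soc_ab = behavior_modulation(session.raster, ann, ("A","B"), "social",
                             "mean-difference", n_shuffles=2000, seed=5)
soc_cd = behavior_modulation(session.raster, ann, ("C","D"), "social",
                             "mean-difference", n_shuffles=2000, seed=6)
ok = soc_ab.valid() & soc_cd.valid()
print("social index correlation AB vs CD: "
      f"r = {np.corrcoef(soc_ab.index[ok], soc_cd.index[ok])[0,1]:.3f}")

ctx = context_modulation(session.raster, ann, (("A","B"),("C","D")),
                         n_shuffles=2000, seed=7)
rep = vector_similarity(soc_ab, ctx, "cosine", n_permutations=5000, seed=8)
print(f"social-vs-context cosine: {rep.observed:+.3f} "
      f"(permutation-null percentile {rep.percentile:.1f})")
```

Output:

```
decoder accuracy: real 53.5%  surrogate 49.9%
social index correlation AB vs CD: r = 0.375
social-vs-context cosine: -0.063 (permutation-null percentile 28.1)
```

Reading: the decoder finds real social structure (53.5% vs a 49.9% chance
level measured on the margin-preserving surrogate); the social modulation
index computed in one context correlates with the index computed in the
other (r = 0.375 — the social ensemble generalizes, as planted); and the
social vector is statistically orthogonal to the context vector (cosine
near 0, inside the central 95% of its permutation null — the two planted
ensembles were drawn independently).

End-to-end drivers with report tables are available both as functions
(`popcode.run_social_pipeline`, `popcode.run_maze_pipeline`) and from the
shell:

```bash
popcode simulate --mode social --seed 1 --out session_dir
popcode run-social --config config.yaml --seed 1 --out bundle_dir
```

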