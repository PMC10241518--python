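# gainscope

**A neural-network observer model of spatial attention: gain, its
receptive-field side effects, and which of them actually improves
behavior.**

Cueing spatial attention improves object detection, and physiology shows two
co-occurring neural correlates: response **gain** near the attended location
and **changes in receptive fields** (RFs shift toward the locus, shrink, and
change structure).  Because the two always co-occur in biology, they cannot
be disentangled experimentally — but they can in a model.  `gainscope`
implements a complete, fully synthetic version of that experiment for
computational-neuroscience use:

* a four-block CORnet-Z-style convolutional observer (V1/V2/V4/IT analogue;
  conv → ReLU → max-pool per block, average-pooled encoding, per-category
  logistic-regression readouts), implemented in NumPy with hand-written
  gradients,
* a stimulus generator for category image libraries and 2×2 **composite
  grids** (detection and discrimination protocols, pixel-scramble masks),
* a multiplicative **Gaussian gain** g(r,c) = (β−1)·exp(−((r−r₀)²+(c−c₀)²)
  /(2σ²)) + 1 applied to input pixels at the cued quadrant,
* gradient-based RF estimation (sensitivity maps → Gaussian moment fits →
  center, covariance, FWHM = 2√(2 ln 2)·σ) and **effective gain**
  (std ratio of unit activity with/without attention),
* three **counterfactual rewirings** that reproduce one RF consequence each
  while nulling gain — shift-only resampling, L2-preserving kernel
  restructuring, and distance-dependent kernel shrinkage
  f_β(d) = 1 − β·exp(−2.44 d²/112²)·cos(2.89 d²/112²),
* the **propagated-gain** necessity/sufficiency test (multiply a no-gain
  model's final feature maps by the measured per-position effective gain, or
  divide a gained model's maps by it),
* normalized exponentiation (winner-take-all amplification of small gains),
  masked spatial readouts, and
* behavioral statistics: d′ = Z(H) − Z(FA), the duration curve
  d′(t) = α·log(κt+1) (statsmodels-style `DPrimeCurveModel(...).fit()`),
  d′ = √2·Z(AUC), the closed-form EZ-diffusion transform, and seeded
  bootstrap CIs.

## Worked example

```python
from gainscope import ExperimentConfig, run_experiment, summarize

record = run_experiment(ExperimentConfig(seed=1))
print(summarize(record)[["condition", "median", "delta_vs_none"]])
```

This trains the observer on 8 synthetic texture categories at the full
224-px stimulus geometry (channel widths reduced to 16/32/64/128; about ten
CPU-minutes) and evaluates every attention condition.  Output from that
exact call:

```
               condition   median  delta_vs_none
                    none 0.799316       0.000000
            gaussian-1.1 0.811035       0.011719
              gaussian-2 0.893066       0.093750
              gaussian-4 0.939941       0.140625
             gaussian-11 0.962891       0.163574
           flat-isolated 0.905762       0.106445
              shift-only 0.800293       0.000977
               structure 0.807617       0.008301
                  shrink 0.802246       0.002930
     propagated-multiply 0.880859       0.081543
       propagated-divide 0.812012       0.012695
             masked-none 0.983887       0.184570
         masked-gaussian 0.984863       0.185547
     discrimination-none 0.734375            NaN
 discrimination-gaussian 0.843750            NaN
```

Reading the table: Gaussian gain at the cued quadrant raises median
detection AUC monotonically with strength (to 0.96 at β = 11).  The
strength β = 2 matches the human-scale cueing benefit of ≈ +0.09 median
AUC and anchors all downstream analyses.  A flat quadrant gain with
quadrant-isolated processing performs like the Gaussian (0.91, overlapping
CIs) — the *asymmetry* of the Gaussian is not needed.  The three rewired
models that reproduce the RF shift, structure, and shrinkage effects
**without** gain all sit within 0.01 of baseline: none of the RF side
effects carries the benefit.  Multiplying a no-gain model's output layer by
the propagated gain map recovers 87% of the benefit (0.88), and dividing it
out of a gained model returns performance to baseline (0.81, within 0.013) —
gain at the output is both sufficient and necessary.  A readout restricted
to the cued quadrant's output positions is already elevated with no gain at
all (0.98), showing that gain acts as a selection mechanism.  The same
ordering holds for criterion-free discrimination (0.73 → 0.84).

`record.tables["rf_gaussian"]` holds the per-unit RF analysis (shifts
toward the locus grow across blocks, from ~0.06 px in block 1 to ~5 px in
block 4, while RFs near the locus shrink), and
`record.tables["amplification"]` the normalized-exponentiation measurement
(a 1.1× gain is amplified to a 1.22× inside/outside effective-gain ratio at
exponent ξ = 3.8).  Behavioral estimators are validated by parameter
recovery on synthetic trial tables (focal/distributed sensitivity ratio
α ≈ 1.77 recovered for a generating ratio of 1.67; EZ-diffusion drift ratio
1.60 for a generating 1.61).

A thin CLI wraps the same pipeline:

```bash
gainscope -v run --seed 1 --out runs/demo
gainscope summarize runs/demo
```

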