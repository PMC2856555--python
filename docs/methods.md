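# Methods

## Instability quantification from fragment traces

A PCR across a CAG tract yields a cluster of fragment peaks one repeat unit
apart. The quantification pipeline is:

1. identify the tallest peak of the tail (reference) trace — the **main
   allele** — and record its fragment size and the animal's constitutive
   repeat count;
2. map every tissue peak to a signed integer offset
   Δ = round((size − main_size) / spacing), rejecting peaks whose residual
   from the nearest rung exceeds a tolerance; peaks colliding on one Δ are
   summed (a split peak, signal conserved);
3. within the tissue analysis, set the background threshold at
   `threshold_factor` × the tallest rung and discard rungs below it;
4. normalize surviving heights to their sum and form
   index = Σ w(Δ)·Δ.

Key choices:

* **threshold_factor** — fraction of the tallest peak, default **0.20**.
  Conservative: detects peaks of good signal intensity and is resistant to
  amplification variation; 0.10 or 0.05 give more sensitive quantification
  when signals are strong. The threshold is always computed from the tissue
  ladder's own maximum (per-analysis), which is what makes the index
  invariant to template amount.
* **Anchoring** — Δ is always measured from the *tail's* main allele, even
  when the tissue's own tallest peak has shifted; the shift itself is
  reported separately (`main_allele_shift`). An alternative anchoring to the
  tissue mode is available but not default.
* **unit_spacing** (default 3.0 bp/repeat) and **tolerance** (default 1.0 bp,
  required < spacing/2 so assignment is unambiguous) are exposed as
  configuration since instruments differ in effective mobility; an optional
  one-pass least-squares recalibration of the spacing (size regressed on
  assigned Δ) absorbs mobility drift.
* **Ties** — equal heights resolve to the smaller fragment size (or smaller
  Δ), consistent with the constitutive allele preceding its expansion
  products, and making every operation deterministic.
* **Exactness** — the index is computed as expansion_index +
  contraction_index, each an exactly rounded (`math.fsum`) sum over the
  shared denominator Σh. Consequences: additivity holds to the bit, and a
  height-symmetric ladder scores exactly 0.0 in floating point, not just
  approximately.
* The expansion/contraction split normalizes both parts by the sum over
  *all* above-threshold rungs (a shared denominator) rather than
  renormalizing within each subset; this is what makes the three indices
  mutually consistent.
* Degenerate inputs: an empty trace or ladder is an error; the tallest rung
  always survives thresholding, so the index is always defined.

The **small-pool index** consumes per-molecule repeat-length frequency
distributions (e.g. from single-molecule dilution PCR): frequencies are
normalized, anchored at the modal length (ties → smaller length), and the
frequency-weighted mean deviation from the mode is returned.

## Synthetic data generator

The generator provides ground-truthed inputs for every stage and defines the
conditions the test suite measures under.

**Somatic repeat distributions** are closed-form mixtures over Δ: a point
mass at 0, a geometric expansion tail over Δ ≥ 1 scaled to carry a requested
expected gain (`expansion_rate`; tail decay `tail_shape`), and a contraction
mass split 3:1 over Δ ∈ {−1, −2}. The construction is exact — the returned
object's `mean_delta()` is the true generating mean, enabling exact recovery
scoring downstream. Infeasible combinations (tail mass + contraction > 1)
raise.

**Trace rendering** models the two PCR artifacts that shape real traces:
slippage stutter, as a predominantly minus-one geometric kernel (mass
(1−s)s^k at −k; an optional +1 component defaults to 0), and the
amplification advantage of shorter alleles, as a monotone weight
(1 + amp_bias)^(−Δ). Heights are the distribution convolved with the stutter
kernel, bias-weighted, scaled to a total signal (the template-amount dial),
plus zero-truncated Gaussian noise; sizes sit at exact unit spacing. With
stutter, bias and noise all off, the measured index over all rendered peaks
equals the distribution's true mean exactly — the identity the simulator
tests exploit (using a threshold placed below the smallest rendered peak;
at the default 20% threshold the tail is truncated by design, so the
identity intentionally does not hold there).

Defaults: stutter_ratio 0.12, amp_bias 0.03, noise_sd 20 RFU on an
8000-RFU-total trace — values chosen once so that stable tissues render with
the slight contraction bias seen in real traces while high-instability
renders remain quantifiable.

**Tissue presets** define a 17-"tissue" panel whose noise-free rendered
indices span ≈ −1.03 (testis-like) to +6.38 (striatum-like), the range
observed across real mouse tissues, with the tail as stable reference. The
preset parameters were calibrated once, by grid search, against those target
indices and then frozen. Two features of the calibration are worth knowing:
high-index tissues need a long tail (`tail_shape` 0.94–0.95) because a
short-tailed geometric cannot carry a mean of 6 within unit mass; and under
a 20% threshold with unimodal distributions the measured index is quantized
near zero (a ±1 peak is either above threshold, contributing |Δ|·w ≳ 0.17,
or absent), so presets targeting tiny positive indices land at ≈ +0.2
instead. Strongly contracted presets (heart-, testis-like) place their modal
peak at Δ = −1, which the pipeline reports as a −1 main-allele shift.

**Expression matrices** are simulated directly at normalized log2 scale:
probe baselines ~ N(7, 1); planted signature probes respond to the tissue's
true instability index with slope ±effect_size (random sign per probe);
decoys are pure noise; replicate samples share their tissue's phenotype.
Defaults mirror the study design: 16 tissues × 2 replicates, 20,000 probes,
150 planted, effect_size 0.5, noise_sd 0.5 log2 units. The structure RNG
(which probes, signs, baselines) and the noise RNG are decoupled
(`seed` vs `noise_seed`), so two cohorts sharing `seed` are independent
replicate arrays of the same tissues — the natural train/test split.

What the generator does **not** emulate: electrophoretic mobility curves and
dye effects, sequence-context-dependent stutter, rare large expansions
(visible to small-pool PCR but not to bulk traces), array normalization
artifacts, and probe–probe correlation beyond the single planted latent
factor. Passing tests therefore demonstrate correctness of the computations
and recoverability under idealized but structurally faithful inputs, not
performance on real arrays.

## Signature model

Probes are ranked by the two-sided p-value of their Pearson correlation with
the phenotype (t-transform, ties broken by probe id; zero-variance probes
flagged and ranked last). The correlation is a ranking metric only — the
model itself is PLSR (mean-centered predictors and response, no
unit-variance scaling, matching the common default of R's pls family) on the
top-n probes, so the fit captures covariance structure rather than the
marginal association used for ranking.

Forward selection over n ∈ {5, 10, 25, 50, 75, 100, 150, 200, 300, 500}
(capped at the probe count) minimizes RMSEP under leave-one-**tissue**-out
cross-validation: all replicate arrays of a tissue are held out together,
and probes are **re-ranked within each fold** so that selection never sees
the held-out tissue. Without fold-internal re-ranking the CV error is
optimistically biased; the leaky variant is implemented behind a flag for
comparison, and a dedicated test asserts that corrupting a held-out tissue's
phenotype cannot change its prediction. Ties in the curve resolve to the
smaller n.

The PLS component count is not a free parameter: per fit, an inner
leave-one-group-out RMSEP over 1..max_components (default cap 10) picks it,
exploiting the nesting of PLS components (one K-component fit yields every
k ≤ K model by truncating the rotation/loading matrices — verified against
per-k refits). Requests beyond the data's rank are reduced. All fits are
deterministic; refitting identical data gives bit-identical coefficients.

Prediction is a linear map in original probe space (coefficients +
intercept, serializable to JSON); missing signature probes raise with the
missing ids; replicate arrays can be averaged per tissue on request.

## Pathway enrichment

Probes are ordered by signed Pearson correlation with the phenotype
(descending, ties by id). Each gene set is scored with the weighted
running-sum statistic: member probes increment by |r|^weight normalized over
the set, non-members decrement by 1/(N − m); the enrichment score is the
extremum of the walk, which starts and ends at zero. weight defaults to 1
(standard weighted form); weight 0 reduces to the classic
Kolmogorov–Smirnov statistic, which the tests verify exhaustively on small
universes. The permutation engine evaluates the walk only at hit positions
(its extrema can occur nowhere else), vectorized across permutations; a
dual-route test pins it to the direct cumulative-sum implementation.

Significance uses **phenotype permutation at the tissue level**: tissue
index values are shuffled across tissues and replicate arrays inherit their
tissue's permuted value, respecting exchangeability of the replicated
design (gene-permutation nulls are out of scope). Per set, NES = ES / mean
|same-signed null ES| and the nominal p is the fraction of same-signed null
scores at least as extreme, with a +1 pseudocount in numerator and
denominator so finite permutation counts never report p = 0. Set-size
filters default to 15–500 after intersection with the expression universe.

One statistical property of the tissue-block null is worth documenting:
when two tissues dominate the phenotype variance (as striatum- and
liver-like tissues do in the default panel), any permutation that preserves
that pair as a set keeps the permuted phenotype highly correlated with the
original (probability 2!·14!/16! = 1/120 for 16 tissues), which places a
floor of roughly 0.01–0.03 on the achievable nominal p of even a perfectly
coherent probe set. The enrichment power study therefore uses an evenly
spaced 16-tissue instability gradient over the same span, where the
granularity floor vanishes (planted-set p ≈ 0.002 at 1,000 permutations);
the calibration study (null phenotype association, ~5% of sets at p < 0.05)
is unaffected by this choice.

## Problem sizes used by the test suite

The suite runs the signature study at its native scale (16 × 2 samples,
20,000 probes, 150 planted) — one fit takes a few seconds thanks to the
component-path trick. Enrichment calibration uses a 2,000-probe universe
with 250 random sets and 1,000 permutations; power uses the full 20,000
probe universe. Oracle checks use 1,000 random ladders and exhaustive
subsets of universes up to N = 8.

## Known limitations

* The bulk-trace index underestimates instability dominated by rare large
  expansions; the small-pool index exists for that regime but requires
  single-molecule data.
* Repeat-unit assignment assumes sizes already calibrated upstream; raw
  electropherogram decoding is out of scope.
* The tissue-block permutation null is conservative for outlier-dominated
  phenotypes (see above); per-sample permutation would be anticonservative
  for replicated designs and is deliberately not offered.
* Only nominal permutation p-values are reported; no FDR across sets.
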