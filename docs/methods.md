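# Methods

## Model

A fractionation profile is the per-fraction abundance of one species in
one replicate, normalized to sum 1. The generative assumption is linear
mixing: a species distributed over compartments with weights `w` (a point
on the C-simplex) produces the `w`-weighted combination of the
compartment profiles. Compartments are not single canonical profiles but
distributions of similar profiles — marker proteins of one organelle vary
around a common sedimentation behavior — so the estimator is a regression
trained on observed marker profiles and on synthetic profiles drawn from
the marker distribution, not a template matcher.

The regression network is deliberately small: input `F`, one ReLU layer
whose width is a hyperparameter in `C + 0.4(F−C) … C + 0.6(F−C)` (floored
at `C` so the layer never bottlenecks below the output when `F ≤ C`), a
linear layer of size `C`, and an output head that clamps negative
activations at zero and divides by the sum so every output is a simplex
point. If all activations are clamped the output is uniform `1/C`; during
training such dead rows receive the raw mean-squared-error gradient on
their activations so they can re-enter the live region (with a zero
gradient they could never recover — observed as stalled training on
separable toy data before the fix). The output bias starts at `1/C` for
the same reason. Forward/backward passes, the three optimizers (SGD,
RMSprop with decay 0.9, Adam with 0.9/0.999) and early stopping are
implemented directly in NumPy; the matrices involved are tiny (at most a
few thousand × ~16), and a full training run takes well under a second on
one CPU.

## Training data

Per condition, replicate and optimization round:

* every compartment is upsampled to the largest marker-class size
  `N_max`: an artificial profile is the fraction-wise median of three
  randomly drawn marker profiles plus `N(0, (2σ_f)²)` noise, `σ_f` the
  fraction-wise s.d. of the three; negative values are clipped to zero
  and the profile renormalized (the clip-then-renormalize rule is our
  concrete reading of "rescaling to a plausible range");
* `round(0.05·N_max)` mixed profiles per ratio (25:75, 50:50, 75:25) per
  compartment are added, the partner compartment drawn uniformly at
  random per profile; the mixing ratio is the regression target.

Tuning (optimizer × log-uniform learning rate in `[1e-4, 1e-1]` × hidden
width) uses Hyperband-style successive halving with budget 20 epochs and
reduction factor 3. Final training runs up to 100 epochs with early
stopping at patience 5 on the 20% validation split (the 20-epoch cap
applies to the search, not the final fit; with patience 5 the final fit
rarely exceeds ~30 epochs). Batch size is 32 and the split is random
without stratification; both are exposed in the code. The ensemble
repeats augmentation + tuning + `runs` independent trainings for `rounds`
rounds (defaults 3 × 10; the acceptance runs use 1 × 3 with tuning off
and the documented midpoint defaults: Adam, learning rate 1e-3, hidden
width at the middle of the admissible range). All randomness flows from
one seed; per-replicate/round/run sub-seeds are derived deterministically
(CRC of the replicate key, `+1000·round + run`).

## Filtering

For each compartment `c` the filter collects the outputs that marker
proteins of *other* compartments receive on `c` — false positives by
construction — and sets the threshold `τ_c` at their 95th percentile
(linear interpolation between order statistics). Mean weights below `τ_c`
are zeroed and survivors renormalized into CC values. The collection
granularity matters and is configurable (`threshold_level`):

* `replicate` (default): one ensemble-averaged output vector per
  (marker, replicate) — the network outputs at the granularity at which
  they are defined, while the filter is applied to the across-replicate
  mean;
* `run`: every raw per-run vector (much noisier collection, markedly
  higher thresholds);
* `mean`: the fully aggregated per-species means (lowest thresholds).

With the default, a low fraction-to-compartment ratio (8 compartments
over 10 fractions) leaves roughly 4–6% of simulated species below every
threshold, and the effect nearly vanishes once the ratio reaches 2 —
the behavior that motivates recommending at least twice as many fractions
as compartments. Thresholds are computed per condition
(`threshold_scope: condition|global`). Argmax ties in localization calls
are broken by marker-list compartment order and flagged.

## Relocalization statistics

For species assigned in both conditions of a pair:
`RL_c = CC_c(g2) − CC_c(g1)` (sums to zero exactly), `RLS = Σ_c |RL_c|`
in `[0, 2]` with 2 iff the CC supports are disjoint. Welch's t
(`(w̄₂ − w̄₁)/√(σ₁²/n₁ + σ₂²/n₂)`, Welch–Satterthwaite degrees of
freedom, two-sided p) and Cohen's d (`(w̄₂ − w̄₁)/√((σ₁²+σ₂²)/2)`) are
computed per compartment on the unfiltered ensemble outputs; the default
sample unit is one raw vector per (replicate, round, run)
(`stat_samples: runs`), with per-replicate means as the alternative. The
distance score aggregates effect sizes as `DS = max_c |d_c|` (a ranking
score; `sum` is available). p-values are reported raw; a clearly labeled
Benjamini–Hochberg column is added per compartment but is not used for
any built-in decision. Degenerate cases: both variances zero gives p = 1
(equal means) or p = 0 (unequal), and d undefined (NaN).

## Composition

`SA = CC·Ī` (Ī the replicate-mean total intensity), `CA = Σ_s SA`,
`NA = SA/CA`, `CFC = log2 NA(g2) − log2 NA(g1)`. `CA` sums over all
species by default; `ca_mode: markers` restricts the sum to marker
species (the marker-intensity variant of organelle abundance — the two
definitions coexist in the field and disagree when many non-marker
species carry signal). No pseudocounts in CFC: a zero CC means "not in
this compartment", so the fold change is reported missing rather than
inflated. Total-omics missing values are imputed from
`N(µ − 1.8σ, (0.3σ)²)` computed on log2 intensities (the left-shifted
Gaussian convention for intensities missing not at random), globally per
table by default with a per-column option. Total-lipidome tables use
nearest-neighbor imputation instead (`k = 1` in log space, prediction
offset by the mean log difference over shared samples, truncated at the
observed minimum).

## Lipidome co-profiling

Lipid fractionation profiles are appended to the protein table as
additional species and share the filtering/normalization/prediction code
path; only proteins supervise the network. Molar amounts ≤ 1 pmol are
discarded before mol% normalization. Compartment-level lipid chemistry is
summarized as the amount·CC-weighted mean feature (total carbons or
double bonds) per fatty acid:
`q̄ = Σ_k q_k n_k CC_k / (f_L Σ_k n_k CC_k)`, where `f_L` is the number
of acyl chains of the class (built-in table: TAG 3, CL 4, diacyl classes
2, lyso/Cer/CE 1; overridable). The species-level total feature is used
and divided by `f_L` — the division only makes sense for species totals.

## Simulator

The generator emulates density-gradient centrifugation: the gradient axis
`[0, F]` is split into `C` equal windows; each single-compartment profile
draws a peak center uniformly within its compartment's window and a peak
s.d. uniformly from `[1.5, 2]` fractions, then bins ~200 (±10%) Gaussian
draws into the `F` unit-width fractions (draws off the gradient ends are
discarded). The draw is per species × replicate, so compartments are
overlapping distributions of profiles and species near window boundaries
genuinely resemble the neighboring organelle — the property that makes
filtering and error rates realistic. Intensities are the counts times a
per-species factor `U(5000, 8000)` with `±50` fluctuation of the factor
per fraction; mixtures are combined at the count level (before scaling)
so ratios refer to underlying mass. Default inventory per dataset: 75–125
annotated markers per compartment, 100–200 unannotated singles, 150–250
doubles per compartment (75:25 or 50:50, partner random), 20–80 triples
per compartment (50:25:25). Dropout: each (species, replicate) fully
missing with probability 0.04; in two-condition datasets each species
absent from one condition with probability 0.02 and relocalized (same
kind, assignment redrawn until it differs) with probability 0.01. The
accompanying total-proteome table is a simple log-normal stand-in
(per-species log2 mean `U(18, 26)`, replicate s.d. 0.3) sufficient for
exercising the composition pipeline; it is not calibrated to any real
proteome. What the simulator does **not** emulate: correlated
fraction-to-fraction noise, shared peaks between biologically related
organelles, intensity-dependent missingness, batch effects. Passing tests
on simulated data therefore demonstrate correct recovery under the
linear-mixing model, not robustness to real-data artifacts.

## Evaluation

Main-compartment calls are scored with per-class precision/recall/F1 and
the marker-count-weighted F1 (classes absent from the truth are excluded
from the weighting). Distribution recovery uses
`LE = Σ_c |true − predicted| / 2 ∈ [0, 1]` (halved because mass
overestimated in one compartment is necessarily missing from another).
Relocalization is scored through transport plans: for each species the
localization change is decomposed into origin→target flows by minimizing
transport cost under a 0/1 ground cost (compartments carry no metric
order, so all moves cost alike; a user cost matrix falls back to a linear
program). Under 0/1 cost the optimum keeps `min(P_i, Q_i)` in place; the
off-diagonal split is not unique, so the deterministic proportional plan
(outer product of residual marginals over total residual) is used for
both truth and prediction — the optimal cost, which equals `LE(P, Q)`, is
unique and is what the LP cross-check asserts. The relocalization-error
matrix is the element-wise mean `|plan_true − plan_pred|` over species
present (and assigned) in both conditions. Unassigned species count into
the unassigned fraction and are excluded from F1/LE denominators.

## Problem sizes and numerical choices

The acceptance script and the heavier tests run full-size simulated
datasets (≈ 2,900–4,500 species) but a reduced ensemble — one round,
three runs, tuning off — as their study condition; the full 3 × 10
ensemble is the analysis default. Tolerances: profile sums 1 ± 1e-9, raw
network outputs on the simplex ± 1e-6, transport marginals ± 1e-9.
Reduced ensembles leave more run-to-run noise in the per-replicate means,
which raises the false-positive thresholds and clips minor (≈ 0.25) true
contributions of multi-localized species more often; mean localization
error on doubles improves with ensemble size (e.g. 0.34 → 0.31 from 3 to
10 runs on the 8-compartment/16-fraction dataset) while single-localized
species are essentially unaffected.

## Known limitations

* Linear mixing ignores compartment crowding and gradient saturation.
* The false-positive filter is calibrated on markers; compartments with
  few or atypical markers get unstable thresholds.
* Relocalization statistics treat ensemble spread as measurement error;
  they quantify confidence of the model, not biological variance, and no
  absolute protein mass is estimated.
* The distance score formula (`max |d|`) is a ranking convention, not an
  inferential statistic.
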