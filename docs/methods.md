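# Methods

## Rankability and the δ meta-parameter

A pair of samples is rankable when the separation of their labels exceeds
a threshold δ: `f(y_i, y_j) ≥ δ_ij`.  Two modes are implemented.

* **indicator** — `f` is an indicator on label inequality and δ is fixed
  at 0.5, so any two distinct labels are rankable.  This is the right mode
  for binary classes and for ordinal stages mapped to integers (e.g.
  mild/moderate/severe disease encoded 0/1/2: two samples are rankable iff
  their stages differ).
* **absolute_difference** — `f = |y_i − y_j|` with δ either a constant or
  `max(σ_i, σ_j)` from per-sample technical-replicate standard deviations.
  The replicate rule encodes that a model cannot be expected to order two
  samples whose label difference is within measurement error.

Identical labels are never rankable in either mode — there is no ordering
to recover — so `constant_delta = 0` means "any strict difference".
Pairs are stored oriented (`hi` = larger label), which makes correctness
simply `score(hi) > score(lo)` for classification and regression alike.

When no δ specification is given, the library guesses: ≤ 10 distinct label
values looks ordinal → indicator mode; otherwise regression with
`constant_delta = 0`.  The guess is logged at WARNING level because it is
a fallback, not a recommendation; δ should come from replicate variance or
domain knowledge.  There is no principled default δ for regression tasks
without replicates, which is why the fallback is deliberately the weakest
possible threshold.

## AUC estimation

`AUC = Σ p_ij / |R|` with tie credit 0.5 (Mann–Whitney convention): a
constant predictor scores exactly 0.5 rather than 0, and on binary labels
the estimator coincides with the Wilcoxon–Mann–Whitney AUC to machine
precision (asserted in tests against `sklearn.metrics.roc_auc_score`).

Two paths compute it:

* **brute force** — scores every pair individually; works for any δ mode;
  the defining computation, and the oracle the fast path is tested against.
* **fast path** — valid for indicator-mode rankability only.  Samples are
  sorted by score ascending with score ties broken by ascending label;
  the number of label inversions in that order is exactly the number of
  strictly misranked rankable pairs, and tied-score cross-label pairs are
  counted separately for half credit:
  `AUC = (|R| − inversions − 0.5·tied) / |R|`.
  With per-pair δ thresholds an inversion need not be a rankable pair, so
  the fast path refuses `absolute_difference` mode rather than silently
  approximating.

Inversion counting is an iterative bottom-up merge sort.  Leaf blocks of
64 elements are tallied by direct pairwise comparison; sorted runs are
then merged pairwise level by level, and each merge adds, for every
right-run element, the number of left-run elements strictly greater than
it (equal values contribute nothing).  The per-merge bookkeeping is
vectorized with numpy (`searchsorted` against the sorted left run), which
keeps the python-level loop at O(n / leaf) iterations: 10^6 values count
in about a second on one CPU.  `return_comparisons=True` exposes the
element-comparison count for empirical complexity checks (doubling n from
10^5 to 2·10^5 raises the count by ~2.1×, far from quadrupling).

Ties are everywhere the delicate part: the tie credit (0.5), the sort
tie-break (label ascending, so within-tie pairs produce no inversions),
and the separate tied-pair tally were chosen together so that the fast
path equals brute force exactly on every instance, which the test suite
asserts on hundreds of random instances with and without ties.

## Cross-validation

Paired evaluation needs only pooled out-of-sample scores, so any CV scheme
works.  The harness provides:

* **LPOCV** — one model per rankable pair, trained on everything except
  the pair's two samples; the verdict compares the two held-out scores
  from the same model.  Training one model per *rankable* pair (not per
  unordered pair) keeps cost proportional to |R|.
* **k-fold / LOO / Monte Carlo** — standard schemes; a sample scored
  several times (Monte Carlo) gets the arithmetic mean of its out-of-fold
  scores, with the multiplicity recorded.  Incomplete coverage is an
  error, not a silent gap.

Models plug in via a three-method adapter (`fit(X, y, seed)` →
state, `score(state, X)` → scores, `importances(state)` → named vector or
None).  Scores are always oriented "higher = larger predicted label"
(probability of the positive class in classification).  Per-fold seeds are
derived via `numpy.random.SeedSequence(seed, spawn_key=(fold,))`, giving
decorrelated yet fully reproducible fits; repeated runs with the same plan
are bit-identical for deterministic adapters.  k-fold assignment is a
seeded shuffle followed by a contiguous split, unstratified — matching the
plain schemes the method is usually compared across.

A caution that the simulation studies made concrete: pooled LOO scores
carry a small anti-correlated bias (each held-out prediction is pulled
toward a training mean that excludes that sample), which depresses the
pairwise AUC when the signal is weak.  LPOCV does not suffer from this
because each verdict compares two scores from the same model.

## Model comparison

Two verdict lists on the same pairs produce a *marginal* table
(model × correct/incorrect, Fisher's exact test) and a *paired* table
(both correct / only A / only B / both incorrect, exact McNemar on the
discordant cells as a Binomial(b+c, ½) tail).  McNemar's test can detect
that two models with indistinguishable AUCs succeed on different pairs.
Exact forms are used throughout — the package targets datasets of tens of
samples, where χ² approximations are unreliable.  Half-credit (tied)
verdicts are counted as incorrect for both models by default, since exact
tests need integers and this is the conservative resolution; a
`tie_policy="exclude"` flag drops tied pairs instead.

Fisher's two-sided p sums all tables with the observed margins whose
probability does not exceed the observed table's (the standard exact
convention; stated explicitly because conventions differ).  The
implementation delegates to `scipy.stats`; the test suite checks it
against an independent full hypergeometric enumeration for hundreds of
tables up to N = 40, and McNemar against hand-computed binomial tails.

`compare_correctness_tallies` additionally exposes a one-sided Fisher
contrast of two correct/incorrect tallies *as given*, including the
common presentation where an all-pairs column is contrasted with its own
matched subset; the library's own confounder test (below) uses disjoint
rows, which an exact test formally requires.

## Outlier detection

`AUC_k` restricts the tally to the pairs R_k containing sample *k*.  The
scan builds, per sample, the 2×2 table (in-R_k / not-in-R_k ×
correct/incorrect) and applies a one-sided Fisher test with the
alternative that pairs containing *k* are more likely misranked, then
Benjamini–Hochberg across all scanned samples (a scan over n samples is n
hypotheses; raw p values are reported alongside).  Useful identities,
asserted on every test instance: Σ_k |R_k| = 2|R|, Σ_k credit_k = 2·credit,
and removing sample *k* shrinks the pair set by exactly |R_k|.

Removal is advisory.  `remove_and_reevaluate` rebuilds the pair set
without the sample and retrains every LPOCV model from scratch (the
honest, more expensive route), optionally returning full-fit feature
importances before and after for interpretation.

## Confounder-matched evaluation

Discrete confounders: pairs partition exactly into matched (equal values)
and mismatched.  Continuous confounders, possibly censored at a bound
(e.g. age recorded as "90+"): for each index sample, one *matched* pair —
the rankable partner minimizing the confounder gap, where two censored
values count as gap 0 (one censored category) — and one *mismatched* pair
per strategy: the maximal-gap partner, a random partner from the censored
category (drawn without replacement across index samples while fresh
candidates remain, then with replacement; seeded), or all remaining
pairs.  Ties break on the smallest partner id, so selection is
deterministic given (spec, seed).  This gives each data point its
minimal- and maximal-separation pair along the confounding variable.
Considering *all* partners within a gap window instead of one per sample
is available as the `all_remaining` strategy but is not the default.

`confounder_effect` reports AUC over all, matched, and mismatched pairs,
ΔAUC = AUC_all − AUC_matched, and a one-sided Fisher test on the disjoint
matched/mismatched × correct/incorrect table (alternative: matched pairs
are more likely misranked).  A significantly positive ΔAUC indicates the
predictor has at least partially learned the confounder.  `anova_f`
(one-way ANOVA of the label across confounder groups) quantifies how
strongly the label itself tracks the confounder — the settings where a
large ΔAUC is to be expected.  The package diagnoses confounding but does
not correct for it: the data are never modified.

## Synthetic data

The generator emulates the structure the diagnostics target, not the
marginal distributions of any particular assay: Gaussian features, a
signal block (first `n_signal_features` columns) whose mean drives the
label, a disjoint confounder block shifted by the confounder value, label
noise, technical replicates (the per-sample SD of `n_replicates` label
re-draws, feeding replicate-based δ), and injected outliers.

`label = beta_signal · mean(signal features) + beta_confounder · c + N(0, noise_sd)`

with `c` the binary confounder or the standardized continuous one
(uniform ages 65–95, censored at 90 in output tables).  Outlier injection
targets are drawn from the outer label quartiles and their label is
replaced by a uniform draw from the opposite outer decile, features
untouched — a sample whose molecular profile clusters with one response
group while its recorded response resembles the other.  An opposite-tail
flip is only meaningful for a sample that sits toward one side, hence the
quartile restriction.  Injection changes nothing but the flagged samples'
labels, and everything is reproducible from the seed.

What passing simulations do *not* show: robustness to count-distributed
(RNA-seq-like) features, correlated gene modules, or batch structure
beyond a single shifted block.  The generator exercises the evaluation
machinery; it is not a transcriptome simulator.

## The canonical studies (`paireval.studies`)

Fixed once as study designs:

* **Confounder recovery** — n = 60 samples, generator defaults (100
  features, unit confounder feature shift), δ = 0.3, ridge scores pooled
  from LOO (any pooled-CV scheme is valid for paired evaluation and LOO
  keeps a 50-seed study at a few seconds).  Confounded condition:
  beta_signal = 0, beta_confounder = 1 — median ΔAUC ≈ 0.19–0.20 with the
  one-sided Fisher p < 0.01 in essentially every seed.  Clean control:
  beta_signal = 1, beta_confounder = 0 — median |ΔAUC| < 0.01.
* **Outlier recovery** — n = 40 samples, 40 features, strong signal
  (beta_signal = 2, label noise 0.1), one injected flip, δ = 0.3, ridge
  LPOCV.  The injected sample is the top-ranked scan hit (by adjusted p)
  in ≥ 90% of 50 seeds; overall AUC ≈ 0.77, comparable to the regime in
  which the diagnostic is used in practice.  Forty features rather than
  100 because ridge shrinkage at p/n = 2.5 caps LPOCV AUC near 0.70,
  leaving too little headroom between "model error" and "outlier" for the
  enrichment test to separate them reliably.

## Numerical conventions and edge cases

* AUC is kept at full precision internally; two-decimal presentation
  rounds half up.
* Empty rankable set → AUC is an error (undefined), never NaN or 0.
* Non-finite scores, missing replicate SDs in replicate mode, missing
  confounder values, and duplicate sample ids raise typed errors naming
  the offending sample/fold.
* Verdict credit is constrained to {0, 0.5, 1} at construction.
* TSV vs CSV is decided by file extension; labels ascending always mean
  "more" of the endpoint, scores ascending "predicted more".

## Known limitations

* The outlier scan tests one sample at a time; groups of samples sharing
  a misranking pattern (a hidden batch) are out of scope.
* Fisher p-values across overlapping pair sets (a pair contributes to both
  samples' R_k) are not independent; BH is used as a pragmatic control,
  not an exact guarantee.
* Continuous-confounder selection assumes a single confounder column;
  multivariate matching is not implemented.
* Feature importances are reported as-is; the package does not attribute
  importance to confounder vs signal.
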