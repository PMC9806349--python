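# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic cohorts do and do not emulate, and the numerical
conventions a user relying on the results should know.

## Dynamic FC construction

Windows are half-open `[o, o+w)` in 0-based time indexing, advanced by step
`s`; the count is `K = ⌊(M−w)/s⌋ + 1` and trailing time points not covered
by a full window are dropped. Defaults `w = 30`, `s = 2` time points are
the standard sliding-window choice for ~3 s TR acquisitions (window ≈ 90 s);
both are in time points — seconds↔TR conversion is the caller's concern.
Pearson correlation is computed per window; a zero-variance sub-series
makes the coefficient undefined and the affected entries are set to 0 with
a warning, a neutral value that neither attracts nor repels under cosine
similarity. Values are clipped to [−1, 1] against floating-point overshoot
and the diagonal is set to exactly 1.

The P = N(N−1)/2 pair series are ordered by scanning the lower triangle
row by row (`np.tril_indices` order); each entry of `pair_index` is stored
as `(i, j)` with `i < j`. This order is fixed across the codebase and
recorded in every serialized container.

## Self-attention layer

Tokens are ROI-pair FC series (rows of the P×K matrix); the feature axis is
the K windows, and softmax normalizes each query row over the P key tokens.
`W_V` is K×K so the output preserves the input shape; `d_k` defaults to K.
One head, no residual, no layer norm — the layer is deliberately the
minimal learnable reweighting.

**Initialization.** The projections are anchored at scaled identity maps
(`W_Q = W_K = gain·I + ε`, `W_V = I + ε`, noise ε of scale `0.05/√K`).
A pure zero-mean initialization makes all attention scores ≈ 0, the softmax
over P tokens uniform, and every output row equal to the same mean Value
vector — pair identity, which carries the method's signal, is erased before
training starts. Anchoring at the identity makes the untrained network
behave approximately like the unweighted per-pair comparison, so training
starts from a meaningful similarity measure. `identity_gain` defaults to 3;
`identity_gain=0` recovers the fully random alternative for ablation.
Because FC-series tokens are mutually correlated, self-attention mass
saturates well below 1 even at large gains; the anchor sets the direction
of the initial map, not a hard diagonal attention.

**Gradients.** No autodiff framework is used. The reverse-mode gradient of
the attention → cosine → aggregation → contrastive-loss chain is derived
and implemented explicitly (`attention_backward`,
`_cosine_similarity_with_grads`); the test suite validates it against
central finite differences to 1e-4 relative tolerance at random parameter
points, and at the hinge point of the loss the subgradient 0 is used.

## Similarity and aggregation

Per-pair cosine over the K windows is symmetric, invariant to positive
rescaling of either subject, and exactly invariant under any window
re-ordering applied jointly to both subjects — inter-subject window phases
are matched by construction. Zero-norm series yield cosine 0 with a
warning, consistent with the neutral-FC convention. The subject-level
aggregate defaults to the **mean** of the P cosines so the similarity stays
in [−1, 1] and the contrastive margin is meaningful independent of N; the
raw summed variant is available via `aggregation="sum"`.

Discriminative-pair ranking scores each ROI pair by the absolute difference
in mean similarity between NC queries and patient queries against a shared
support set, averaged over the two support classes; signed per-class
differences are reported alongside, and ties break in pair order. The
re-folded average similarity matrix sets its (cosmetic) diagonal to 1.

## Training

Adam (β = 0.9/0.999), one step per epoch on the mean contrastive loss over
freshly sampled scan pairs (default 256/epoch, 50% same-class, 50 epochs).
Pair labels follow y = 1 for same-category pairs. The margin defaults
to 1.0 under mean aggregation.

The default learning rate is **1e-4**. At 1e-3 the objective reliably
collapses the similarity representation on cohorts like the synthetic
default within ~10 epochs: the loss falls while few-shot accuracy drops to
chance, because amplifying the component common to all subjects is the
steepest way to satisfy same-class pairs. Two guards are built in: the
smaller default step, and **validation-based epoch selection** — after each
epoch a small fixed few-shot probe runs on the validation split and the
returned parameters are those of the best-scoring epoch (the pre-training
baseline included). This is early stopping in selection form and is what
the pipeline uses; `train()` without a validation cohort returns the final
epoch. Non-finite losses or gradients raise a training error immediately.

Scans pair at scan level, but the train/validation/test split assigns whole
subjects (largest-remainder apportionment per class, default 60/20/20), so
multi-scan subjects can never leak across splits.

## Few-shot protocol

2-way episodes with `n_shot` supports (default 5) and up to `n_query`
queries (default 5) per class, sampled without replacement within an
episode; supports and queries are disjoint by construction. The decision
rule compares the query's mean similarity to each class's supports
(`nearest` single-support rule available); exact ties go to NC. Patient is
the positive class for TP/TN/FP/FN. Metrics are pooled over episodes
(micro-average); per-episode accuracy mean/sd are reported as the macro
view. Ratios with empty denominators return NaN markers, never exceptions.

## Synthetic cohorts

Each scan mixes independent band-pass-filtered Gaussian sources: a global
factor (background coupling `c` between every pair), one shared factor per
altered pair, and per-ROI private noise, with loadings chosen so the
instantaneous correlation is `c` everywhere except at altered pairs, where
patients get `c + sign·effect`. White measurement noise (sd 0.1) attenuates
every correlation by `1/(1+sd²)`; the ground-truth record carries the
resulting closed-form expectations, and a Monte-Carlo test confirms the
generator hits them.

Default study conditions: 20 ROIs, 137 time points, 40 subjects per group,
one scan each, 5 disjoint altered pairs, `base = 0.35`, `effect = 0.6`
with **negative sign**, i.e. NC +0.35 vs patient −0.25 at altered pairs.
The sign matters: with same-sign couplings the weak-coupling group is
noise-dominated at the altered pairs, its FC series do not align within
class, and a cosine comparison is structurally asymmetric (the weak class
looks *more* similar to the strong class than to itself) — no effect size
rescues that regime. Oppositely signed coupling is the regime in which a
cosine-of-FC-series comparison genuinely carries a strong effect, and it is
what the recovery experiments use. Patient coupling additionally oscillates
slowly (amplitude 0.07 of the effect, period 45 time points, random phase
per scan) so FC series, not just their means, differ between groups. The
Butterworth band (0.09–0.9 of Nyquist) mirrors a 0.015–0.15 Hz BOLD band at
TR = 3 s.

Not emulated: hemodynamic response shape, head motion and scanner
artifacts, inter-subject anatomical variability, site effects, and
realistic whole-brain covariance beyond the single global factor. Passing
recovery tests therefore demonstrates that the pipeline detects planted
dynamic-coupling differences under controlled conditions — not clinical
performance on real rs-fMRI.

## Problem sizes in tests and the acceptance script

Unit and property tests run at toy sizes (N ≤ 6, K ≤ 12). The recovery and
null experiments use the default 20-ROI/40-per-group cohorts with 50–60
evaluation episodes — large enough that the pooled null accuracy's binomial
99% interval (±0.053 at n = 600) comfortably contains the observed
across-seed dispersion (sd ≈ 0.02), and small enough that the entire suite
and the acceptance script each finish in well under a minute on one CPU.
The 116-ROI scale (P = 6670) is supported but not exercised by default.

## Known limitations

- Attention is single-head with data-correlated tokens, so it cannot
  produce an exact per-pair identity map; the identity anchor is an
  approximation whose quality degrades as FC series become collinear.
- The contrastive landscape has a genuine collapse basin; the lr default
  and validation selection mitigate it but aggressive settings (lr ≥ 1e-3,
  no validation cohort) can still reach it.
- The mean aggregation dilutes few-pair effects by 1/P; for very large N
  with small planted sets, sum aggregation with a rescaled margin, or
  attention trained long enough to concentrate on informative pairs, is
  required.
- `classify_query`'s decision rule (class-mean similarity) is a design
  choice, not derived from the training objective; the `nearest` rule is
  provided for sensitivity analysis.
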