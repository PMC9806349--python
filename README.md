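# pairfc

Pairwise dynamic functional-connectivity (FC) similarity for two-group
resting-state fMRI classification, evaluated in a few-shot protocol.

Early mild cognitive impairment alters resting-state functional
connectivity between a limited set of brain regions rather than across the
whole brain, and labeled clinical cohorts are small. `pairfc` targets
exactly this regime: instead of fitting a high-capacity classifier to
scarce labels, it *compares subjects pairwise* — two subjects from the same
group should have similar connectivity dynamics at corresponding ROI pairs
— and classifies a new scan by its similarity to a handful of labeled
support scans. It is intended for methods researchers working with
ROI-level BOLD time series (e.g., AAL-parcellated rs-fMRI) who need a
metric-learning baseline that runs on plain tabular inputs.

## Method

Given a scan `X ∈ R^{N×M}` (N ROIs, M time points):

1. **Dynamic FC network.** A sliding window of length `w` and step `s`
   yields `K = ⌊(M−w)/s⌋ + 1` overlapping segments; each segment's Pearson
   correlation matrix `D(k) ∈ R^{N×N}` is a short-term FC network. Since
   every `D(k)` is symmetric with unit diagonal, the dynamic network is
   flattened to `D ∈ R^{P×K}` with `P = N(N−1)/2` lower-triangle ROI pairs;
   row `p` is the FC *series* of one ROI pair.
2. **Self-attention weighting.** ROI pairs contribute unequally to group
   discrimination, so a learnable single-head self-attention layer over the
   P pair-tokens reweights the FC series:
   `D̂ = softmax(QKᵀ/√d_k)·V` with `Q = D·W_Qᵀ`, `K = D·W_Kᵀ`,
   `V = D·W_Vᵀ`; `W_V` is K×K so `D̂` keeps the P×K shape of `D`.
3. **Subject similarity.** For subjects `p, q`, each ROI pair contributes
   `cos(D̂_i^p, D̂_i^q)`; aggregating the P cosines (mean by default, raw
   sum available) gives the subject-level similarity `s`. The element-wise
   cosine keeps window phases matched between the two subjects.
4. **Siamese training.** Both scans of a labeled pair pass through the
   *same* attention parameters, and the contrastive loss
   `L = (1−y)s² + y·max(margin−s, 0)²` (y = 1 for same-group pairs) is
   minimized with Adam; a few-shot probe on the validation split selects
   the best epoch.
5. **Few-shot evaluation.** 2-way K-shot episodes are drawn from the
   held-out test split; a query is assigned the class whose support scans
   it is most similar to on average, and pooled confusion counts yield
   ACC, SPE, PPV and NPV (patient = positive class).

Because clinical rs-fMRI cannot be redistributed, the package ships a
synthetic cohort generator (`pairfc.synthdata`) that plants group-dependent
coupling in a designated subset of ROI pairs of band-limited latent-factor
signals, with a ground-truth record for recovery scoring.

## Worked example

```python
from pairfc import (CohortSpec, generate_cohort, prepare_cohort, SlidingWindowConfig,
                    init_params, split_cohort, train, LossConfig, TrainConfig, evaluate)

spec = CohortSpec(seed=11)                       # 20 ROIs, 137 tp, 40 subjects/group,
scans, truth = generate_cohort(spec)             # 5 planted ROI pairs, effect 0.6
cohort = prepare_cohort(scans, SlidingWindowConfig(window_length=30, step=2))
tr, va, te = split_cohort(cohort, seed=12)       # subject-level 60/20/20 split
params = init_params(cohort[0].fcm.n_windows, seed=13)
state = train(tr, params, LossConfig(), TrainConfig(seed=14), val_cohort=va)
result = evaluate(te, state.params, n_shot=5, n_query=5, n_episodes=50, seed=15)
```

Output of the example (printing the quantities as they are computed):

```
scans: 80 | N ROIs: 20 | time points: 137
ROI pairs P: 190 | windows K: 54
training loss: 0.4304 -> 0.4076 (selected epoch: -1)
pooled 2-way 5-shot: ACC=1.000 SPE=1.000 PPV=1.000 NPV=1.000
```

The 137-point scans give K = 54 windows of length 30 at step 2, and the 20
ROIs give P = 190 FC series per scan. The contrastive loss falls over the
50 epochs; the validation probe selects the pre-training baseline here
(epoch −1) because the planted effect is already fully separable at the
identity-anchored initialization. On the held-out test split, all 300
pooled queries are classified correctly — the planted five-pair coupling
difference is far above the noise floor of these study conditions.

The same pipeline is available from the shell:

```bash
pairfc init-config --out pairfc.yaml       # all defaults, editable
pairfc run --config pairfc.yaml --seed 1 --out results_run
pairfc simulate --seed 1 --out cohort      # TSV scans + manifest
pairfc rank-pairs --manifest cohort/manifest.tsv --out ranked
```

`pairfc run` writes the resolved config, checkpoint, metrics JSON/TSV, four
average query-vs-support similarity matrices and the top-10 discriminative
ROI-pair table under the output directory.

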