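# cellfusion

Cellular-level survival prediction from whole-slide pathology images (WSI):
per-window cell-type abundance maps, a dual global-fusion risk network
trained with the Cox partial likelihood, and the survival statistics to
evaluate it.

## Who this is for

Computational-pathology researchers who already run block-wise nuclei
segmentation/classification (e.g. a HoVer-Net-style tool emitting per-block
JSON with nucleus centroids and PanNuke classes) and want a fully automatic
route from that output to patient-level survival risk — without hand-crafted
nuclear-morphology features and without patch-level black boxes.

## The method

A gigapixel slide is reduced to a 3-channel **embedded map**: nuclei are
merged from the six PanNuke classes into neoplastic (tumor), inflammatory
(immune) and miscellaneous, and each 64 × 64 px window stores the count of
each class — a 64-fold lateral reduction that preserves the spatial layout
of the tumor microenvironment exactly (channel sums equal nucleus counts).

The map, resized to a fixed resolution R and log1p-normalized, feeds a
**dual-branch network**:

* a Mixer branch (token-mixing + channel-mixing MLPs in residual paths)
  captures the *global* composition and distribution of cell types;
* a ViT branch (pre-norm transformer encoder with multi-head self-attention
  over patches) captures *inter-patch* context and long-range cell-to-cell
  structure.

Each branch mean-pools its tokens to a 128-vector; the fused input to the
final fully connected risk head is `[z_mixer; z_vit; mu]` — length
2·128 + 1 = 257, where mu is the patient's event indicator (a documented
leakage concern; a `mask_event` flag zeroes it and all evaluations report
both variants).  The model emits a scalar risk r on the Cox
linear-predictor scale and is trained with the negative Cox log partial
likelihood

    loss = sum_i  mu_i * ( -r_i + log sum_{j : t_j >= t_i} exp(r_j) )

(Breslow ties, batch-level risk sets).  Evaluation uses the concordance
index, Kaplan–Meier curves, the two-sided log-rank test and a quantile-grid
optimal risk cutoff; cohorts are split with stratified randomized five-fold
cross-validation balanced on half-year survival bins × event status.

The network, its analytic backward pass and the Adam optimizer are
implemented in numpy; gradient correctness is pinned by finite-difference
checks in the test suite.  A built-in synthetic-data module generates nuclei
tables, embedded maps and proportional-hazards outcomes with known ground
truth, so the whole pipeline is testable end to end without clinical data.

## Worked example

```python
from cellfusion import (
    SyntheticCohortSpec, generate_cohort, prepare_dataset,
    desk_model_config, desk_train_config, train, evaluate, concordance_index,
)

spec = SyntheticCohortSpec(n_patients=200, seed=7)      # known planted hazard
maps, records, truth = generate_cohort(spec)
dataset = prepare_dataset(maps, records, resolution=64)
train_set, test_set = dataset.subset(range(160)), dataset.subset(range(160, 200))

model, manifest = train(train_set, desk_model_config(seed=0), desk_train_config(seed=0))
metrics = evaluate(model, test_set)

print(f"ceiling C-index of the true hazard: "
      f"{concordance_index(truth.eta, dataset.times, dataset.events):.3f}")
print(f"final training loss: {manifest['epoch_losses'][-1]:.3f}")
print(f"held-out C-index: {metrics['cindex']:.3f} "
      f"(event-masked {metrics['cindex_event_masked']:.3f})")
print(f"log-rank chi2 {metrics['logrank_chi2']:.2f}, p = {metrics['logrank_p']:.3g} "
      f"at risk cutoff {metrics['cutoff']:.3f}")
```

prints (a few minutes on one CPU core):

```
ceiling C-index of the true hazard: 0.873
final training loss: 1.120
held-out C-index: 0.754 (event-masked 0.754)
log-rank chi2 24.02, p = 9.51e-07 at risk cutoff 4.026
```

Reading: the generator planted a composition-driven hazard whose true linear
predictor ranks outcomes at C = 0.873 (the oracle ceiling); after 30 desk-
profile epochs the model ranks 40 held-out patients at C = 0.754, and
dichotomizing at the training-derived cutoff separates their survival curves
at p ≈ 1e-6.  Risks are on the Cox linear-predictor scale — only their
ordering and the induced grouping are meaningful.

The same stages are available from a shell via the `cellfusion` CLI
(`ingest`, `embed`, `synth`, `split`, `train`, `eval`, `cv`, `project`);
see `cellfusion --help`.

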