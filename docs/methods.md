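# Methods

## Problem and model

`deathscreen` classifies cell-painting field images from a high-content
cell-death screen into three states — healthy, apoptosis, ferroptosis. The
experimental unit is a well of a multi-well plate, treated with one inducer
at one dose (or DMSO solvent) and imaged at 9–11 field positions in four
fluorescence channels (ER, Actin/Golgi, Mitochondria, Nuclei). Per-well ATP
luminescence, normalised to the plate's DMSO controls, measures residual
viability.

The classifier is a serial network: a convolutional backbone maps a
4-channel crop to a feature vector; an embedder (fully connected stack,
default widths 512→128) maps features to an embedding; a classifier head
(default 64→3) produces class logits from the pre-normalisation embedding.
Training minimises

    L = λ₁ · L_sup + λ₂ · L_ce,     λ₁ = λ₂ = 0.5

where `L_ce` is categorical cross-entropy (mean over the batch) and `L_sup`
is the supervised contrastive loss over L2-normalised embeddings z_i with
labels y_i:

    L_sup = Σ_i  (−1/|P(i)|) Σ_{p∈P(i)} log [ exp(z_i·z_p/τ) / Σ_{a∈A(i)} exp(z_i·z_a/τ) ]

with A(i) the batch without anchor i, P(i) its same-class members, and
temperature τ = 0.1. Anchors with no positives contribute zero (the 0/0
convention; it keeps skewed batches and the λ₁ = 0 ablation well defined).
The loss is a sum over anchors as written; a mean reduction is available
behind a flag for learning-rate portability. Because embeddings are
unit-normalised upstream, the inner products are cosine similarities.

## Batch-aware sampling

Plate-to-plate acquisition drift (gain, offset, focus) is the dominant
nuisance signal in screening images. Each training batch is therefore
composed as bs = n_plates × n_samples × n_classes (default 30 = 2 × 5 × 3):
two plates, and per selected plate five samples of each class. Every anchor
then has positives on *another* plate and negatives on its *own* plate, so
the contrastive objective must align class signal across plates rather than
memorise plate appearance. When a (plate, class) cell has too few items the
sampler resamples with replacement, falling back to the same class on the
other selected plate; a `skip` policy drops unsatisfiable batches instead.
Plates are drawn uniformly without replacement per batch; one epoch visits
each item about once in expectation.

## Data model and filtering

- ATP normalisation: per plate, raw luminescence divided by the **median**
  of the plate's DMSO wells (median for outlier robustness). The median
  DMSO well maps to exactly 1.0.
- Viability filter: treated wells are kept when normalised viability lies in
  the closed interval [0.3, 0.8] — affected but not dead. Healthy/DMSO wells
  sit near 1.0 and would all be excluded, so they bypass the filter; the
  window applies to treated wells only.
- Titration design: five doses per compound in a two-fold series anchored at
  the IC50 — [2·IC50, IC50, IC50/2, IC50/4, IC50/8].
- Images: planar or interleaved 4-channel TIFF; integer data are scaled by
  the dtype maximum, then each channel is stretched to its 1st–99th
  percentile range and clipped to [0, 1]. The percentile stretch is
  per-image and per-channel; it is recorded in the config so it can be
  switched to global statistics.
- Coordinates are (channel, row, col), 0-based, row 0 at top; crops use
  half-open intervals.

## Augmentation and inference

Five crops (four corners + center) are taken from each field; the reference
geometry is 512² crops of a 1320×1024 acquisition, with the crop size
scaled down for smaller synthetic fields. During training each sampled
field contributes one uniformly chosen crop, then horizontal flip, vertical
flip, k·90° rotation (k ∈ {1,2,3}) and additive Gaussian noise
(σ = 0.01 on the unit scale) are each applied with probability 0.5 in that
fixed order. At inference no stochastic augmentation is applied: per-field
class probabilities are the mean over the five crops' softmax outputs, and
per-field embeddings are the L2-renormalised mean of the five crop
embeddings.

Wells are labelled by majority vote over their fields. Vote ties are broken
by the larger summed probability across the tied classes, then by the fixed
order healthy < apoptosis < ferroptosis, and flagged `tie_broken`.

## Backbones and the numpy engine

The network layer is a small self-contained numpy engine (im2col
convolution, batch normalisation, linear layers, Adam) with analytic
backward passes that the test suite checks against finite differences.
Convolution accumulates channel by channel in fixed order; this makes the
RGB→4-channel first-layer adaptation (fourth kernel channel = element-wise
mean of the three) reproduce the original 3-channel convolution exactly on
inputs whose fourth channel is zero.

Backbones are pluggable. The shipped `tiny-cnn` (three stride-2 conv
blocks, 16/32/64 channels, global average pooling, feature_dim 64) trains
from scratch on one CPU core in a few minutes per desk-scale run. An
ImageNet-pretrained EfficientNet-b0 is the intended production backbone and
can be attached through `register_backbone`; nothing in the pipeline depends
on which backbone is used.

Batch-norm layers are frozen by default: running statistics are used in
every pass and never updated, and the affine parameters are excluded from
the optimizer. A sample's output is then independent of the rest of its
batch, which the suite asserts.

## Synthetic screens

The generator emulates the screen's design, not its optics. Per field, a
Poisson number of elliptical cells (mean 25) is rendered as Gaussian blobs:
nucleus (Nuclei channel), soft cytoplasm (ER), a cortical ring (Actin/Golgi)
and scattered granules (Mitochondria). Dose–response follows a Hill curve
v(d) = 1/(1 + (d/IC50)^h); raw ATP is the plate's DMSO level × v × (1 + ε)
with multiplicative Gaussian noise (σ = 0.05, truncated positive). The
fraction of phenotype-expressing cells in a well is 1 − v, coupling
morphology to the ATP readout so the [0.3, 0.8] filter selects exactly the
visibly affected wells. Affected cells express:

- apoptosis — footprint shrink (×0.6), nucleus fragmented into 3–6 bright
  puncta scattered over the *original* footprint (so they resolve as
  separate connected components), membrane blebs on the actin channel;
- ferroptosis — rounding towards circular, mitochondria granules attenuated
  (×0.25), smaller and more numerous (finer granularity).

Per-plate batch effects are a channel gain (log-normal, σ = 0.15 by
default, 0.6 in the "strong" ablation setting), an additive offset
(σ = 0.01) and a defocus blur (half-normal σ = 0.4 px). Default design: 3
plates × (4 compounds × 5 doses + 4 DMSO wells) × 9 fields at 256² px,
written as 16-bit TIFF plus manifest/ATP CSVs, byte-identical under a fixed
seed.

What the generator does **not** emulate: realistic textures and PSFs, cell
overlap/confluence effects, field-position (edge) effects, channel
crosstalk, segmentation artifacts, or compound-specific morphology beyond
the class phenotype. Passing desk-scale tests therefore demonstrates that
the pipeline's mechanisms work (filtering, sampling, contrastive training,
voting), not that the model reaches any particular accuracy on real
microscopy data.

## Desk-scale protocols and numerical choices

Two canned experiments (`deathscreen.protocols`) drive tests, acceptance
and the worked example:

- **Held-out-plate recovery** — simulate 3 plates with the defaults above
  (about 648 fields; after ATP filtering about 12 wells per plate roughly
  balanced over the three classes), train on two plates, test on the third.
  Training: `tiny-cnn`, 128² crops, sampler (2, 5, 3), Adam lr 1e-3,
  120 epochs. The learning rate is the standard choice for a small CNN
  trained from scratch; the TrainConfig default of 1.25e-5 is a fine-tuning
  rate appropriate for a pretrained backbone. Reported as the median over
  three seeds of well-level majority-vote accuracy.
- **Batch-effect ablation** — simulate 2 plates with strong gain
  (log-σ 0.6), train once with λ₁ = 0.5 and once with λ₁ = 0 (15 epochs per
  arm), and compare the plate-mixing score of the training-set embeddings.

The plate-mixing score is the mean, over samples, of the fraction of their
k = 10 cosine-nearest neighbours that share the sample's plate: ≈ 1/n_plates
means plates are mixed in the embedding space (balanced case), → 1 means
embeddings cluster by plate. Neighbour ties are broken by sample index;
retrieval ties by gallery id — both deterministic.

Other numerical choices: log-sum-exp max-subtraction inside the contrastive
loss; softmax with row-max shift; L2 normalisation guarded by a 1e-12 floor;
the 80/20 split operates on wells (fields of one well never straddle the
split), stratified by (class, plate), with a guarantee of at least one well
of each class on each side.

## Known limitations

- The numpy engine is single-threaded BLAS-bound and intended for the test
  backbone and desk-scale experiments, not production fine-tuning.
- Checkpoint reproducibility is exact for a fixed platform/thread count;
  across BLAS builds results may differ in the last bits.
- The synthetic phenotypes are linearly separable by simple image
  statistics at full penetrance by design; real cell-painting phenotypes
  are not, and desk-scale accuracies do not transfer.
- UMAP/t-SNE projection of exported embeddings is delegated to external
  tools; the package exports the embedding CSV only. A two-line recipe:
  read the CSV with pandas, fit `umap.UMAP(metric="cosine")` on the `z_*`
  columns, and colour the scatter by `class_label` (phenotype clusters) or
  `plate_id` (residual batch effect — compare with the mixing score).
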