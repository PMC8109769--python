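# Methods

## The model

`sganfield` implements a semi-supervised generative adversarial network
(SGAN) for two-class image classification of crop vs weed field patches.
The discriminator D is a (K+1)-way softmax classifier over the K = 2 real
classes (crop = 0, weed = 1) plus a *fake* class at index K = 2 reserved
for generator output.  Writing p(y|x) for the softmax output of D, the
discriminator objective decomposes as

    L_D = L_supervised + L_unsupervised

    L_supervised   = − E_{(x,y)~labeled}  log p(y | x, y < K+1)
    L_unsupervised = − E_{x~unlabeled} log(1 − p(y = K+1 | x))
                     − E_{x~G(z)}      log p(y = K+1 | x)

The supervised term is cross-entropy conditioned on the sample being real:
the real-class probabilities are renormalized with the fake class excluded,
so the term is invariant to the fake-class mass (this conditioning is
implemented in logit space as `logsumexp(real logits) − logit_y`).  With
p_fake playing the role of 1 − D(x), the unsupervised term is the classic
real/fake GAN loss expressed through the (K+1)-way softmax: unlabeled
images are pushed toward the real classes collectively, generated images
toward the fake class.  Labeled images can optionally also enter the
unsupervised term (`include_labeled_in_unsupervised`); the default keeps
them out, using them only in the supervised term.

The generator G maps latent noise z ~ N(0, I_100) to an image and is
trained by **feature matching**: with f(x) the discriminator's globally
averaged penultimate activation,

    L_G = ‖ E_{x~real} f(x) − E_{z} f(G(z)) ‖²₂

computed over half-batches of real and generated images.  Feature matching
is the standard stabilizer for semi-supervised GANs: the generator chases
first-order feature statistics rather than trying to win the minimax game
outright, which keeps the classifier's feature space informative.

## Architectures

Both networks are fully parameterized by `GanConfig`:

* **Generator** — dense layer from the 100-dim latent to a
  `base × base × gen_width` tensor, then four fractionally strided 5×5
  convolutions (stride 2, output side doubling each stage) with channels
  halving `gen_width → gen_width/8`, ending in a 3-channel Tanh image of
  side `base × 16`.  Hidden activations are ReLU.  `base = 28, gen_width =
  512` reproduces the full-scale 448×448 geometry; the desk profile uses
  `base = 4, gen_width = 64` for 64×64 images.
* **Discriminator** — five stride-2 3×3 convolution blocks with
  LeakyReLU(0.2) and dropout 0.3, channels `w, 2w, 4w, 8w, 8w`
  (`disc_width = w`), global average pooling (which makes one architecture
  serve any image side and defines the feature vector f), and a linear head
  to K+1 logits.

Exact layer counts and the choice of f are open in the source description
of the method; five blocks and the post-pool activation are the
conventional completions.  Upsampling is realized as transposed
convolution (kernel 5, stride 2, padding 2, output padding 1 — exact side
doubling).

**Initialization.** Weights are truncated-normal (cut at 2 sd) with
He-scaled standard deviation √(2/fan-in).  A fixed small sd (the classic
DCGAN 0.02) collapses activations to ~1e−9 through five layers at
desk-scale widths because this architecture has no normalization layers;
He scaling keeps activation magnitude O(1), which both losses require.
Biases start at zero.

## Training loop

Inputs are normalized to [−1, 1] by v ↦ v/127.5 − 1 (bilinear resize to a
side divisible by 16 first).  One *epoch* is one pass over the whole
training pool (labeled + unlabeled) in minibatches of m = 30, so the
optimization budget is independent of the labeled rate and per-epoch work
grows mildly with the labeled fraction, consistent with published per-epoch
timings that increase with the rate.  Each iteration:

1. **D step** (generator frozen): draw m labeled, m unlabeled, and m
   freshly generated images; one Adam step on L_D.
2. **G step** (discriminator frozen, bitwise): m/2 real + m/2 generated
   images through D; one Adam step on L_G.

Pools smaller than m are sampled with replacement.  Adam uses β₁ = 0.8
(the stated momentum), β₂ = 0.999, and coupled L2 weight decay 5e−4.
Gradients are clipped to a global L2 norm of 5 in every step (both
networks, and the supervised baseline identically): without normalization
layers the feature-matching loss shows episodic blow-ups that otherwise
derail the classifier mid-training.  The desk profile additionally uses a
two-time-scale update (lr_d = 1e−3, lr_g = 2e−4): with equal rates the
validation curve cycles by ±10 points as the generator chases the
discriminator's features; slowing the generator yields the smooth,
monotonically improving accuracy curve the method is expected to show.  The
full-scale default learning rate is 1e−4 (the source gives both 1e−5 and
1e−4; the latter is the default, both are exposed); the desk profile uses
1e−3 because its optimization budget is ~10³ steps on narrow networks —
at 1e−4 neither the adversarial classifier nor the supervised baseline
leaves its transient within 150 epochs at this scale.  Validation accuracy
(argmax over the K *real* logits only; the fake logit is ignored) is
recorded every epoch and the best-validation parameters are retained; no
early stopping.  Training aborts with the last good checkpoint preserved
if any loss or gradient becomes non-finite.

Every stochastic element (init, minibatch order, noise, dropout) derives
from `GanConfig.seed` through spawned NumPy generators, so runs are
bit-reproducible on a fixed platform.

## Synthetic field imagery

The undeposited UAV dataset is emulated procedurally at 64×64 (any side
divisible by 16 is supported): a brown textured soil background (enforced
R > G > B with ≥ 18-count margins, low-frequency mottling, pixel noise
sd 8) composited with 1–4 single-class plants — crop patches carry
rosettes of 4–8 broad elliptical leaves around a core; weed patches carry
tufts of 5–12 thin curved blades (0.8–1.6 px wide).  Both classes share
the same green color distribution, so color does not separate them;
morphology does, mirroring early-growth dicot crops vs grass weeds.  A
per-image illumination factor (0.60–1.30) emulates uneven daylight across
frames.

**Separability probe.** Two features per image — green-pixel fraction of
the vegetation mask (G > R and G > B, speckle components ≤ 5 px removed)
and area/perimeter² compactness of the largest connected component — feed
a standardized logistic regression with an 80/20 split.  Compactness on
the *largest* component is plant-count- and border-clipping-invariant;
at the default parameters the probe scores 100%, so failures of trained
networks reflect the learner, not the data.  Shrinking the morphology gap
(blade-like leaves, broad blades) drives the probe toward chance — the
difficulty dial.

**Difficulty calibration.** The defaults were set against two observable
anchors: the probe stays above 90% (learnability), and a small supervised
CNN trained on 40 labeled images lands in the low/mid-80s — the accuracy
regime reported for compact CNNs on comparable field imagery at low label
budgets.  An earlier, cleaner parameterization saturated that baseline
near 97%, which both misrepresents the difficulty of real crop/weed
imagery and leaves a low-label benchmark without statistical headroom.

What the synthetic data does *not* model: mixed crop/weed scenes,
perspective and shadows, radiometric calibration, within-class species
variation, and blur/compression of real video frames.  Passing results
demonstrate that the semi-supervised mechanism works end to end under
controlled conditions; they do not certify field performance.

## Evaluation

`confusion` builds the K×K matrix (rows = truth, columns = prediction);
accuracy is its trace over its total, ×100.  SSCA (semi-supervised
classification accuracy) and SCA (supervised classification accuracy) are
this same number for classifiers trained with and without the unlabeled
pool; the distinction lives in run metadata, never in the metric.  Class 0
(crop) is logged as "positive"; for K = 2 the metric is symmetric in that
choice.  The supervised baseline is a LeNet5-style small CNN (three
stride-2 3×3 conv blocks, global pooling, two dense layers) trained with
softmax cross-entropy on the labeled subset only, under the same
optimizer, batch size, epoch budget and best-validation selection as the
adversarial run.  `compare_label_rates` runs both methods at each labeled
rate on identical splits and seeds and emits a tidy table/CSV; external
classifiers can be plugged in for parity runs.

The desk-scale experiment (64×64, 200 training images, 150 epochs, batch
30, three seeds, both methods at 20% and 80% labeled) runs in roughly
fifteen minutes on one CPU; problem sizes were chosen so the whole
protocol stays desk-interactive.

## Numerical choices

* Losses are computed from logits with log-sum-exp stabilization;
  probability-facing APIs clamp to [1e−7, 1−1e−7] before logs (the
  unsupervised loss is unbounded at p_fake ∈ {0, 1}).
* Label-count rounding is half-up on rate × N, with per-class quotas by
  largest remainder — deterministic, reproduces the published
  labeled/unlabeled tables exactly, and keeps stratification within ±1
  sample per class.
* Gradient verification uses central finite differences in float64 with a
  two-stencil consistency filter, and evaluates at biases nudged off zero:
  with zero biases, feature-map positions whose receptive fields are
  entirely ReLU-zeroed sit exactly at the activation kink, where a
  two-sided difference quotient is undefined (the analytic code uses the
  ∂ReLU(0) = 0 convention).
* The backward pass skips the discriminator's input gradient during D
  steps (it is unused there); G steps compute it, since it carries the
  feature-matching signal to the generator.

## Known limitations

* Pure-NumPy training: practical for the desk profile; the full-scale
  448×448/512-channel configuration builds and runs but is not a realistic
  training target on one CPU.
* No batch normalization — faithful to the stated block structure, at the
  cost of He-initialization being load-bearing.
* The adversarial run has higher seed-to-seed variance than the supervised
  baseline; comparisons should always average over ≥ 3 seeds, as the
  bundled harness does.  Even then, at desk scale the 20%-labeled SSCA−SCA
  gap carries an uncertainty of several points (test sets of ~40 images;
  per-run accuracies swing by up to ~10 points across seeds), so the
  low-label comparison here demonstrates the mechanism rather than a
  certified effect size; resolving small gaps needs larger test sets and
  more seeds than a desk budget allows.
* Checkpoints are NumPy `.npz` archives; no cross-framework portability.
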