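# Methods

`fmri2img` implements a three-stage visual-decoding pipeline — multimodal
masked-autoencoder (MAE) pre-training on paired image–fMRI data, masked
fine-tuning on a target dataset, and conditional latent-diffusion image
generation — together with the evaluation metrics used in the visual
decoding literature and a probing analysis that decodes synthetic ±1 ROI
activation patterns. Everything runs end to end on synthetic data at desk
scale; the full-scale ("full_scale") hyperparameter presets are retained as named
configurations for fidelity, but the tested path is the desk preset.

## Synthetic world

A `SyntheticWorld` defines categories, an image renderer and an
fMRI-response model.

**Images.** Each of 60 categories has a deterministic rendering recipe:
background hue (golden-ratio spacing on the hue circle), a horizon line
splitting sky and ground (scene layout), an oriented stripe texture on the
ground (period 4 px, orientation/amplitude per category), and a bright
object (disc/square/triangle/cross/ring) whose colour complements the
background. Per-sample randomness jitters object position and stripe phase.
Default size 64×64 (the 224/256 sizes of the full-scale presets remain
config options).

**fMRI.** Voxels are partitioned into the five scene-decoding ROIs — EVC
(500), LOC (400), OPA (280), PPA (305), RSC (200); 1685 voxels total,
padded to 1696 at patch size 16. Each ROI responds through a fixed linear
readout (seeded Gaussian weights) to a distinct feature family:

* EVC — mean RGB and four oriented finite-difference energies (low level);
* LOC — moments of the foreground mask (area, centroid, spread, edge
  density): object shape;
* OPA — cosine coefficients of the column profile of a 2×2 low-passed
  image (horizontal scene organisation);
* PPA — cosine coefficients of the row profile (vertical layout /
  horizon);
* RSC — coarse global statistics (global mean, top–bottom and left–right
  asymmetries, quadrant means).

The feature families are constructed so that EVC information lives purely
in high-spatial-frequency content: a period-2 texture change leaves the
low-pass image, the foreground mask and the mean colour exactly unchanged
and therefore perturbs only EVC voxels — the ROI-locality property that
the probing analysis assumes.

Each feature is standardised by affine constants calibrated once at world
construction from a fixed 64-image probe ensemble, so every voxel's
signal has roughly unit variance across stimuli and `noise_sd` reads as a
relative noise level (per-voxel SNR ≈ 1/noise_sd). The default
`noise_sd = 0.2` (SNR ≈ 5) is the "low-noise" regime in which end-to-end
decodability is tested. Real fMRI is far noisier; passing tests here show
the machinery decodes when information is present, not that it would decode
BOLD data.

A second "pre-training world" mirrors the dataset shift of the full-scale
setting: four early-visual-style ROIs (V1–V4, 931 voxels, padded to 944)
with a different readout seed. Stage-2 fine-tuning across the voxel-count
change keeps all transformer weights and re-initialises the fMRI patch
embedding (positional tables are fixed sinusoids and adapt automatically).

**Normalisation.** fMRI vectors are z-scored per voxel with training-split
statistics and then zero-padded to the patch grid, so padding sits at the
data mean. The ±1 ROI probing patterns are injected after this
normalisation stage (they are already in z-score-like units).

## Multimodal MAE

Images and padded fMRI vectors are tokenized into non-overlapping patches
(16 px square, 16-voxel 1-D). A uniformly random `floor(ratio·n)` subset of
tokens per modality is masked (default ratio 0.75 for both). Visible tokens
pass through modality-private lower transformer layers, then weight-shared
top layers (mid-fusion). The shared decoder sees the concatenated fMRI+image
sequence with learned mask tokens reinserted at masked positions, fixed
sinusoidal positional encodings, and a learned additive modality tag;
per-modality linear heads map decoder outputs back to patch space. The
joint loss sums squared errors within each masked patch, normalises by
`mask_ratio · n_tokens` per modality, and averages the two modality losses
with equal weight. Images are reconstructed as raw pixel values in [0, 1].

Presets: the full-scale encoder (12 layers, 768 dim, 12 heads, shared top
2; decoder 4×512) is kept for configuration-fidelity tests; the desk
preset is 4×128 (decoder 2×64), and the pipeline runs an even smaller
3×64 encoder (decoder 2×48) so the five-replicate ablation fits on one
CPU. `count_parameters` gives the closed-form parameter count of any
configuration.

Training uses Adam with decoupled weight decay and a cosine-annealed
learning rate; stage-1/2 batches are augmented with random crop + resize.
Stage-3 augmentation adds 20 % voxel dropout (`round(0.2·V)` positions
zeroed without replacement). All hyperparameters of the full-scale stages
(batch 512 / lr 2·10⁻⁴ / 300 epochs; batch 64 / lr 10⁻⁴ / 100 epochs;
batch 32 / lr 5.3·10⁻⁵, Adam betas (0.9, 0.999)) are stored as named
presets; desk schedules are listed below.

## Latent diffusion

**Autoencoder.** A small conv net maps 64×64 RGB images to an 8×8×12
latent (f = 8) and back. The AE operates in an orthonormal opponent colour
space (luminance, red–green, blue–yellow) with the chroma channels
up-weighted ×2 in the loss: in plain RGB the common (luminance) mode
dominates the MSE gradient and hue is learned an order of magnitude more
slowly — at desk scale the reconstructions stayed grey for the whole
training budget. Reported MSEs are plain RGB MSE (the transform is
orthonormal). Convergence is init-sensitive, so three candidate inits
(He-gain conv weights) race for five epochs and the best continues. The
desk preset trains 45 epochs (batch 16, lr 8·10⁻³, cosine) on 240 images
and lands at held-out MSE ≈ 0.012–0.017 depending on seed; the configured
tolerance is 0.02 and training raises an error if it is not met.

**Schedule.** Variance-preserving forward process with a linear β
schedule. The desk preset uses T = 100 with β endpoints scaled by 1000/T
(10⁻³ → 0.2) so that ᾱ_T ≈ 2·10⁻⁵ — with the full-scale endpoints at
T = 100 the forward process would retain ~60 % signal at t = T and
sampling from pure noise would be biased. The full-scale preset is
T = 1000, β ∈ [10⁻⁴, 0.02].

**Denoiser.** A two-resolution time-conditional U-Net (32/64 channels,
sinusoidal time embeddings added per ResBlock) with cross-attention over
the conditioning tokens at four points (both 8×8 blocks and both 4×4
blocks). Cross-attention output projections are zero-initialised, so an
untrained conditional branch coincides exactly with the unconditional one.

**Backbone pre-training (the stand-in for an external checkpoint).** The
stage-3 recipe — train only the cross-attention heads plus the fMRI encoder
and the linear conditioning map — presumes a checkpoint whose
cross-attention already routes conditioning, as a text-conditional
diffusion model's does. The backbone is therefore pre-trained
*caption-conditionally* on the synthetic training images: conditioning
tokens are fixed "caption embeddings" (each class's mean scaled latent laid
out over the token grid, zero-padded), and 10 % conditioning dropout trains
a learned null embedding, which later serves as the unconditional branch of
classifier-free guidance. The backbone (AE + denoiser + null embedding) is
frozen during stage 3 and shared across ablation arms and replicate seeds,
exactly as a released checkpoint would be.

**Stage 3.** Trains the conditioning map — a token-mixing linear
(n_f → 16 tokens) composed with a channel linear (enc_dim → 64), whose
output starts near zero (0.1-scaled init) so initial conditioning looks
like the padded caption slots the backbone knows — at the full learning
rate, the fMRI-side encoder (patch embedding, private fMRI layers, shared
top layers, final norm) at 0.2× and the cross-attention blocks at 0.1×,
the latter joining after two thirds of the schedule. The staggering
matters at desk scale: the map must first align to the backbone's caption
space through the intact cross-attention; co-adapting the cross-attention
from step one overwrites the backbone's conditioning pathway before the
fMRI map is informative. Everything else is frozen, asserted by checksum
before/after. The objective is the eps-prediction MSE at a uniformly
sampled timestep, exactly the conditional-LDM objective. Image
augmentation draws a fresh crop of every training image each epoch
(pre-encoded to latents — exact, since the AE is frozen) plus fresh 20 %
voxel dropout per batch.

**Sampling.** Deterministic DDIM (η = 0) over an evenly spaced timestep
subsequence including t = T, decoded through the AE. Classifier-free
guidance combines conditional and null-conditioned estimates,
`(1+w)·eps_c − w·eps_u`, with w = 1.5 as the generation default. The
predicted clean latent is clamped to ±3 (latents are ~unit variance) each
step: without this static threshold, desk-scale eps errors at the earliest
steps are amplified by 1/√ᾱ and the trajectory leaves the data manifold.
The clamp is disabled in the analytic Gaussian-oracle tests, where the
score is exact.

## Metrics

SSIM is computed on grayscale with a 7×7 Gaussian window (scikit-image).
Two-way identification compares Pearson correlations of feature vectors
(reconstruction vs own truth against a distractor; ties 0.5; exhaustive
over all distractors when enough trials are requested). n-way (default
50-way) classification forms a candidate set of the true class plus
n−1 sampled distractors and scores the reconstruction by the stand-in
classifier. Chance levels are 0.5 and 1/n.

Stand-in extractors replace the pretrained networks of the full-scale
protocol: an untrained oriented-filter energy bank (+ mean colour) as the
low-level extractor, and the penultimate features of two independently
trained small conv classifiers as high-level extractors; the first net's
softmax head is the n-way classifier. They are trained with Gaussian
blur + pixel-noise augmentation so they stay informative on the softened
detail of generated images (the robustness that ImageNet pre-training
provides at full scale); a held-out accuracy floor of 0.9 on clean images
is enforced. Metrics are computed per generated sample, averaged per test
item, and reported mean ± sd over items. The low-level two-way channel has
a ceiling of ≈ 0.62 at desk scale even for per-item AE reconstructions
(the AE loses fine texture), so above-chance decodability is judged on the
high-level features.

## Pipeline and ablation

A single experiment seed is expanded into named substreams (data, model
init, masking, sampling, ...) so every stage is independently reproducible;
run manifests record configs, seeds and content hashes. The ablation runs
the four stagewise arms (stage 3 only; 2+3; 1+3; 1+2+3) on shared data,
backbone and evaluation seeds, with replicate seeds varying only the
trainable stages.

Desk problem sizes (chosen for a single-CPU budget): target dataset 500
samples (400/50/50 split over 60 categories), pre-training dataset 500
samples of the V1–V4 world; stage 1: 4 epochs (batch 64, lr 2·10⁻³);
stage 2: 3 epochs (batch 64, lr 10⁻³); stage 3: 15 epochs (batch 16,
lr 5·10⁻³) by default, shortened to 6 epochs in the five-replicate
ablation and extended to 30 epochs in the single-run low-noise
decodability probe; backbone 80 epochs; evaluation decodes 1–2 samples
per test item at guidance 1.5 with 25 DDIM steps (more DDIM steps do not
help at this scale: with an imperfect denoiser each extra step re-injects
model bias, and 25-step samples identified better than 50-step ones).

The end-to-end decodability check runs on a low-noise dataset
(noise_sd = 0.05, SNR ≈ 20) regenerated from the same world, reusing the
frozen backbone and evaluation stand-ins (images are independent of the
fMRI noise level). The stagewise ablation runs on the default-noise world
and checks ordering of the arm means only.

## Known limitations

* The synthetic world is linear-plus-noise with strongly colour-coded
  categories; it exercises the machinery, not the difficulty of real BOLD
  data.
* At desk scale the stagewise arms differ much less than in the full-scale
  setting: the fMRI encoding task is easy enough that stage-3 training
  alone nearly matches the fully pre-trained arm. The 50-way ordering of
  the two extreme arms is dominated by replicate noise (both means sit in
  the 0.0–0.1 range) and can come out either way for a given seed; a short
  masked-reconstruction pre-training does not measurably improve — and may
  slightly hinder — the eps-loss conditioning alignment under a
  few-hundred-step fine-tuning budget.
* The latent AE plateaus at held-out MSE ≈ 0.011; finer texture is lost,
  which caps SSIM and low-level identification.
* Absolute metric values are not comparable to any published full-scale
  numbers; only orderings and above-chance margins are meaningful here.
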