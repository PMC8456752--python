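# Methods

`connectoscramble` implements an end-to-end methodology for classifying
subjects (here: sex) from wavelet-band functional connectomes while
controlling measured confounds, and for interrogating *which* brain networks
carry the classification signal. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Wavelet connectomes

Parcel-average BOLD series (116 AAL regions) are decomposed with a
maximal-overlap (stationary, shift-invariant) discrete wavelet transform.
Detail scale *j* at sampling interval *dt* has the nominal passband
[1/(2^(j+1)·dt), 1/(2^j·dt)] Hz. Each of the three target bands —
0.05–0.1, 0.03–0.05 and 0.01–0.03 Hz — is assigned the scale(s) whose
nominal passband overlaps it by at least half the scale's width (falling
back to the single best-overlapping scale); at TR = 0.735 s the three bands
map to scales 4, 5 and 6. Pearson correlation of the band coefficient
series between all parcel pairs yields one symmetric 116×116 matrix per
band with unit diagonal.

Choices the band definition leaves open, and what we picked:

* **Wavelet family**: Daubechies-4, exposed in `BandSpec`. Longer filters
  (sym8/sym16) sharpen the band edges only marginally.
* **Boundary rule**: periodic extension — the series is wrapped to the next
  multiple of 2^J and coefficients truncated back to T, so the transform is
  deterministic and length-preserving.
* **Dyadic leakage**: target bands are Hz ranges, but dyadic scales have
  fixed boundaries (0.0425, 0.0213, … Hz at this TR). Oscillations near a
  boundary (e.g. 0.04 Hz) split their energy between neighbouring scales —
  roughly 60/40 with db4 — which no dyadic wavelet choice removes. The
  tests therefore assert dominant-band placement near boundaries and
  near-total concentration at scale centres.

## Synthetic cohorts

The generator emulates the three features of large-cohort fMRI data the
pipeline is built around:

* **Confounded covariates.** Five balancing covariates per acquisition with
  class-conditional normal models (sex × rest/task cells): age 62 ± 7.5 y
  in all cells; ICV 1.60e6 ± 1.3e5 mm³ (male) vs 1.40e6 ± 1.2e5 mm³
  (female), the well-documented head-size difference; mean framewise
  displacement, DVARS and spike percentage all higher under task (e.g. MFD
  0.13 vs 0.16 mm at rest/task) with a small male excess. Motion/volume
  covariates are truncated at zero. These defaults are the package's fixed
  study conditions; any cell can be overridden through
  `CohortSpec.covariate_models`.
* **Correlation-like connectomes.** Per band, a population mean correlation
  comes from a low-rank latent-factor model (rank 8, shrunk 0.6 toward the
  identity) so edges co-vary the way real correlation matrices do; each
  subject adds Gaussian noise of sd 0.15 on the Fisher-z scale.
* **Plantable class effects.** An effect entry shifts the inner edges of a
  chosen node set by ±d·sd/2 (male/female) on the z scale, restricted to a
  condition and to chosen bands, then back-transforms with tanh. Because
  both the shift and the subject noise scale by the same local derivative
  1−r², the standardized effect size survives the back-transform to first
  order; values can never leave (−1, 1) (saturation beyond |r| = 0.999 is
  warned about). Planted-effect experiments in the tests use d = 1.5 on the
  salience network's 45 inner edges, rest only: a strong but
  tightly-localized effect, the regime in which a 45-of-6670-edge signal is
  learnable from a few hundred training subjects.

Time series are synthesized per band by bandpass-filtering white noise
(4th-order Butterworth, zero-phase), imposing the band's target correlation
via a Cholesky factor, summing bands, and adding white observation noise.

What the generator does *not* emulate: scanner artifacts and motion spikes
in image space, site effects, non-Gaussian edge distributions, any true
anatomical organization of the correlation structure, or genuine sex
differences beyond the planted entries. Passing tests therefore demonstrate
that the machinery recovers what was planted under realistic confounding —
not that real resting-state data would yield any particular accuracy.

## Covariate balancing

Continuous covariates are discretized into equal-width bins computed over
the full input table (bins must be shared between classes to define
correspondence). Within each multivariate bin, min(nA, nB) subjects per
class are drawn at random (seeded) under a forced 1:1 ratio — making the
retained class counts exactly equal — or, with no forced ratio, in
proportion to the global class ratio, which matches distribution shapes
while leaving prevalence untouched. Starting from one bin per covariate,
the covariate with the smallest two-sided Mann-Whitney p (tie-corrected)
between the retained classes is refined by one bin and the matching rerun,
until every covariate's p > .10 or a per-covariate bin ceiling (default 64)
is reached; the first passing configuration is returned with a certificate
of p-values that can be recomputed independently from the retained rows.
The p-values are computed on the retained subset — the quantity the balance
claim is about. Matching restarts from scratch at each refinement
(stateless); the random draw is re-executed per ensemble member from the
fixed bin scheme, so each member trains on its own balanced subsample.

Two-factor balancing applies the algorithm by sex (forced 1:1), then by
rest/task (no forced ratio). Because the second stage subsamples the first
stage's output it can disturb the first factor's balance, so the stage pair
is alternated (at most 10 rounds) until the final subset passes both
factors' tests; in practice one or two rounds suffice.

## The scrambled-edge classifier

Each ensemble member owns a seeded random bijection over the 6670 unique
(strict upper-triangle, row-major) edge values, shared across the three
bands, which lays the edges out on a 115×58 grid with bands as channels.
Scrambling removes all spatial priors: a convolution can no longer encode
row/column structure, so saliency attributed to an edge cannot be an
artifact of its matrix position.

Architecture: one convolution of 256 filters, each spanning one full grid
row across the 3 bands (58×3 = 174 weights per filter, shared across the
115 rows) → batch-norm → ReLU → flatten → three dense layers of 64 units,
each followed by batch-norm, ReLU and 0.5 dropout → 2-way softmax.
Training: Adam (lr 1e-3, β₁ .9, β₂ .999), categorical cross-entropy,
batch 64, subject-level stratified 4:1:1 train/validation/test split
(val/test floored per class, remainder to train), up to 100 epochs with the
weights of the best-validation-accuracy epoch restored (ties → earliest).
A `convolutional=False` flag gives the fully-connected baseline (same dense
stack on the flattened grid).

The network core is implemented directly in NumPy (float32), including
reverse-mode gradients; correctness is pinned by finite-difference checks
in the test suite. Batch-norm momentum defaults to 0.9 (not the common
0.99) so running statistics converge within the few hundred optimizer steps
a desk-scale member sees; ε = 1e-3. With all seeds fixed (codec, split,
init, shuffling, dropout) a member is bit-reproducible on one device.

## Ensembles and the growth projection

K members train independently — fresh balanced subsample, fresh codec,
fresh split each. A subject's ensemble vote is the mean class-1 probability
over every member in whose held-out test set it appeared; members never
contribute predictions for subjects they trained on, and no subject enters
any AUROC twice. AUROCs are reported per member, for the ensemble overall
and within the rest/task strata. Note that at small K most votes come from
a single member and the pooled ranking mixes differently-calibrated models,
so the ensemble AUROC approaches and then exceeds the member mean only as
coverage and votes-per-subject grow.

The AUROC-versus-ensemble-size curve (members added in training order)
is fit with the logistic growth model y = a/(1 + b·e^(−kx)), k > 0, by
nonlinear least squares; a is confined to (0, 1] because it is an AUROC
ceiling, and its 95% confidence bounds come from the asymptotic covariance
of the fit. Flat series (k unidentifiable) and decreasing series (model
misspecified) are fitted anyway and flagged.

## Guided Grad-CAM in edge space

For a member and input grid, Grad-CAM weights each convolutional feature
map by the spatial mean of the target-class logit gradient, combines maps
with those weights and rectifies, giving one coarse value per grid row;
that value is broadcast over the row and multiplied by the
guided-backpropagation input gradient (negative gradients zeroed at every
ReLU). The product is rectified — guidance alone does not guarantee
non-negativity once gradients re-mix through the convolution weights — and
mapped through the member's inverse permutation to (edge, band) space.
Per-subject maps average members × {class 0, class 1} × 3 bands (equal
weights throughout; the class and band weighting is otherwise arbitrary)
into one symmetric non-negative 116×116 matrix, zero diagonal. Each member
contributes CAMs only for its own held-out test subjects, mirroring the
vote contract.

Network relevance is summarized by pooled-sd Cohen's d of CAM values on a
network's edge set versus all remaining edges, per rest/task stratum — an
effect size rather than a significance test, because the number of
subject-edge values makes any difference "significant".

## Network occlusion

For each network and edge mode (inner: 45 edges, 0.67% of all edges;
connecting: 1105, 16.57%), two arms of K members train on exactly half the
edges — 3335 = floor(6670/2), grid 115×29, the one leftover edge dropped
from both halves. Include-arm halves always contain the network's edges
plus a fresh random fill per member; exclude-arm halves are fresh random
draws from the non-network edges. Filters still span one full grid row
(29×3 weights). Arms are compared by two-sided Mann-Whitney U on their
member test AUROCs — overall and per stratum, each member's own test set
restricted to the stratum — with Holm correction across all
(network × mode × stratum) rows of one report. The full published-scale
grid is 2 modes × 2 arms × 3 networks × 300 members = 3600 training runs;
the tests run a 2 × 20-member salience-inner cell.

## A-priori networks

DMN, CEN and salience are each 10 distinct AAL-116 nodes. The bundled table
maps the classical region families (DMN: medial orbitofrontal, posterior
cingulate, parahippocampus, precuneus, inferior parietal; CEN: middle
frontal, inferior frontal triangularis, superior medial frontal, superior
and inferior parietal; SAL: insula, anterior cingulate, amygdala, middle
and superior temporal pole — all bilateral) onto lateralized AAL labels.
Which lateralized areas fill each family to exactly ten nodes is a
documented package choice; pass your own YAML to override. DMN and CEN
share the inferior parietal pair; the salience set is disjoint from both,
which the planted-effect tests rely on.

## Problem sizes used in the test suite

All checks run on synthetic cohorts at desk scale, chosen as the smallest
sizes at which the planted signal is comfortably detectable: n = 2000 for
balancing contracts; the planted effect is d = 1.5 on the salience inner
edges, rest-only, throughout. The occlusion recovery uses n = 600 with
2×20 members at 20 epochs — the arm-difference test has large power even
when members learn weakly, because the exclude arm is pinned at chance.
The CAM recovery needs every member to actually learn the 45-edge signal
(near-chance members contribute larger-magnitude noise saliency that
dominates the plain member average), so it uses n = 1600 — after balancing,
~450 training subjects per member — with 10 members at 30 epochs. The
growth-curve and vote contracts use K = 30 members at 6 epochs on n = 400
with the effect in both conditions.

## Known limitations

* The ensemble's accuracy gain over members needs many members and high
  coverage; desk-scale runs (K ≤ 30) mostly demonstrate the contracts, not
  the asymptotic gain.
* Equal-width binning is sensitive to covariate outliers (one extreme value
  stretches every bin); the balancer compensates with more bins.
* Grad-CAM row weights are shared across a grid row (115 coarse positions),
  so single-edge saliency is the product of a row-level and an edge-level
  term; averaging over many members with different scramblings is what
  makes per-edge attribution meaningful.
* The Mann-Whitney comparison of occlusion arms treats members as
  independent; they share the cohort, so p-values are exact only under the
  per-member resampling scheme used here.
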