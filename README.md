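# connectoscramble

Scrambled-edge CNN ensembles for functional-connectome classification,
with multivariate confound balancing and two interpretability procedures —
guided Grad-CAM in edge space and a-priori-network occlusion testing.

## The problem

Functional connectomes — here, 3-band wavelet correlation matrices over the
116-region AAL parcellation, one symmetric 116×116 matrix per frequency
band (0.05–0.1, 0.03–0.05, 0.01–0.03 Hz) — can be classified by deep
networks, but two obstacles stand between a high AUROC and a scientific
claim. First, covariates such as intracranial volume and head motion differ
between the classes and between rest and task acquisitions, so a classifier
can cheat. Second, convolutions over a matrix impose spatial priors: a
salient edge drags its whole row and column along in any saliency map.

This package addresses both. A **balancing algorithm** bins the covariates
(age, mean framewise displacement, intracranial volume, DVARS, spike
percentage), matches the classes within every multivariate bin, and refines
bins until every covariate's two-sided Mann-Whitney p exceeds .10 on the
retained subset — with an optional exact 1:1 class ratio. A **scrambled
CNN** erases spatial priors: each ensemble member permutes the 6670 unique
edge values onto a 115×58 grid with its own random bijection (shared across
bands) before convolving with row-spanning filters; averaging saliency over
many members with different scramblings leaves only edge-level signal.
Members train on independently drawn balanced subsamples (4:1:1
train/val/test, best-validation epoch restored) and a subject's **ensemble
vote** is the mean probability over every member that held it out, so train
and test never mix. AUROC versus ensemble size is extrapolated with a
logistic growth model y = a/(1 + b·e^(−kx)) whose asymptote a estimates the
accuracy ceiling of vote averaging.

Two procedures then localize the signal: **guided Grad-CAM**, mapped back
through each member's inverse permutation and averaged over members,
classes and bands into one 116×116 saliency map per subject, summarized by
Cohen's d of a network's edge values against all others; and **occlusion**,
which trains paired model sets on half the edges (3335, grid 115×29) that
deliberately include versus exclude a network's edges — 45 inner or 1105
connecting edges for a 10-node network — and compares the arms' AUROC
distributions by Mann-Whitney U with Holm correction.

Everything runs on synthetic cohorts with realistic confound structure and
plantable, condition-specific class effects, so every stage is testable
without access-restricted imaging data.

## A worked example

`examples/03_confound_balancing.py` generates 2000 subjects with the
default confound structure (male ICV larger by ~2×10⁵ mm³, task scans with
more motion) and balances them by sex:

```
input: 2000 subjects; retained: 750 (375 male / 375 female)
final bin counts: {'age': 1, 'mfd': 1, 'icv': 11, 'dvars': 2, 'spike_pct': 3}

covariate      p before     p after (certificate / recomputed)
  age           3.78e-01   0.505 / 0.505
  mfd           5.29e-03   0.435 / 0.435
  icv          7.35e-197   0.150 / 0.150
  dvars         8.41e-05   0.556 / 0.556
  spike_pct     5.04e-04   0.804 / 0.804
```

ICV needed 11 bins; after matching, the retained 375+375 subjects are
indistinguishable on every covariate (all p > .10, recomputed here with an
independent call to `scipy.stats.mannwhitneyu`), so a classifier trained on
this subset cannot lean on head size or motion.

The other example scripts follow the same pattern: `01` inspects the
planted condition-specific edge effect, `02` builds a wavelet connectome
from synthesized time series, `04` trains a small ensemble and fits the
growth projection, and `05` runs both interpretability procedures against
a planted salience-network effect — Grad-CAM reports a positive Cohen's d
only on the planted inner edges, and occlusion shows an AUROC cost only in
the rest stratum, where the effect lives.

A thin CLI mirrors the library:
`connectoscramble synth|make-connectomes|balance|ensemble|cam|occlusion|fit-curve|run`
(see `connectoscramble --help`); `connectoscramble run` executes the full
balance → ensemble → CAM → occlusion → fit pipeline from one YAML config
with a single master seed.

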