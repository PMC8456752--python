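"""Synthetic cohorts with the confound structure of large fMRI studies.

This module generates phenotype tables, band-limited parcel time series and
3-band wavelet-style connectivity matrices for a two-class (female/male),
two-condition (rest/task) cohort. It emulates the features the downstream
pipeline assumes about real data:

* class-dependent covariate distributions — males have larger intracranial
  volume (ICV), head-motion summaries (mean framewise displacement, DVARS,
  spike percentage) differ between rest and task acquisitions;
* per-subject symmetric 3x116x116 correlation stacks drawn from a shared
  low-rank population model, so edges are correlated with each other the way
  real correlation matrices are rather than i.i.d.;
* plantable class effects: a configurable set of nodes whose inner edges
  separate the sexes by a chosen standardized effect size, restricted to a
  condition (rest/task/both) and to chosen frequency bands.

Effects are planted additively on Fisher-z transformed edge weights and
back-transformed with tanh, which keeps every edge inside (-1, 1) and, to
first order, preserves the standardized effect size on the correlation scale
(both the mean shift and the subject-level noise are scaled by the same
local derivative 1 - r^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from . import edges

PHENOTYPE_COLUMNS = (
    "subject_id", "sex", "condition", "age", "icv", "mfd", "dvars", "spike_pct"
)
COVARIATES = ("age", "icv", "mfd", "dvars", "spike_pct")

#: Default frequency bands (Hz), highest first, matching the connectome stack.
DEFAULT_BANDS = ((0.05, 0.10), (0.03, 0.05), (0.01, 0.03))


def default_covariate_models() -> dict:
    """Class-conditional (sex x condition) normal parameters per covariate.

    Keys are covariate names; values map (sex, condition) -> (mean, sd) with
    sex 0=female/1=male and condition 0=rest/1=task. Units: age in years,
    ICV in mm^3, MFD in mm, DVARS in arbitrary BOLD units, spike percentage
    in percent. The defaults encode a large male-female ICV shift, a small
    male excess in motion, and higher motion during task acquisition.
    """
    def cells(f_rest, f_task, m_rest, m_task):
        return {(0, 0): f_rest, (0, 1): f_task, (1, 0): m_rest, (1, 1): m_task}

    return {
        "age": cells((62.0, 7.5), (62.0, 7.5), (62.0, 7.5), (62.0, 7.5)),
        "icv": cells((1.40e6, 1.2e5), (1.40e6, 1.2e5),
                     (1.60e6, 1.3e5), (1.60e6, 1.3e5)),
        "mfd": cells((0.13, 0.050), (0.16, 0.060),
                     (0.14, 0.050), (0.17, 0.060)),
        "dvars": cells((1.15, 0.18), (1.30, 0.20),
                       (1.18, 0.18), (1.33, 0.20)),
        "spike_pct": cells((1.5, 0.8), (2.2, 1.0), (1.6, 0.8), (2.3, 1.0)),
    }


@dataclass(frozen=True)
class EffectEntry:
    """A planted sex effect on the inner edges of a node set.

    ``d`` is the standardized mean difference (male minus female) on the
    Fisher-z edge scale, in units of the between-subject edge noise sd.
    ``condition`` restricts the effect to rest, task or both; ``bands`` lists
    the band indices (0 = highest frequency) that carry it.
    """

    nodes: tuple[int, ...]
    condition: str = "both"          # rest | task | both
    d: float = 0.0
    bands: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self):
        if self.condition not in ("rest", "task", "both"):
            raise ValueError(f"condition must be rest|task|both, got {self.condition!r}")
        if not np.isfinite(self.d):
            raise ValueError("effect size must be finite")
        for v in self.nodes:
            if not 0 <= int(v) < edges.N_NODES:
                raise ValueError(f"node {v} outside [0, {edges.N_NODES})")
        for b in self.bands:
            if not 0 <= int(b) < 3:
                raise ValueError(f"band index {b} outside [0, 3)")

    @property
    def edge_indices(self) -> np.ndarray:
        return edges.inner_edges(self.nodes)

    def applies_to(self, condition: int) -> bool:
        return self.condition == "both" or condition == {"rest": 0, "task": 1}[self.condition]


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    The base connectome model draws a per-band population correlation from a
    low-rank latent-factor model (``latent_rank`` factors, shrunk toward the
    identity by ``latent_shrink``) and adds per-subject Gaussian noise of sd
    ``edge_noise_sd`` on the Fisher-z scale.
    """

    n_subjects: int = 2000
    sex_ratio: float = 0.5           # fraction male
    rest_fraction: float = 0.5
    covariate_models: dict = field(default_factory=default_covariate_models)
    effect_plan: tuple[EffectEntry, ...] = ()
    seed: int = 0
    latent_rank: int = 8
    latent_shrink: float = 0.6
    edge_noise_sd: float = 0.15

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        for name, frac in (("sex_ratio", self.sex_ratio),
                           ("rest_fraction", self.rest_fraction)):
            if not 0.0 < frac < 1.0:
                raise ValueError(f"{name} must lie in the open interval (0, 1)")
        if not 0.0 < self.latent_shrink <= 1.0:
            raise ValueError("latent_shrink must lie in (0, 1]")
        if self.edge_noise_sd <= 0:
            raise ValueError("edge_noise_sd must be positive")
        for cov in COVARIATES:
            if cov not in self.covariate_models:
                raise ValueError(f"covariate_models missing entry for {cov!r}")

    def with_effects(self, *entries: EffectEntry) -> "CohortSpec":
        return replace(self, effect_plan=tuple(entries))

    def _streams(self):
        """Independent substreams: phenotypes, connectomes, time series."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(np.random.default_rng(s) for s in children)


def generate_phenotypes(spec: CohortSpec) -> pd.DataFrame:
    """Draw the phenotype table for a cohort.

    Sex and condition counts are fixed at round(n * fraction) and assigned in
    a seeded random order; covariates are drawn from the class-conditional
    normal models (motion and volume covariates truncated at zero).
    """
    rng, _, _ = spec._streams()
    n = spec.n_subjects
    sex = np.zeros(n, dtype=int)
    sex[: round(n * spec.sex_ratio)] = 1
    rng.shuffle(sex)
    condition = np.ones(n, dtype=int)  # 1 = task
    condition[: round(n * spec.rest_fraction)] = 0
    rng.shuffle(condition)

    table = pd.DataFrame({
        "subject_id": [f"sub-{i:05d}" for i in range(n)],
        "sex": sex,
        "condition": condition,
    })
    for cov in COVARIATES:
        cells = spec.covariate_models[cov]
        vals = np.empty(n)
        for (s, c), (mean, sd) in cells.items():
            mask = (sex == s) & (condition == c)
            vals[mask] = rng.normal(mean, sd, mask.sum())
        if cov != "age":
            vals = np.clip(vals, 0.0, None)
        table[cov] = vals
    return table


def _population_z(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-band population mean edge weights on the Fisher-z scale, (3, E)."""
    out = np.empty((3, edges.N_EDGES))
    for b in range(3):
        load = rng.standard_normal((edges.N_NODES, spec.latent_rank))
        gram = spec.latent_shrink * (load @ load.T) / spec.latent_rank
        gram += (1.0 - spec.latent_shrink) * np.eye(edges.N_NODES)
        d = np.sqrt(np.diag(gram))
        corr = gram / np.outer(d, d)
        out[b] = np.arctanh(np.clip(edges.vectorize(corr), -0.99, 0.99))
    return out


def generate_connectomes(labels: pd.DataFrame, spec: CohortSpec) -> np.ndarray:
    """Per-subject 3x116x116 symmetric stacks, (n, 3, 116, 116).

    ``labels`` must carry ``sex`` and ``condition`` columns aligned with the
    cohort (typically the output of :func:`generate_phenotypes`). Effects
    from ``spec.effect_plan`` shift the listed inner edges by +/- d*sd/2 on
    the z scale for males/females, in the stated condition and bands only.
    """
    _, rng, _ = spec._streams()
    pop_z = _population_z(spec, rng)
    sex = labels["sex"].to_numpy()
    condition = labels["condition"].to_numpy()
    r = np.tanh(_apply_effects(pop_z, spec, sex, condition, rng))
    return edges.unvectorize(r, diagonal=1.0)


def _apply_effects(pop_z, spec, sex, condition, rng) -> np.ndarray:
    n = len(sex)
    z = pop_z[None, :, :] + rng.normal(
        0.0, spec.edge_noise_sd, size=(n, 3, edges.N_EDGES)
    )
    for entry in spec.effect_plan:
        if entry.d == 0.0:
            continue
        idx = entry.edge_indices
        rows = np.flatnonzero([entry.applies_to(c) for c in condition])
        shift = np.where(sex[rows] == 1, 0.5, -0.5) * entry.d * spec.edge_noise_sd
        for b in entry.bands:
            z[np.ix_(rows, [b], idx)] += shift[:, None, None]
    bad = np.abs(np.tanh(z)) > 0.999
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} edge weights saturated beyond |r| = 0.999; "
            "requested effects are effectively clipped at the [-1, 1] boundary"
        )
    return z


def generate_timeseries(
    labels: pd.DataFrame,
    spec: CohortSpec,
    T: int,
    dt: float,
    noise_sd: float = 0.5,
    bands=DEFAULT_BANDS,
) -> np.ndarray:
    """Band-structured parcel time series, (n, T, 116).

    Each parcel series is the sum of three band-limited stochastic
    components (one per frequency band, cross-parcel correlation equal to
    the subject's band connectome) plus white observation noise.
    """
    if dt <= 0:
        raise ValueError("sampling interval dt must be positive")
    if T < 64:
        raise ValueError("T must be at least 64 samples")
    f_low = min(lo for lo, hi in bands)
    if T * dt < 2.0 / f_low:
        raise ValueError(
            f"T={T} samples at dt={dt}s spans {T * dt:.0f}s, shorter than two "
            f"cycles of the lowest band ({f_low} Hz)"
        )
    conns = generate_connectomes(labels, spec)
    _, _, rng = spec._streams()
    out = np.empty((len(labels), T, edges.N_NODES))
    for i in range(len(labels)):
        out[i] = synthesize_timeseries(conns[i], T, dt, rng, noise_sd, bands)
    return out


def synthesize_timeseries(
    band_corrs: np.ndarray,
    T: int,
    dt: float,
    rng: np.random.Generator,
    noise_sd: float = 0.5,
    bands=DEFAULT_BANDS,
) -> np.ndarray:
    """One subject's T x 116 series from per-band target correlations."""
    fs = 1.0 / dt
    nyq = fs / 2.0
    total = np.zeros((T, band_corrs.shape[-1]))
    for b, (lo, hi) in enumerate(bands):
        if hi >= nyq:
            raise ValueError(f"band {lo}-{hi} Hz exceeds the Nyquist rate {nyq:.3f} Hz")
        corr = band_corrs[b] + 1e-6 * np.eye(band_corrs.shape[-1])
        chol = np.linalg.cholesky(_nearest_spd(corr))
        white = rng.standard_normal((T, band_corrs.shape[-1]))
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        limited = signal.sosfiltfilt(sos, white, axis=0)
        limited /= limited.std(axis=0, keepdims=True) + 1e-12
        total += limited @ chol.T
    total += rng.normal(0.0, noise_sd, size=total.shape)
    return total


def _nearest_spd(mat: np.ndarray) -> np.ndarray:
    """Clip eigenvalues below a floor so Cholesky always succeeds."""
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    vals = np.clip(vals, 1e-6, None)
    return vecs @ np.diag(vals) @ vecs.T
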