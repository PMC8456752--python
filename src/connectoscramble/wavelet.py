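"""Wavelet-band decomposition and per-band connectivity matrices.

Parcel-average BOLD series are decomposed with a maximal-overlap (stationary)
discrete wavelet transform; detail scale j at sampling interval dt covers the
nominal passband [1/(2^(j+1) dt), 1/(2^j dt)] Hz. Each target frequency band
is assigned the scale(s) whose passband best matches it, and the inter-parcel
Pearson correlation of the band's coefficient series gives one symmetric
116x116 matrix per band — the subject's wavelet connectome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from . import edges

#: Target bands in Hz, highest frequency first.
DEFAULT_BANDS = ((0.05, 0.10), (0.03, 0.05), (0.01, 0.03))


@dataclass(frozen=True)
class BandSpec:
    """Frequency bands, sampling interval and wavelet family."""

    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    sampling_interval: float = 0.735
    wavelet_name: str = "db4"

    def __post_init__(self):
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        nyq = self.nyquist
        for lo, hi in self.bands:
            if not 0 < lo < hi:
                raise ValueError(f"band ({lo}, {hi}) must satisfy 0 < low < high")
            if hi > nyq:
                raise ValueError(
                    f"band ({lo}, {hi}) exceeds the Nyquist rate {nyq:.4f} Hz"
                )
        flat = sorted(self.bands, key=lambda b: b[0])
        for (l1, h1), (l2, h2) in zip(flat, flat[1:]):
            if h1 > l2:
                raise ValueError("bands must not overlap")

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.sampling_interval)

    def scale_passband(self, j: int) -> tuple[float, float]:
        """Nominal Hz passband of wavelet detail scale j (j >= 1)."""
        dt = self.sampling_interval
        return 1.0 / (2 ** (j + 1) * dt), 1.0 / (2 ** j * dt)

    def scales_for_band(self, band: tuple[float, float],
                        max_scale: int = 24) -> list[int]:
        """Detail scales assigned to a target Hz band.

        A scale is assigned when at least half of its nominal passband lies
        inside the target band; if no scale reaches that threshold the single
        best-overlapping scale is used.
        """
        lo, hi = band
        chosen, best, best_frac = [], None, 0.0
        for j in range(1, max_scale + 1):
            s_lo, s_hi = self.scale_passband(j)
            overlap = max(0.0, min(hi, s_hi) - max(lo, s_lo))
            frac = overlap / (s_hi - s_lo)
            if frac >= 0.5:
                chosen.append(j)
            if frac > best_frac:
                best, best_frac = j, frac
        if chosen:
            return chosen
        if best is None:
            raise ValueError(f"no wavelet scale overlaps band {band} Hz")
        return [best]

    @property
    def max_required_scale(self) -> int:
        return max(max(self.scales_for_band(b)) for b in self.bands)


@dataclass(frozen=True)
class WaveletConnectome:
    """A 3x116x116 symmetric correlation stack for one subject."""

    subject_id: str
    matrix: np.ndarray
    band_spec: BandSpec = field(default_factory=BandSpec)

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 3 or m.shape[1] != m.shape[2]:
            raise ValueError(f"expected (bands, V, V) stack, got {m.shape}")
        if not np.allclose(m, np.swapaxes(m, 1, 2), atol=1e-8):
            raise ValueError("connectome bands must be symmetric")
        if not np.allclose(np.diagonal(m, axis1=1, axis2=2), 1.0, atol=1e-8):
            raise ValueError("connectome diagonal must be 1")
        if np.abs(m).max() > 1.0 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")


def decompose_bands(series: np.ndarray, spec: BandSpec) -> list[np.ndarray]:
    """MODWT band coefficients for a T x P series: list of (T_b, P) arrays.

    The stationary transform is computed to the deepest required scale with
    periodic extension (the series is wrapped to the next multiple of 2^J and
    coefficients truncated back to T). Where a target band covers several
    scales the coefficient series are concatenated along time.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be a 2-D (time x parcels) array")
    if not np.isfinite(series).all():
        raise ValueError("series contains non-finite values")
    T = series.shape[0]
    max_scale = spec.max_required_scale
    if T < 2 ** max_scale:
        offending = max(spec.bands, key=lambda b: max(spec.scales_for_band(b)))
        raise ValueError(
            f"T={T} samples cannot resolve wavelet scale {max_scale} needed for "
            f"band {offending} Hz at dt={spec.sampling_interval}s "
            f"(need at least {2 ** max_scale} samples)"
        )
    block = 2 ** max_scale
    padded_len = int(np.ceil(T / block)) * block
    padded = np.concatenate([series, series[: padded_len - T]], axis=0)

    # pywt.swt with trim_approx returns [cA_J, cD_J, ..., cD_1]
    coeffs = pywt.swt(padded, spec.wavelet_name, level=max_scale,
                      trim_approx=True, norm=True, axis=0)
    detail = {j: coeffs[max_scale - j + 1][:T] for j in range(1, max_scale + 1)}

    out = []
    for band in spec.bands:
        scales = spec.scales_for_band(band)
        out.append(np.concatenate([detail[j] for j in scales], axis=0))
    return out


def band_correlation(
    coefficients: list[np.ndarray],
    subject_id: str = "",
    spec: BandSpec | None = None,
) -> WaveletConnectome:
    """Pearson correlation between parcels within each band's coefficients."""
    spec = spec or BandSpec()
    mats = []
    for b, coef in enumerate(coefficients):
        sd = coef.std(axis=0)
        dead = np.flatnonzero(sd <= 0)
        if dead.size:
            raise ValueError(
                f"zero-variance coefficient series for parcel(s) {dead.tolist()} "
                f"in band {b}; correlation undefined"
            )
        corr = np.corrcoef(coef, rowvar=False)
        np.fill_diagonal(corr, 1.0)
        mats.append(np.clip((corr + corr.T) / 2.0, -1.0, 1.0))
    return WaveletConnectome(subject_id=subject_id, matrix=np.stack(mats),
                             band_spec=spec)


def timeseries_to_connectome(series: np.ndarray, spec: BandSpec,
                             subject_id: str = "") -> WaveletConnectome:
    """Convenience: decompose then correlate one subject's series."""
    return band_correlation(decompose_bands(series, spec), subject_id, spec)


def stack_cohort(connectomes: list[WaveletConnectome]) -> np.ndarray:
    """Stack per-subject matrices into an (n, bands, V, V) array."""
    return np.stack([c.matrix for c in connectomes])
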