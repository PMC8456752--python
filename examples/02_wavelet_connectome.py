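"""From parcel time series to a 3-band wavelet connectome.

Synthesizes one subject's BOLD-like series (T=2048 samples at TR=0.735 s)
with a strong 0.03-0.05 Hz coupling between two parcels, decomposes it with
a db4 MODWT, and correlates the band coefficients. The planted coupling
should surface in the middle band and be near zero elsewhere.
"""

import numpy as np

import connectoscramble as cs
from connectoscramble import cohort

spec = cs.BandSpec(sampling_interval=0.735)
print("band -> wavelet scales at TR=0.735 s:")
for band in spec.bands:
    scales = spec.scales_for_band(band)
    lo, hi = spec.scale_passband(scales[0])
    print(f"  {band[0]:.2f}-{band[1]:.2f} Hz -> scale(s) {scales} "
          f"(nominal passband {lo:.4f}-{hi:.4f} Hz)")

rng = np.random.default_rng(0)
corr = np.stack([np.eye(6)] * 3)
corr[1, 0, 1] = corr[1, 1, 0] = 0.9        # couple parcels 0-1 in band 2 only
# synthesize inside the nominal scale passbands so the demo coupling does
# not straddle the dyadic band boundaries
dyadic = tuple(spec.scale_passband(spec.scales_for_band(b)[0])
               for b in spec.bands)
series = cohort.synthesize_timeseries(corr, T=2048, dt=0.735, rng=rng,
                                      noise_sd=0.3, bands=dyadic)

coefs = cs.decompose_bands(series, spec)
conn = cs.band_correlation(coefs, subject_id="demo", spec=spec)
print("\nedge (0,1) correlation per band:")
for b, band in enumerate(spec.bands):
    print(f"  {band[0]:.2f}-{band[1]:.2f} Hz : r = {conn.matrix[b, 0, 1]:+.3f}")
print("\nthe planted 0.03-0.05 Hz coupling dominates its own band; the "
      "residual in neighbouring bands is wavelet filter roll-off.")
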