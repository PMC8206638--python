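"""Plant a phase-lagged oscillation between two ROIs and measure it with wPLI.

Two synthetic source series share a 10 Hz sinusoid with a constant pi/4
phase lag plus independent noise; a third channel is pure noise.  The wPLI
spectrum of the coupled pair peaks at the planted frequency, while the
uncoupled pair stays at the noise floor.
"""

import numpy as np

from megnet import CouplingSpec, SpectralParams, generate_coupled_sources, wpli_spectrum

spec = CouplingSpec(pairs=((0, 1, 10.0, np.pi / 4, 1.0),), noise_sd=0.5)
series = generate_coupled_sources(spec, n_rois=3, duration_s=60, fs=200, seed=1)
params = SpectralParams()  # 2 s Hann segments, 50% overlap, 1-80 Hz at 0.5 Hz

coupled = wpli_spectrum(series, "roi00", "roi01", params)
uncoupled = wpli_spectrum(series, "roi00", "roi02", params)

k = int(np.argmax(coupled.wpli))
print(f"coupled pair:   peak wPLI {coupled.wpli[k]:.3f} at {coupled.freqs[k]:.1f} Hz")
print(f"uncoupled pair: max wPLI {uncoupled.wpli.max():.3f}")
print()
print("The coupled pair's wPLI reaches 1 within one grid bin of the planted")
print("10 Hz (a constant non-zero lag makes every segment's imaginary")
print("cross-spectrum agree in sign; the Hann taper spreads the peak by one")
print("bin); the uncoupled pair has no consistent phase relation anywhere.")
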