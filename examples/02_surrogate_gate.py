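"""Call connections against a phase-randomized surrogate null.

Builds a per-subject null (mean/SD of surrogate wPLI per frequency, pooled
over random ROI-pair draws), then expresses each pair's wPLI excess in null
SD units.  A pair is connected iff its maximum z reaches 2.5 SD, at the
frequency of maximal excess.
"""

import numpy as np

from megnet import (
    CouplingSpec,
    SpectralParams,
    build_surrogate_null,
    generate_coupled_sources,
    pairwise_wpli,
    select_connection,
)

spec = CouplingSpec(pairs=((0, 1, 12.0, np.pi / 3, 1.0),), noise_sd=0.4)
series = generate_coupled_sources(spec, n_rois=8, duration_s=60, fs=200, seed=2)
params = SpectralParams()

null = build_surrogate_null(series, params, n_pairs=300, seed=3)
print(f"null over {null.n_pairs} surrogate draws: "
      f"mu ~ {null.mu.mean():.3f}, sigma ~ {null.sigma.mean():.3f}")

for pair, spectrum in sorted(pairwise_wpli(series, params).items())[:6]:
    cand = select_connection(spectrum, null, gate=2.5)
    tag = "CONNECTED" if cand.connected else "-"
    print(f"{pair[0]}-{pair[1]}: z_max {cand.z_max:5.1f} at {cand.f_star:5.1f} Hz  {tag}")
print()
print("The planted roi00-roi01 coupling clears the gate decisively at the")
print("planted 12 Hz.  Some noise pairs also scrape past 2.5 SD: z_max is a")
print("maximum over ~159 frequencies, so its null distribution sits well")
print("above a single-frequency z.  The density threshold applied next")
print("(keeping only the strongest candidates) prunes these weak survivors.")
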