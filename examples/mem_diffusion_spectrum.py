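"""Maximum-entropy inversion of an FCS curve into a diffusion-time
distribution.

Instead of assuming exactly two species, the inversion solves for a full
probability distribution over 101 log-spaced diffusion times, with the
regularization strength chosen at the L-curve corner. A bimodal result
confirms the two-species picture without presupposing it.
"""

import numpy as np

from precluster import mem_invert
from precluster.fcs import eval_fcs_model
from precluster.synthetic import FcsSimSpec, gen_fcs_curve

base = FcsSimSpec(components=[(0.7, 0.2), (0.3, 2.0)], n_particles=2.0, seed=0)
clean = eval_fcs_model(base.lag_grid_ms, base.model_params()).values
noise = lambda lag: 0.01 * np.interp(lag, base.lag_grid_ms, clean)
curve = gen_fcs_curve(
    FcsSimSpec(components=[(0.7, 0.2), (0.3, 2.0)], n_particles=2.0, noise_sd=noise, seed=42)
)

res = mem_invert(curve, offset=0.0, n_particles=2.0)
peaks = res.td_grid_ms[res.peaks()]

print(f"regularization nu at L-curve corner: {res.nu:.2f} (chi2_red {res.chi2_red:.3f})")
print(f"entropy of the selected distribution: {res.entropy:.3f}")
print(f"distribution peaks at: {', '.join(f'{p:.3f} ms' for p in peaks)}")
for target in (0.2, 2.0):
    sel = (res.td_grid_ms > target / 1.5) & (res.td_grid_ms < target * 1.5)
    print(f"probability mass within x1.5 of {target} ms: {res.p[sel].sum():.2f}")
print()
print("Two well-separated peaks near the true 0.2 and 2.0 ms times show the")
print("mixture is resolved; mass between the peaks would indicate smearing.")
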