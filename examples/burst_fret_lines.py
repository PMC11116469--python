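"""Single-molecule burst selection, lifetimes and FRET reference lines.

Simulates a photon trace with diffusing-molecule bursts on a dim
background, selects bursts with the 2-sigma / 10-photon rule, estimates a
fluorescence lifetime from photon delay times, and evaluates the static
and dynamic FRET lines used to classify bursts in E-vs-tau histograms.
"""

import numpy as np

from precluster.bursts import burst_lifetime, fret_lines, select_bursts
from precluster.synthetic import gen_burst_trace, gen_photon_delays

events = [(0.2 + 0.19 * k, 0.002, 15.0) for k in range(50)]
trace, truth = gen_burst_trace(0.2, events, bin_width_ms=1.0, total_time_s=10.0, seed=7)
table = select_bursts(trace, sigma_mult=2.0, min_photons=10, max_photons=3000)

print(f"injected bursts: {len(truth)}, selected bursts: {len(table)}")
print(f"background: {table.background_mean:.2f} +- {table.background_sd:.2f} counts/bin, "
      f"threshold {table.threshold:.2f}")
print(f"median burst size: {np.median(table.photon_counts):.0f} photons")

delays = gen_photon_delays(5000, lifetime_ns=4.0, seed=3)
tau = burst_lifetime(delays)
print(f"\nfitted donor lifetime: {tau:.3f} ns (truth 4.0 ns)")

for t in (0.5, 2.0, 3.5):
    print(f"tau = {t:.1f} ns -> static line E = {fret_lines(t, 'static'):+.3f}, "
          f"dynamic line E = {fret_lines(t, 'dynamic'):+.3f}")
print()
print("Bursts on the static line are conformationally homogeneous during")
print("transit; displacement toward the dynamic line reveals millisecond")
print("interconversion between FRET states.")
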