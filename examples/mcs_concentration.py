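"""Counting rare clusters by microfluidic confocal scanning.

Simulates a 200-position scan of a four-channel microfluidic device at a
known femtomolar cluster concentration, counts 5-SD intensity peaks, and
converts the mean count back into a flux and a molar concentration.
"""

from precluster import MCSGeometry, detect_peaks, flux_and_concentration
from precluster.synthetic import gen_mcs_scan

geom = MCSGeometry()  # 4 s dwell, 28 um channel, 15 uL/h sample flow
print(f"geometric factor 4*h*d_step/(pi*z*w) = {geom.geometric_factor:.2f}")

c_true = 3.3e-14  # 33 fM of clusters
traces, n_injected, lam = gen_mcs_scan(c_true, geom, seed=11)
n_bar, group_means = detect_peaks(traces)
flux, c_est = flux_and_concentration(n_bar, geom)

print(f"expected peaks/trace {lam:.2f}; injected {n_injected} over {len(traces)} traces")
print(f"detected mean peaks/trace: {n_bar:.2f} (groups: "
      + ", ".join(f"{g:.2f}" for g in group_means) + ")")
print(f"cluster flux: {flux:.1f} /s")
print(f"recovered concentration: {c_est*1e15:.1f} fM (true {c_true*1e15:.1f} fM)")
print()
print("Single-cluster counting resolves concentrations far below what")
print("ensemble scattering can see - the femtomolar tail of the cluster")
print("size distribution.")
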