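"""Chemical shift perturbation mapping: find the RNA-binding surface.

Simulates free/bound amide peak tables for the toy complex, computes the
combined 1H/15N shift change per residue and selects the binding-site
residues above the 0.08 ppm threshold.
"""

import numpy as np

from prelink import compute_csp, make_toy_complex, select_above_threshold
from prelink.synthetic import NoiseConfig, simulate_observables

conf, partition, truth = make_toy_complex()
bundle = simulate_observables(truth, NoiseConfig(), np.random.default_rng(0))

profile = compute_csp(bundle.peaks_free, bundle.peaks_bound, alpha=0.2)
hits = select_above_threshold(profile, threshold=0.08)

print(f"CSP profile over {len(profile)} residues; max {profile['delta_delta'].max():.3f} ppm")
print(f"{len(hits)} residues above 0.08 ppm: {hits}")
terminal = partition.rigid_segments()[-1]
in_terminal = [r for r in hits if terminal.start <= r <= terminal.stop]
print(f"of these, {len(in_terminal)} lie in the terminal domain -> they become")
print("ambiguous 4 +/- 1 A restraints to the RNA in the modeling stage.")
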