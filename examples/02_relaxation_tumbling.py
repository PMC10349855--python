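"""15N relaxation analysis: R1/R1rho decay fits to per-domain tumbling times.

Each residue's decay series is fit mono-exponentially; R1rho is corrected to
R2 for the spin-lock offset, and tau_c comes from the R2/R1 ratio.  Rigid
domains tumble slowly (large tau_c); flexible linkers average much lower.
"""

import numpy as np
import pandas as pd

from prelink import domain_average_tauc, make_toy_complex, theoretical_tauc
from prelink.relaxation import fit_rates, rate_table, tumbling_summary
from prelink.synthetic import NoiseConfig, simulate_observables

conf, partition, truth = make_toy_complex()
bundle = simulate_observables(
    truth, NoiseConfig(intensity_frac=0.01), np.random.default_rng(1)
)

r1 = fit_rates(bundle.decays_r1)
r1rho = fit_rates(bundle.decays_r1rho)
rates = rate_table(r1, r1rho, bundle.nu1_hz, pd.Series(bundle.offsets_hz))
summary = tumbling_summary(rates, truth.field_1h_mhz)

print(f"fitted {len(rates)} residues at {truth.field_1h_mhz:.0f} MHz (1H)")
for name, (mean, sd) in domain_average_tauc(summary, partition).items():
    print(f"  {name}: tau_c = {mean:.1f} +/- {sd:.1f} ns")
print("rigid domains cluster near the complex-wide tumbling time;")
print("linkers fall well below it -> they move independently of the domains.")
print(f"for scale: a 14 kDa globular protein expects tau_c ~ {theoretical_tauc(14.0)} ns")
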