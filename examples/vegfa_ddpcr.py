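"""VEGFA copy-number calling from droplet digital PCR counts.

Each 20,000-droplet well yields positive-droplet counts for VEGFA and the
diploid reference gene EIF2C1; Poisson inversion (lambda = -ln(1 - k/n))
gives copies per droplet, and the VEGFA ratio is 2 * lambda_V / lambda_E.
Amplification is called above the healthy-control mean + 3 SD.
"""

import numpy as np

from plasmacna.ddpcr import amplification_call, amplification_cutoff, vegfa_ratio
from plasmacna.simulate import simulate_droplets

rng = np.random.default_rng(3)

# healthy controls cluster near 2 copies; derive the cutoff from them
control_calls = [
    vegfa_ratio(simulate_droplets(20_000, rng.normal(2.0, 0.1), 0.15,
                                  seed=rng, sample_id=f"ctrl{i}"))
    for i in range(14)
]
control_values = [c.copy_number for c in control_calls]
cutoff = amplification_cutoff(control_values)
print(f"control copy numbers: {np.round(control_values, 2)}")
print(f"cutoff (mean + 3 SD): {cutoff:.2f}")

# one diploid patient, one amplified patient (true copy number 9.7,
# the level of the VEGFA-amplified OE19 calibration line)
for name, true_cn in (("diploid_patient", 2.0), ("amplified_patient", 9.7)):
    d = simulate_droplets(20_000, true_cn, 0.15, seed=rng, sample_id=name)
    call = amplification_call(vegfa_ratio(d), control_values=control_values)
    print(f"{name}: k_V={d.k_target}, k_E={d.k_ref} -> "
          f"copy number {call.copy_number:.2f}, amplified={call.amplified}")
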