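"""Forward models: diffusion closed form vs Monte-Carlo oracle.

Evaluates the spatial-frequency-domain diffuse reflectance of the
665 nm calibration phantom (mu_a = 0.01 /mm, mu_s' = 1.1 /mm, n = 1.4)
with the diffusion closed form, then cross-checks it against a
100k-photon Monte-Carlo run Hankel-transformed to the same frequencies.
"""

import numpy as np

from ssoptools import MediumContext, OpticalProperties, diffusion_rd, \
    hankel_rd, mc_rd

props = OpticalProperties(mu_a=0.01, mu_s_prime=1.1)
ctx = MediumContext(n_tissue=1.4)

print("diffuse reflectance of the 665 nm calibration phantom")
print(f"  properties: mu_a={props.mu_a} /mm, mu_s'={props.mu_s_prime} /mm")

profile = mc_rd(props, ctx, n_photons=100_000, seed=1)
print(f"  MC weight ledger imbalance: {profile.weight_ledger_error():.2e}")
for fx in (0.0, 0.1, 0.2):
    rd_diff = diffusion_rd(props, fx=fx)
    rd_mc = hankel_rd(profile, fx).value
    gap = abs(rd_mc - rd_diff) / rd_diff * 100
    print(f"  fx={fx:0.1f}/mm: diffusion {rd_diff:.4f}  "
          f"monte-carlo {rd_mc:.4f}  gap {gap:.1f}%")
print("R_d falls with spatial frequency because high-frequency patterns "
      "probe shallow, scattering-dominated transport; the MC-diffusion gap "
      "grows with fx, which is why Monte-Carlo lookup tables are preferred "
      "for inversion.")
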