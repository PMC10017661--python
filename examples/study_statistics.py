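"""Study statistics on a synthetic ischaemia time course.

Simulates six animals with five bowel ROIs sampled at 0/15/30/45/60 min
(capillary + systemic lactates, terminal histology grade, measured
StO2), normalises capillary lactates against systemic ones, compares
the ischaemic zone with the perfused zones, and correlates the
perfusion biomarkers with StO2.
"""

import numpy as np

from ssoptools import normalise_lactates, pearson, simulate_study, students_t

df = normalise_lactates(simulate_study(n_animals=6, seed=4))

print("normalised capillary lactate (mmol/L) by zone, pooled over time:")
for zone, g in df.groupby("roi_zone"):
    print(f"  {zone:<13} {g['normalised_lactate'].mean():5.2f} "
          f"+/- {g['normalised_lactate'].std():.2f}")

isch = df[df.roi_zone == "ischaemic"]["normalised_lactate"]
vasc = df[df.roi_zone == "vascularised"]["normalised_lactate"]
cmp_ = students_t(isch, vasc, labels=("ischaemic", "vascularised"))
print(f"\nischaemic vs vascularised lactate: t={cmp_.t_statistic:.2f}, "
      f"df={cmp_.degrees_of_freedom}, p={cmp_.p_value:.2e} "
      f"(KS normality check passed: {cmp_.ks_pass})")

for x, y, name in (
        ("normalised_lactate", "sto2_measured", "lactate vs StO2"),
        ("sto2_measured", "park_chiu", "StO2 vs histology grade"),
        ("normalised_lactate", "park_chiu", "lactate vs histology grade")):
    r = pearson(df[x], df[y].astype(float))
    print(f"pearson {name}: r={r.r:+.3f} (n={r.n}, p={r.p_value:.2e})")

print("\nLactate rises as StO2 falls (negative r), and both track the "
      "terminal histological injury grade, mirroring how an optical "
      "oximeter is validated against biochemical and histological ground "
      "truth.")
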