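"""Survey-layer transformations at the reference Bornean coefficients.

Prints the protocol-specific nest detection probabilities, the interview
detection probabilities by forest-entry frequency, the forest-type nest
decay times, and an aerial-index conversion. These are the quantities a
field ecologist uses to turn raw nest survey output into animal densities.
"""

import pandas as pd

from apedyn import reference
from apedyn.observation import (aerial_index_to_nest_density,
                                interview_detection_prob,
                                nest_count_detection_prob,
                                nest_occurrence_detection_prob,
                                nest_scaling_factor,
                                orangutan_density_from_nests)

obs = reference.borneo_observation_params()

print("Nest detection by survey protocol:")
for protocol in ("aerial", "ground"):
    print(f"  {protocol:7s} {100 * nest_count_detection_prob(obs, protocol):.0f}%")
print(f"Sub-cell nest occurrence detection: "
      f"{100 * nest_occurrence_detection_prob(obs):.0f}%")
print("Interview detection (respondent enters forest "
      "less / more than monthly): "
      f"{100 * interview_detection_prob(obs, 0):.0f}% / "
      f"{100 * interview_detection_prob(obs, 1):.0f}%")

print("\nNest decay time by forest type (days):")
for label, flags in [("baseline", {}), ("mangrove", {"MGV": 1}),
                     ("peat", {"PT": 1}), ("lowland", {"LOWL": 1}),
                     ("montane", {"MONT": 1})]:
    row = {"MGV": 0, "PT": 0, "LOWL": 0, "MONT": 0, "FRGM": 0}
    row.update(flags)
    psi = nest_scaling_factor(obs, pd.DataFrame([row]))[0]
    print(f"  {label:9s} {psi:.0f}")

ai = 2.0   # nests seen per km of helicopter flight
gnest = aerial_index_to_nest_density(ai)
gou = orangutan_density_from_nests(gnest, d=228.0)
print(f"\nAerial index {ai} nests/km flight -> {gnest:.0f} nests/km2 "
      f"-> {gou:.2f} animals/km2 (0.9 builders x 1.1 nests/day x 228 days)")
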