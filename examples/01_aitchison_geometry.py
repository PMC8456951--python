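"""Basic Aitchison geometry: closure, perturbation, distance, evenness.

Relative-abundance vectors live on the simplex, where ratios — not
absolute proportions — carry the information.
"""

import numpy as np

from oligocoda import (
    Composition,
    aitchison_distance,
    aitchison_index,
    closure,
    perturb,
    perturb_diff,
)

winter = Composition.from_counts([55, 2, 12, 5, 4, 22], "O1 O2 O3 O4 O5 O6".split())
summer = Composition.from_counts([25, 25, 15, 12, 10, 13], winter.labels)

print("winter composition:", np.round(winter.parts, 3))
print("summer composition:", np.round(summer.parts, 3))

# the perturbation that turns winter into summer (simplex 'difference')
shift = perturb_diff(summer, winter)
print("seasonal shift (perturbation):", np.round(shift.parts, 3))
print("  -> applying it to winter recovers summer:",
      np.round(perturb(winter, shift).parts, 3))

d = aitchison_distance(winter, summer)
print(f"Aitchison distance winter->summer: {d:.3f}  (0 means identical ratios)")

for name, comp in [("winter", winter), ("summer", summer)]:
    idx = aitchison_index(comp)
    print(f"{name}: AI2={idx.ai2:.3f}, scaled={idx.scaled:.3f} "
          "(scaled near 1 = one or two parts dominate)")

print("closure is scale-invariant:", np.allclose(closure([10, 20, 30]), closure([1, 2, 3])))
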