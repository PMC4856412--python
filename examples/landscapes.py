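"""Generate the four landscape regimes and summarise their geometry.

Each regime is drawn on the default 200 x 200 torus.  The printed numbers
are the resource-site count, total food units, and (for a poisoned variant)
the poison fraction; they show the scarce < average < abundant ordering the
regimes are defined by.
"""

import numpy as np

from wellforage import MAP_KINDS, MapSpec, generate_map

rng = np.random.default_rng(0)

print(f"{'regime':18s} {'sites':>7s} {'food units':>11s}")
for kind in MAP_KINDS:
    grid = generate_map(MapSpec.for_kind(kind), rng)
    sites = int((grid.food > 0).sum())
    print(f"{kind:18s} {sites:7d} {grid.total_food():11d}")

spec = MapSpec.for_kind("patchy_abundant", poison_fraction=0.7)
grid = generate_map(spec, rng)
sites = int((grid.food > 0).sum()) + grid.total_poison()
print(
    f"\npoisoned patchy_abundant: {grid.total_poison()} of {sites} resource"
    f" sites are poison ({grid.total_poison() / sites:.1%}; nominal 70%)."
)
print("Poison items cost one fitness unit each when consumed.")
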