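"""Browse the packaged polysaccharide structures and their enzyme needs.

Loads the soluble galactoglucomannan map, lists its bond classes, and joins
them against the activity registry to get the six enzymatic activities a
fungus must express to take the polymer apart completely.
"""

from psdmap import (
    enumerate_bond_classes,
    list_structures,
    load_structure,
    required_activities,
    residue_composition,
)

print(f"{len(list_structures())} packaged structures:")
print(" ", ", ".join(list_structures()))

s = load_structure("soluble_galactoglucomannan")
print(f"\n{s.name}: {len(s)} residues")
comp = residue_composition(s)
print("composition:", {k: round(v, 2) for k, v in comp.items()})

print("\nbond classes (the join key to enzymatic activities):")
for label, context in sorted(enumerate_bond_classes(s)):
    print(f"  {context:<13} {label}")

req = required_activities(s)
print(f"\nrequired activities ({len(req)}):")
for act in req:
    print(f"  {act.ec or '(no EC)':<10} {act.mode:<16} {act.name}")

# Each activity is needed: the endo-mannanase opens the backbone, the two
# exo glycosidases peel mannose/glucose from non-reducing ends, the
# alpha/beta-galactosidases clear the galactosyl branches, and the acetyl
# esterase removes the esters that block every glycosidase.
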