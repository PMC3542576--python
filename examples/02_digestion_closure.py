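"""Digest galactoglucomannan with complete and incomplete enzyme sets.

Shows the closure engine's central behaviours: the full required set
converts everything to free monosaccharides (completeness 1.0), dropping
the debranching alpha-galactosidase strands the backbone behind its
branches, and the blocker report names the bond class responsible.
"""

from psdmap import (
    digest,
    explain_blockers,
    get_activity,
    load_structure,
    minimal_sufficient_sets,
    required_activities,
)

s = load_structure("soluble_galactoglucomannan")
req = required_activities(s)

full = digest(s, req)
print(f"full set of {len(req)} activities:")
print(f"  completeness {full.completeness:.2f}, "
      f"monomer yield {full.monomer_yield}")

partial = [a for a in req if a.name != "α-galactosidase"]
res = digest(s, partial)
print(f"\nwithout α-galactosidase: completeness {res.completeness:.2f}")
print(f"  leftover fragments (DP): {sorted(len(f) for f in res.fragments)}")
for msg in explain_blockers(res):
    print(f"  blocker: {msg}")

# which subsets of a candidate set suffice for cellulose?
cel = load_structure("cellulose")
cands = [get_activity("endo-1,4-β-glucanase"), get_activity("β-glucosidase"),
         get_activity("α-amylase")]
print("\nminimal sufficient sets for cellulose from "
      f"{[a.name for a in cands]}:")
for subset in minimal_sufficient_sets(cel, cands):
    print("  ", sorted(a.name for a in subset))
# the alpha-amylase (an alpha-1,4 starch enzyme) never appears: it cannot
# touch a beta-1,4 glucan.
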