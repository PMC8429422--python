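"""Meta-star: amplifier at the migration extremes, piecewise in between.

A hub patch connected to three leaf patches, all of size 5, is classified
against the well-mixed population of size 20 in three migration regimes.
"""

import metafix as mf

star = mf.meta_star(4, 5)

for name, method, lam in (
    ("low migration ", "lowmig", None),
    ("lambda = 0.1  ", "exact", 0.1),
    ("full migration", "bipartite", 1.0),
):
    label = mf.classify_structure(star, method, lam)
    extra = f", sign changes near r = {label.sign_changes}" if label.sign_changes[1:] else ""
    print(f"{name}: {label.label}{extra}")

print()
r = 1.5
print(f"at r = {r}: closed form phi_star = {mf.fixation_metastar(4, 5, r):.6f}, "
      f"well-mixed = {mf.fixation_wm(r, 20):.6f}")
print()
print("At both migration extremes the meta-star amplifies selection like the")
print("star graph of individuals; at intermediate migration the sign of the")
print("difference flips across the fitness range (piecewise amplifier).")
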