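"""Well-mixed Moran baseline: the reference every structure is compared to.

A single mutant of relative fitness r in a well-mixed population of size N
fixes with probability (1 - 1/r) / (1 - 1/r^N); a neutral mutant with 1/N.
"""

import metafix as mf

N = 10
for r in (0.5, 1.0, 1.5, 2.0):
    phi = mf.fixation_wm(r, N)
    print(f"r = {r:4.1f}  phi_wm = {phi:.6f}")

print()
print("A deleterious mutant (r<1) almost never fixes, a neutral one fixes")
print(f"with 1/N = {1 / N}, and selection lifts an advantageous mutant well")
print("above that; these closed-form values anchor all structured results.")
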