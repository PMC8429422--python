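"""Monte Carlo simulation of the individual-level process vs the exact chain.

The simulator realises the Birth-death meta-population process event by
event; its binomial estimate should straddle the exact absorption
probability within a couple of standard errors.
"""

import metafix as mf

g = mf.two_patch(3, 7)
lam, r = 0.1, 1.5

exact = mf.fixation_exact(g, lam, r).phi
est = mf.estimate_fixation(g, lam, r, mf.SimConfig(replicates=50_000, seed=1))

print(f"exact chain        phi     = {exact:.5f}")
print(f"simulator (5e4)    phi_hat = {est.phi_hat:.5f} +- {est.se:.5f}")
print(f"fixed/extinct/censored     = {est.n_fixed}/{est.n_extinct}/{est.n_censored}")
print(f"|phi_hat - phi| / se       = {abs(est.phi_hat - exact) / est.se:.2f}")
print()
print("The z-score should rarely exceed ~2-3; censored replicates (event cap")
print("reached) are reported separately and never folded into the estimate.")
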