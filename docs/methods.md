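# Methods

## Process definition

The meta-population is an undirected, connected graph of M patches; patch j
holds a well-mixed sub-population of constant size N_j, total N = Σ N_j.
Two types compete: wild-type (fitness 1) and mutant (fitness r > 0).
Updating is Moran Birth–death with **global** selection: per event one
parent is drawn from the entire meta-population proportional to fitness,
and its offspring replaces one individual chosen by the replacement
weights. With probability 1 − λ the offspring stays in the natal patch and
replaces a uniform individual there (the mother included); with probability
λ it migrates and replaces an individual among the adjacent patches.

Two migration conventions are supported for choosing the replaced
individual when migrating:

- **union** (canonical, used by the exact chain and simulator): uniform
  over the union of individuals in all adjacent patches — per-individual
  weight λ / Σ_{k∈V(i)} N_k;
- **patch**: an adjacent patch uniformly, then an individual uniformly —
  per-individual weight λ / (deg(i) · N_j).

The conventions coincide whenever all neighbours of a patch have equal
size, which covers every structure with a closed form here (two-patch,
equal-size meta-star, regular graphs). For irregular size profiles they
genuinely differ; the `convention` flag exists for sensitivity checks, and
the coarse-grained route uses the patch kernel its derivation is built on.
A sole patch (M = 1) keeps all replacement internal regardless of λ, so the
well-mixed closed form is a strict special case.

## Routes and their numerics

**Well-mixed closed form.** Because the backward/forward transition ratio
of the mutant-count chain is the constant 1/r, the fixation probability
from i mutants is φ_i = (1 − r^−i)/(1 − r^−N). It is evaluated via
`expm1` of −i·log r and −N·log r, with an explicit i/N branch for
|r − 1| < 1e−12 and a log-space fallback once N·|log r| > 700 (where r^−N
overflows). This keeps the curve continuous through neutrality and correct
for sizes far beyond float overflow.

**Exact chain.** States are per-patch mutant-count vectors indexed in
mixed radix (patch document order, first patch most significant); the
transition matrix is assembled vectorised over all ∏(N_j + 1) states. For
λ > 0 the only absorbing states are all-mutant and all-wild-type, and the
absorption system is solved on the embedded jump chain (self-transitions
stripped row-wise and rows renormalised — mathematically identical, better
conditioned). The sparse LU solution is then refined: the system is
rebuilt in 80-bit extended precision and 3–4 iterations of mixed-precision
iterative refinement run against the double-precision factorisation.
This matters because the condition number grows like 1/λ as migration
becomes rare; plain LU leaves ~1e−10 errors at λ = 1e−6 on the 1296-state
meta-star, refinement brings them to ~1e−13. Systems above 1e5 transient
states fall back to GMRES (residual tolerance 1e−12, recorded in the
result); above the 2e6-state ceiling a capacity error points to the
simulator. For λ = 0 and M ≥ 2 the mixed homogeneous configurations are
additional absorbing states and a single mutant can never fix globally;
the solver returns 0 with a warning rather than erroring, marking the
regime boundary.

**Low-migration coarse graining.** When 1/λ is much longer than any
within-patch absorption time, the meta-population is homogeneous at
migration events and the dynamics reduce to a chain on the 2^M binary
patch configurations. A wild-type patch k adjacent to a mutant patch j
flips with probability (r N_j / F) · (λ/deg j) · φ_wm(r, N_k), where
F = r·(mutant mass) + (wild mass) is the global selection normaliser; the
reverse flip uses the 1/r mirror. Since λ multiplies every coarse
transition it cancels from the absorption probabilities, so the route is
λ-free. The fixation probability combines two phases: the founding mutant
first fixes its own patch (probability φ_wm(r, N_j), origin weighted by
N_j/N), then the homogeneous patch spreads (coarse absorption A(e_j)).
The validity threshold in λ is not enforced — the approximation is
documented, and its quality is checked against the exact chain (agreement
to ~1e−3 at λ = 1e−6 on both canonical structures; the error grows to
~1e−2 by λ = 0.01).

Closed forms: the two-patch expression (per-origin products of local
fixation and patch-level invasion odds) and the equal-size meta-star form.
For the meta-star, the exit probabilities T_open / T_filled of the two
center states are independent of the number of mutant leaves, which
collapses the leaf-count recursion to a geometric sum; the resulting
closed form was derived independently and verified against the 2^M solver
to 1e−16 over the fitness grid. All closed forms are finite and accurate
through r = 1 (the neutral branch of φ_wm removes the 0/0).

`metastar_amplification_gap` evaluates φ_star − φ_wm with mpmath at 200
decimal digits: for M·N1 ≈ 300 both probabilities agree to ~1e−90-ish for
strongly favoured mutants and the gap underflows doubles entirely, yet its
sign is the amplifier statement being scanned.

**Maximal migration.** At λ = 1 every offspring leaves its patch, so the
two-patch meta-population is the complete bipartite graph K_{N1,N2} of
individuals and the meta-star is K_{(M−1)N/M, N/M} (leaves vs hub). The
product h1^a h2^b over part-wise mutant counts is a martingale of the
process (verified in tests against one step of the exact chain), giving
φ^1 = (h1 − 1)/(h1^{N1} h2^{N2} − 1) and its part-2 counterpart. The
denominator is computed as `expm1(N1·log1p(h1−1) + N2·log1p(h2−1))` with
h − 1 formed cancellation-free as (1/r − r)/(N_j/N_i + r); for
|r − 1| < 1e−8 the analytic limits φ^1 = N1/(N1² + N2²) etc. are used.

**Simulator.** The individual-level process is simulated event by event:
parent categorical over (patch × type) cells, landing patch from the
precomputed row-stochastic landing matrix, replaced individual uniform in
the landing patch. Replicates run in fixed batches of 8192 that advance in
lockstep on vectorised arrays, with absorbed replicates compacted away;
each batch owns a `SeedSequence`-spawned child stream, so results are
bit-reproducible for a given seed and a batch's trajectories do not depend
on how many batches follow (per-replicate stream independence is relaxed
to per-batch granularity — the price of vectorisation). Replicates hitting
the event cap (default 1e7) are reported as censored and excluded from the
binomial estimate with a warning, never folded into either outcome:
silent truncation would bias φ̂ downward exactly in the slow low-λ regime.

## Classification

A structure is classified against φ_wm(·, N) on a log-spaced fitness grid
(default 41 points on [0.25, 4]) excluding a ±1e−3 guard band around r = 1
where the sign of the difference is numerically meaningless. Labels are
strict sign patterns outside a tolerance (default 1e−12 for
closed-form/exact curves): amplifier (+ above 1, − below), suppressor
(reverse), enhancer/reducer (one sign everywhere), isothermal-equivalent
(tied everywhere), else piecewise with the geometric midpoints of
sign-change brackets reported — this covers what is informally called a
transient amplifier. For structures whose fixation probabilities decay
toward double-precision noise at the grid edges (e.g. a 25-individual
meta-star at r = 0.25, where both probabilities are ~1e−15 but relatively
accurate), the tolerance must be tightened below the probabilities
themselves for the pattern to resolve; the hub-vs-leaf scan uses 1e−15.

## Synthetic inputs

No external data exist for this problem: all inputs are structures built
in code (`two_patch(3, 7)`, `meta_star(4, 5)`, `cycle(3, 3)`, and JSON
documents of the same dialect). The canonical sizes are deliberately
small so the exact chain (32 and 1296 states) is a cheap, airtight oracle;
conclusions about much larger patch sizes rest on the closed forms and the
high-precision scan, not on enumeration. The Monte Carlo defaults used in
tests (2e4–1e5 replicates) put standard errors at ~1.5e−3, enough to
detect the regime-level effects (~2e−2 gaps) but not the 1e−10 agreements,
which only the analytical routes certify.

## Known limitations

- Weighted, directed, or time-varying migration graphs, patch
  extinction/recolonisation, and death–Birth (local competition) updating
  are out of scope; amplifier/suppressor conclusions here are specific to
  Birth–death with global selection.
- The low-migration route has no enforced validity threshold in λ.
- Fixation *times* are not computed anywhere; the simulator exposes raw
  event counts but does not analyse them.
- For structures where a patch's neighbours have unequal sizes the union
  and patch migration conventions differ and the choice is a genuine
  modelling decision; results for such structures should be reported with
  the convention stated.
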