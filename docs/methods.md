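# Methods

## Model

`cryptdyn` models colorectal carcinogenesis as a continuous-time linear
dynamical system over crypt genotypes. The colon is treated as a
population of `n_crypts = 9.95e6` independent crypts; each crypt carries
one genotype, a tuple of per-gene mutation statuses for the modelled
driver genes (MMR gene, CTNNB1, APC, KRAS, TP53). Mutations are
irreversible and assumed to be fixed (monoclonally converted) in the whole
crypt; intra-crypt dynamics are not modelled, they are summarized by a
per-gene fixation affinity `f(gene)`. The state vector `x(t)` holds the
expected number of crypts in each genotype at patient age `t` (years), and

    dx/dt = Mᵀ x,   M = A + B + C + D + E + F.

Because the model is linear and time-invariant, the solution
`x(t) = expm(t Mᵀ) x₀` is exact; no time-stepping error enters.

### Per-gene mutation graphs

Each gene's mutation statuses form a directed acyclic graph under the
canonical order ∅ < m < l < mm < ml < ll. Which statuses exist depends on
the gene's functional role:

* MMR gene, hereditary (Lynch) context: {m, l, mm, ml, ll} — every cell
  carries the germline first hit, so ∅ is absent;
* MMR gene, sporadic context: {∅, m, l, mm, ml, ll};
* APC, TP53, CTNNB1: {∅, m, l, mm, ml} — the homozygous-deletion status
  ll is omitted because losing both copies of these genes kills the cell
  before a crypt could fix it; the l→ll flux is simply removed (no
  explicit death state);
* KRAS: {∅, m} — one activating point mutation suffices, and no LOH
  channel is modelled (no KRAS gene length is used).

Point-mutation edges (∅→m, m→mm, l→ml) carry the rate
`365·n_pt·n_cells·(n_hs/n_bp,genome)·f·(1−n_mut/2)`: the daily mutation
load of the crypt's dividing cells restricted to the gene's hotspot
positions, converted to years, scaled by the fixation affinity, and
halved when one allele is already hit (the remaining target is one
allele). LOH edges (∅→l, m→ml, l→ll) carry
`365·n_cells·(1−n_mut/2)·α·n_bp·f`, proportional to the full gene length
since any overlapping loss inactivates the gene.

The per-bp LOH constant α is not independently measurable; it is
calibrated from the observation that MLH1 inactivation is twice as likely
by LOH as by point mutation, giving
`α = 2·n_hs(MLH1)·n_pt / (n_bp(MLH1)·n_bp,genome) ≈ 2.961e-11` per bp.
α is gene-independent thereafter.

### Diagonal convention and fitness

The sources that define the mutation graphs draw self-loops ("no
mutation" plus a fitness change) but never print diagonal values. We use
the continuous-time generator convention: each diagonal entry is
`b(state) − Σ(outgoing rates)`, where `b(state)` equals the gene's fitness
term `b_altered` on its functionally altered statuses (MMR: mm/ml/ll;
APC, TP53, CTNNB1: mm/ml; KRAS: m) and 0 elsewhere. Two reasons:

1. the solution is a matrix exponential over decades; any other diagonal
   convention (e.g. a discrete-time `1 − Σout`) adds a constant to every
   diagonal and multiplies the solution by a spurious global exponential;
2. with all `b = 0` every row of `M` sums to zero, so the dynamics
   conserve the total crypt count exactly — a sharp correctness
   diagnostic used in the tests (conservation holds to ~1e-15 relative
   over 70 years).

Fitness terms model clonal expansion (b > 0: APC inactivation 0.10/yr,
KRAS activation 0.01/yr) or disadvantage (b < 0: MMR deficiency
−0.01/yr) at the crypt level; proliferation and disappearance are jointly
absorbed into the self-loop rather than tracked via explicit death
states. Whether `b` should also apply to intermediate single-hit statuses
is not settled; we attach it to the altered statuses only.

### Kronecker assembly

Under independence, the genotype-level rate matrix is the Kronecker sum
`A = A_MMR ⊕ A_CTNNB1 ⊕ A_APC ⊕ A_KRAS ⊕ A_TP53` — the adjacency matrix
of the Cartesian product of the gene graphs, encoding exactly the
one-gene-at-a-time transitions (5·5·5·2·5 = 1250 genotypes for the Lynch
model). The flat genotype index is row-major with the MMR gene most
significant, fixed by the Kronecker factor order.

Dependencies are additive components, each a Kronecker product of a small
modified gene factor with 0/1 selector diagonals and identities:

* **B** (β = 10³): APC's point-mutation edges scaled by β, gated by the
  selector `diag(0,0,1,1,1)` on MMR-deficient statuses;
* **F** (ζ = 10²): KRAS's activation edge scaled by ζ, same MMR gate;
* **D** (δ = 10²): LOH edges of the MMR gene, CTNNB1 and TP53 scaled by
  δ, gated by `diag(0,0,0,1,1)` on APC-inactivated statuses; one
  Kronecker term per target gene (D = D₁+D₂+D₃);
* **C** (r_effLOH = 0.9, MLH1 only): for each MLH1 LOH-gaining transition
  (m→ml, l→ll) with CTNNB1 able to gain an LOH (∅ or m), weight
  `−r·p_LOH(MLH1)/2` on the plain transition and `+r·p_LOH(MLH1)/2` on
  the simultaneous transition whose CTNNB1 status also advances by one
  LOH. Eight edge families × 50 background states = 400 structural
  nonzeros;
* **E** (δ·r_effLOH): the same eight-edge pattern with magnitude
  `δ·r·p_LOH(MLH1)/2`, additionally gated on APC inactivation (160
  nonzeros) — the mutual enhancement of C and D.

Signs in C/E are chosen so that each removed flux is paired with an equal
added flux in the same row: every dependency matrix has exactly zero row
sums (pure flux rerouting/acceleration, never mass creation), all fitness
lives in A, and the 400-nonzero count of C emerges without diagonal
compensation. With an MSH2 scenario, C and E are structurally zero (the
CTNNB1 association is specific to MLH1).

In a sporadic-MMR (6-status) model, D's MMR factor also scales the ∅→l
LOH edge — an extrapolation beyond the hereditary definition, applied for
consistency of the "all LOH rates increase" reading.

### Solver

`solve()` uses the dense `scipy.linalg.expm` up to dimension 2000
(default; the 1250-state model takes milliseconds): on a uniform age grid
one per-step propagator `expm(h·Mᵀ)` is computed and iterated, which is
exact for a time-invariant system. Above the threshold it switches to
`scipy.sparse.linalg.expm_multiply` action on the vector. Entries more
negative than `−1e-9·‖x₀‖₁` raise an error (they would signal a broken
sign convention, since `Mᵀ` has nonnegative off-diagonals and therefore
preserves nonnegativity); smaller floating-point undershoots are clamped
to zero. `solve_factorized()` exploits that, for the independent-only
model and a product initial state, the solution is the Kronecker product
of per-gene exponentials `⊗ᵢ expm(t Aᵢᵀ) eᵢ` — it agrees with the full
exponential to better than 1e-8 relative and is the cheap route for large
gene sets.

The default age grid is 0–70 years in 1-year steps.

### Scenarios and initial values

Every scenario starts with all crypts in a single germline genotype
(`n_crypts` at one index): Lynch with point germline at (m,∅,∅,∅,∅), with
LOH germline at (l,∅,∅,∅,∅) — the two germline classes (90–95% point
mutation vs 5–10% LOH) are separate presets, not mixed in one run;
Lynch-like/sporadic MSI at all-wild-type with the 6-status MMR factor;
FAP at (∅,∅,m,∅,∅) with the APC hotspot count reduced to the 600-bp
germline mutation cluster region; MSS and sporadic-APC with the MMR
factor removed entirely (250 genotypes, only D's CTNNB1/TP53 terms
active).

### Queries

Aggregates are sums over genotype classes defined by per-gene admissible
status sets. "Intact" is functional by default (TP53 intact ⇔ not
biallelically inactivated; KRAS intact ⇔ wild-type); a strict
wild-type-only variant is available (`strict=True`), and is a subset of
the functional one. "Wnt-altered" is the union of APC inactivation and
CTNNB1 activation by default (`wnt="and"|"apc"|"ctnnb1"` give the
conjunctive reading and the per-driver decomposition). The
adenoma–carcinoma stage proportions (`pathway_proportions`) split each
stage into MMR-deficient vs MMR-proficient crypts; stages are exclusive
by default (a crypt counts only in the latest stage it has reached), the
reading under which the early-stage deficient/proficient balance is
meaningful — in cumulative form the APC-inactivated pool is dominated at
later ages by the almost-entirely-deficient KRAS-activated crypts.
Empty-stage fractions are reported as NA, never propagated as 0/0.

## Numerical choices

* All rates are double precision per-year quantities; no capping or
  renormalization is applied (the largest default rate is ~4e-4/yr).
* Row-sum zero tests tolerate ~1e-15 absolute residue after summing six
  components.
* The brute-force oracles (Cartesian-product adjacency by vertex-pair
  enumeration; dense reference exponential) refuse dimensions above 256 —
  they exist to check the fast paths on toy models, not to run the model.
* Toy-model rates are drawn from [1e-6, 1e-1]/yr, spanning the magnitudes
  of the real parameter set.

## What the tests show, and what they do not

The test suite verifies the algebraic structure (upper triangularity,
bijective indexing, zero row sums, selector gating, the 400/160 nonzero
counts), exactness of the solver against closed forms and brute-force
references, conservation, the factorization identity, and the qualitative
clinical orderings (Lynch > Lynch-like MMR-deficient foci at every age;
the MMR-deficient fraction rising with KRAS activation and unchanged by
TP53 inactivation; identical stage proportions when all dependencies are
off — exact in that case, because the solution factorizes over genes).
None of this validates the parameter values against patients: the rates
and fitness terms derive from literature estimates, and the absolute
crypt counts inherit their uncertainty. The model is deterministic
(expected counts); it has no stochastic fluctuation, no immune
interaction, no explicit death states, and no intra-crypt dynamics.

## Known limitations

* The FAP preset yields ~1.07e5 APC-inactivated crypts at age 70 — the
  germline-state outflux (9.8 crypts/yr at the 600-bp hotspot count)
  compounded at b(APC) = 0.1/yr for 70 years. This is the upper edge of,
  and slightly above, the 10⁴–10⁵ range quoted in the clinical-modelling
  literature for this setting; the figure is sensitive to the diagonal
  convention (yearly discrete compounding would give ~8.5e4) and to
  b(APC).
* The allele-phase of the ml status is not tracked, dominant-negative
  single-hit effects are ignored, and hotspot counts are taken as given
  constants (the APC count of 2400 derives from ~4000 tumour samples by
  an unspecified procedure).
* Dependency components exist only for the five relationships listed;
  e.g. no TP53 rate is MMR- or KRAS-dependent, which is why TP53
  inactivation leaves pathway proportions unchanged.
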