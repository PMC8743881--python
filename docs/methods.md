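# Methods

## Model and procedure

`domcert` infers pairwise dominance from a win/loss count matrix by
combining direct observations with evidence carried along indirect
directed pathways, in five stages.

**1. Network construction.** Each strictly positive count `c(i,j)`
becomes a directed edge `i → j` with that weight; both directions of a
contested dyad coexist. Individuals with no interactions remain as
isolated nodes — a never-interacting dyad is a meaningful state, not
missing data.

**2. Directed transitivity.** Each dyad is binarised to a majority
direction (`c(i,j) > c(j,i)` ⇒ `i` over `j`; ties, including 0–0, are
undecided). A node triple is *decided* when all three dyads are; decided
triples are transitive (one animal beats both others, one loses to both)
or cyclic. The transitivity index `t` is the transitive share among
decided triples. The census uses the closed forms `Σ D∘D²` (transitive)
and `tr(D³)/3` (cyclic) on the binarised adjacency `D`, which has no
mutual edges; the test suite checks both against exhaustive triple
enumeration.

When *no* triple is fully decided, `t` defaults to 1. Rationale: absence
of any closed triangle means no intransitivity has been observed, and a
default of 0 or 0.5 would silently discard all indirect information in
sparse chain-like networks — exactly the data the method exists to
handle. The default is configurable (`--default-transitivity`) and
recorded in every run summary.

**3. Evidence imputation.** Every simple directed path `i → … → j` of
length `ℓ` (edges), `2 ≤ ℓ ≤ L`, contributes

    w(path) = β^(ℓ−1) · Π_e f(e),    β = max(0, 2t − 1),
    f(e) = c(e) / (c(e) + c(reverse e)),

as a fractional win for `i` over `j`, added to the direct count. The
linear map from `t` to `β` sends chance-level transitivity (t = 0.5,
as many cyclic as transitive triangles) to zero weight and perfect
transitivity to full weight; the geometric exponent discounts longer
chains; the per-edge consistency factor caps each path at one fractional
win and penalises chains built on contested dyads. Paths in both
directions are imputed independently — contradictory flow is kept, not
netted, because it is precisely what the certainty metric must see.
Paths are simple (no repeated nodes): a revisit adds no independent
information and would break termination.

**4. Dominance probability.** `DP(i,j) = (e(i,j) + s)/(e(i,j) + e(j,i)
+ 2s)` with prior `s > 0` pseudo-wins per direction. By construction
`DP(i,j) + DP(j,i) = 1` and a dyad with zero evidence in both directions
sits exactly at 0.5. Default `s = 0.5` (a Jeffreys-style half-win): small
enough not to drown real data, large enough that a single observed win
yields 0.75 rather than certainty.

**5. Ordering, tiers, certainty.** The order maximising the
upper-triangle DP sum is found exactly (n ≤ 8) or by simulated annealing.
Dominance certainty is `DC(i,j) = max(DP, 1−DP) ∈ [0.5, 1]`; individual
DC is the mean over all partners (non-interacting partners included,
since their DP is exactly what the indirect machinery estimates); group
DC is the mean over individuals, which provably equals the mean over
unordered dyads — asserted to 1e-12 in the tests. Adjacent animals in the
best order merge into one rank tier while the upper-over-lower DP stays
below the ambiguity threshold (default 0.70); tiers are contiguous runs
along the diagonal of the reordered matrix. The average-linkage
dendrogram over the rank distance `|2·DP − 1|` is provided as the
equivalent visual/clustering view, and on clean block-structured
matrices the two agree.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_path_length` (L) | 2 | longest indirect path used, in edges; configurable to 6, beyond which simple-path enumeration is combinatorially explosive |
| `prior` (s) | 0.5 | smoothing pseudo-wins per direction |
| `default_transitivity` | 1.0 | t assumed when no triple is decided |
| `tier_threshold` | 0.70 | adjacent DP below this merges a tier |
| `exact_max_n` | 8 | largest group solved exhaustively |
| `restarts` | 50 | annealing restarts |
| cooling factor | 0.97 | geometric temperature schedule |

Annealing details: each restart starts from the descending row-sum order,
proposes adjacent transpositions or random pair swaps (n proposals per
temperature level), accepts by the Metropolis rule, and cools from an
initial temperature equal to the standard deviation of sampled swap
deltas down to 10⁻³ of it. Ties everywhere resolve lexicographically by
id sequence, so identical seeds give bit-identical results. The suite
verifies the annealed optimum equals the exhaustive one on 100 seeded
6–7-animal problems.

## Certainty diagnostics

Low DC can mean two different things. The diagnostic classifies every
unordered dyad as interacting or non-interacting and summarises the
distribution of indirect-path counts (both directions, lengths 2..L) per
class. When transitivity is high (default cutoff t ≥ 0.9) and
non-interacting dyads still sit on abundant pathways (median ≥ 1), their
uncertainty is flagged *likely biological* — the network had the
information and the relationships are genuinely ambiguous or avoided.
When transitivity is low or pathways scarce, the flag is *likely
inferential*. Both cutoffs are reported in the output, never silently
applied, and the diagnostic is deliberately descriptive — no hypothesis
test is implied.

## Synthetic data

`simulate_group(n, steepness, encounter_rate, zero_fraction, seed)` draws
from a latent linear hierarchy: ranks are a seeded permutation of the
ids; each unordered dyad is a structural zero with probability `z`, else
interacts `Poisson(λ)` times; each encounter is won by the higher-ranked
member with probability `1/(1 + exp(−a·Δ))`, `Δ` the absolute rank
difference. Defaults (a = 2, λ = 10, z = 0.3) describe a steep,
moderately sparse hierarchy typical of despotic macaque groups and are
the reference conditions of the acceptance suite, which uses n = 15,
small enough that ten full pipeline runs (including the annealed search)
complete in well under a minute.

The generator captures the features the inference machinery is sensitive
to — steepness, sampling intensity, sparsity — and deliberately omits
kin structure, temporal dynamics, observation bias correlated with rank,
and rank changes over time. Passing tests therefore show the pipeline
recovers a *static* latent hierarchy from sparse noisy counts; they do
not certify behaviour under rank instability or structured missingness.

Two analytic fixtures complement the simulator: a linear chain (sparse
but fully orderable through indirect paths) and `pathway_motifs()`, a
nine-animal network contrasting a dyad decided by two consistent
indirect pathways (A over D, never interacting, DP = 5/6 at L ≥ 2 under
the defaults) with a dyad receiving contradictory flow (I over F via one
short path, F over I via a longer chain, DC = 0.5 at L ≥ 3). Deleting the
contradictory chain raises DC(F, I) to 0.75 — the fixture's whole point.

## Numerical and design notes

- **Monotonicity** (more direct wins ⇒ no lower DP) holds exactly when
  the transitivity weight is held fixed: indirect evidence for a dyad
  never traverses that dyad's own edges (simple paths cannot revisit
  their endpoints), so adding a win only raises `e(i,j)`. If `t` is
  *re-estimated*, an added win can flip a dyad's majority direction,
  change the census, and shrink β — so DP can legitimately move toward
  its direct-only value. The property test pins `t` accordingly.
- DP diagonals are masked NaN; all reductions use NaN-aware operations.
- Score comparisons in the searches use a 1e-9 tie tolerance; the
  annealed best score is recomputed from scratch at the end of each
  restart, so accumulated per-move deltas cannot drift into the result.
- With L = 1, or β = 0, the pipeline reduces exactly (to 1e-12) to the
  smoothed direct win proportion — a closed form the tests check against.
- Degenerate inputs: all-zero matrices analyse cleanly (everything at
  DP = 0.5, one tier); isolated individuals keep DC contributions of 0.5
  from each unreachable partner.
- The `|2·DP − 1|` rank distance is this package's choice for the
  dendrogram metric; it maps ambiguity (0.5) to distance 0 and certainty
  to 1, making the tier threshold 0.70 correspond to tree height 0.40.

## Known limitations

- Simple-path enumeration is exponential in L; L > 6 is refused. For the
  default L = 2 cost is O(n³).
- Exact ordering is factorial; above `exact_max_n` the annealed search
  carries no global-optimality guarantee (only the empirical oracle
  checks at small n).
- The transitivity-to-weight map β = 2t − 1 is one reasonable calibration
  of "weight paths by transitivity"; no claim of numerical parity with
  other software implementing the same idea is made.
- Point probabilities only: no posterior intervals on DP.
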