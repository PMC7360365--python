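# Methods

## Model

A glycan oligomer is a rooted tree. Nodes are monomers of user-declared
types; each type carries a finite set of acceptor carbons (positions where a
branch may attach) and one donor carbon (the position used when the monomer
is itself attached — the anomeric carbon in real sugars). Each edge records
the pair *(acceptor carbon on the parent, donor carbon on the child)*. One
branch may occupy one carbon; occupied carbons never free up, because
O-glycan-style growth is irreversible (no pruning, no editing). The
protein/lipid anchor is not modeled: the root monomer is the tree root, and
anchor identity is irrelevant to the combinatorics. Consequently every
intermediate of a synthesis is a root-containing connected subtree
("sub-oligomer") of the final product, and the sub-oligomers of a target
form the lattice on which planning happens.

A GTase enzyme rule is a single bond — donor type + donor carbon onto
acceptor type + acceptor carbon — plus a context constraint in one of three
promiscuity classes:

* **context-free**: no constraint beyond the acceptor type and a free
  target carbon (maximal promiscuity);
* **branch-sensitive (ideal)**: the acceptor node must carry specified
  branch subtrees at specified carbons, matched *exactly* (ideal enzymes
  read branches to arbitrary depth), and/or must lack branches at specified
  carbons (a wildcard) or lack a specific subtree there;
* **root-sensitive (ideal)**: the acceptor node's entire chain of linkages
  down to the root must equal a specified chain. Since children are keyed
  by carbon, such a chain identifies a unique position, so root-sensitive
  enzymes can address every monomer individually.

Partial-depth reading (real enzymes often read one or two levels) is
deliberately out of scope: the structural results hold for the three ideal
classes, and partial depth interpolates between them.

Donor (nucleotide-sugar) supply is assumed unlimited; the only kinetic
parameter is the enzyme's concentration, in arbitrary units, which is the
firing propensity of each matching site.

## Stochastic assembly

Within a compartment, the growing oligomer performs a continuous-time
Markov chain on the compartment's reaction network (all states reachable by
single-monomer additions, deduplicated by canonical string). Every matching
(enzyme, site) pair is an independent exponential clock with rate equal to
the enzyme concentration. The oligomer exits after a residence time with
mean `T`: exponentially distributed under the *transport* model (the
default; cisternae ferry cargo onward at a constant hazard) or fixed under
the *maturation* model (the compartment itself converts). The two models
agree in both limits T→0 and (for loop-free compartments) T→∞; all
qualitative conclusions depend only on whether T is small or large relative
to the mean addition time.

Exact exit distributions are computed from the generator Q of the chain:

* transport: π_out = π₀ · λ(λI − Q)^{-1} with λ = 1/T (the resolvent);
* maturation: π_out = π₀ · e^{QT} (matrix exponential);
* T = ∞: absorption probabilities of the embedded jump chain
  (linear solve against I − P restricted to transient states).

The state space is enumerated breadth-first up to a size cap (default 30
monomers) and the exact solver refuses more than 500 states; runaway
scenarios probed at finite T are computed on the capped network with
cap-clipped states treated as absorbing, an explicit approximation that is
accurate whenever the cap sits well above the probed T (repeat lengths are
roughly geometric with mean ~T). A Gillespie sampler provides the
independent Monte Carlo route; it shares no code with the exact path beyond
site matching and is used in tests as a cross-check (agreement within three
binomial standard errors). All randomness flows through one seeded
generator per run.

Microheterogeneity is quantified as Shannon entropy H = −Σ p·log₂ p of the
exit distribution, in bits, with 0·log 0 = 0.

## The three causes of variability

For monomer-by-monomer, irreversible assembly there are exactly three ways
an output distribution becomes non-degenerate, and each has a graph
signature the package detects without enumerating the (possibly infinite)
reaction network:

* **Truncated** reactions: finite T lets intermediates exit. Signature:
  the exit distribution puts mass on states with outgoing reactions.
* **Runaway** reactions: an infinite growth path (tandem repeats).
  Signature: a directed loop in the *linkage network* — one edge per
  enzyme from acceptor type to donor type — restricted to active edges of
  non-root-sensitive enzymes. Root-sensitive enzymes are excluded because
  their acceptors sit at a fixed depth and cannot iterate. A
  branch-sensitive edge is *inactive* when its motif is a **trigger**: an
  acceptor motif unsynthesizable within the compartment from a single
  monomer, so the rule can never fire on material seeded inside.
* **Divergent** reactions: a fork in the reaction network that never
  reconverges. This requires an **acceptor block**: *bidirectional* when
  two enzymes compete for the same carbon of co-satisfiable motifs, and
  *unidirectional* (branch-sensitive victims only) when one enzyme's
  action grows inside the other's required branch (destroying the exact
  match) or creates a branch at one of its forbidden carbons. Blocks are
  necessary but not sufficient for divergence, and the detector is
  intentionally generous in that direction.

Numerical/algorithmic choices inside the detectors:

* Trigger reachability is searched from every single monomer of the
  compartment's alphabet, bounded by the motif size plus the total
  required-branch mass of the compartment. The extra headroom covers
  chains of mutually triggering branch-sensitive rules; a pathological
  compartment needing scaffolds beyond that bound would be misclassified,
  which the loop/unboundedness property suite would expose.
* Input-aware runaway detection keeps only cycles with a reachable seed,
  computed as a fixed-point closure of (monomer type, free carbon) pairs
  obtainable from the input, and filters cycles whose carbon bookkeeping
  cannot work (the next acceptor carbon colliding with the carbon the
  fresh monomer was attached through). The closure is seeded from a small
  bounded expansion of the actual input, because a trigger-disabled
  enzyme can still fire finitely often on motifs the input carries
  ready-made, and the types seeded that way can feed a loop. With the default chemistry-like
  alphabets (donor carbon 1 kept out of the acceptor sets) the filter is
  exact; it is validated empirically against reaction-network
  unboundedness on thousands of random compartments.
* Divergence detection requires a finite (or cap-clipped) network; forks
  whose descendants include a clipped state are skipped as unknown rather
  than guessed.
* `make_algorithmic` removes enzymes greedily — highest loop+block
  participation first, ties broken by name — recomputing trigger activity
  after every removal (so disabling a loop by removing its trigger's
  supplier is found automatically). The result can be the empty
  compartment, which is the identity map; compartments therefore permit
  empty enzyme sets throughout.

## Planning

An *algorithmic compartment* maps each input to a unique output: no
reachable loop and exactly one terminal in the (finite) reaction network at
T = ∞. A stretch edge a → b on the sub-oligomer lattice exists when some
enzyme set's compartment maps a to the unique terminal b. The planner takes
"algorithmic growth stretch" in exactly this dynamic sense — the property
the compartment-count equivalence actually uses — rather than through a
static per-class characterization, and the minimal compartment count is the
shortest path from input to target over stretch edges (breadth-first, with
lexicographic tie-breaks on stage outputs for reproducible plans).

For a fixed library, candidate witness sets are subsets of the enzymes
catalyzing bonds of b∖a (anything else either adds foreign material or can
never fire), searched smallest-first. For class-based planning candidates
are constructed ideally from the growth steps: root-sensitive rules pinned
to each addition's path (a single compartment always suffices, so N = 1
universally); context-free rules are the bare bonds; branch-sensitive
candidates are read off each growth order, with and without the
"forbid-absent-branches" variant. Feasibility is equivalently decidable on
single-enzyme chains; the package exposes that protocol separately and the
test suite checks the equivalence on random instances against an exhaustive
search over ordered series of enzyme subsets.

## Synthetic data and scenarios

The random generators draw monomer types with acceptor carbons from
{2,3,4,6} and donor carbon 1 (kept out of the acceptor set, as in
glycosidic chemistry), grow uniform random trees site-by-site, and build
enzyme libraries through the ideal constructor from random contexts, with a
default class mix of 50% context-free / 30% branch-sensitive / 20%
root-sensitive. Property-suite universes are deliberately small (two or
three types, two or three enzymes, inputs of one or two monomers) so that a
loop-free compartment's network provably fits under the enumeration cap,
making a cap hit an exact witness of unboundedness.

The named scenarios (`builtin_fixtures()`) are hypothetical enzyme sets
constructed to exhibit one cause each — a truncated-convergent compartment,
a divergent cascade delivering a 1:1:2 (1.5-bit) input mixture to its final
stage, and a self-looping chain extender — plus the blood-group B-antigen
pair. They emulate the *patterns* seen in real mucin and chorionic
gonadotropin profiles, not the measured enzyme complements; passing tests
demonstrate the mechanisms, not quantitative agreement with any organism's
glycome. Real-enzyme features the model omits: partial-depth motif reading,
donor-nucleotide depletion, enzyme crowding/competition for the oligomer,
and anomeric stereochemistry beyond what carbon labels encode.

## Known limitations

* Exact distributions on runaway networks are cap-truncated; probe T well
  below the cap or use the Gillespie route.
* Unidirectional block detection is symbolic on motifs and over-reports by
  design; use the reaction-network fork detector for per-instance ground
  truth.
* Class-based branch-sensitive stretch search enumerates growth orders (up
  to 2000) and two constraint variants; exotic witnesses mixing contexts
  across orders are not searched, which can only over-estimate N. The
  library-based search is exhaustive over relevant subsets.
* The problem sizes used by the shipped test batteries (targets ≤ 8
  monomers, libraries ≤ 5 rules, ≤ 3 compartments in the exhaustive
  oracle) were chosen so every oracle is bit-exact at full coverage.
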