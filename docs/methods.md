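# Methods

## Problem

Given a query biochemical reaction — possibly unbalanced, because upstream
retrosynthesis tools routinely omit cofactors and leaving groups — rank the
reactions of an enzyme-annotated database by similarity and surface their
enzymes as candidates for catalysing the query. Two complementary scores
are computed for every database reaction:

* **sim_2018** — a whole-compound score. Every compound is reduced to a
  counted Morgan circular fingerprint (environments up to radius 8, ring
  membership excluded from the atom invariants so that linear-to-ring
  transformations can still share fragments). Query and database compounds
  are paired per reaction side by a *global greedy* heuristic on counted
  Tanimoto similarity (Σ min / Σ max over key counts): the largest
  remaining matrix cell is fixed, its row and column removed, until one
  side is exhausted. Side scores are means over query compound instances
  (surplus query instances count 0 by default), and the final score is the
  mean of the substrate and product side scores. Both written directions
  of the database equation are scored and the larger kept, since stored
  equations have arbitrary direction.

* **sim_RF** — a reacting-fragment score. Atom–atom mapping (AAM) gives a
  correspondence between substrate and product atoms; atoms whose bonding
  environment changes are *reacting atoms*; fragments containing at least
  one reacting atom are *reacting fragments* (RFs). Each query RF gets a
  weight from a reverse sigmoid of its localisation

      f(x) = 1 / (1 + exp(k (x − i))),    defaults k = 0.5, i = 5,

  where x is the maximum over the fragment's atoms of the bond distance to
  the nearest reacting atom within the fragment, and weights are
  linear-sum normalised per compound to total 1. For each compound pair
  fixed by the sim_2018 pairing, the per-pair score is the *containment*
  Σ of normalised weights of query RF keys present in the database
  compound's RF key set. Containment is deliberately asymmetric: an
  unbalanced query can lack atoms (hence RFs) the database reaction has,
  and that is missing evidence, not dissimilarity. Side means S̄ and P̄
  combine as sim_RF = sqrt(S̄ · P̄), so a reaction matching on one side
  only is penalised and S̄ = 0 or P̄ = 0 forces sim_RF = 0.

With i = 5 the weighting gives near-full weight to fragments whose atoms
all lie within ~5 bonds of the reacting site and suppresses large,
unspecific fragments; k controls how sharp that transition is.

## Atom mapping and reacting atoms

Mapping is delegated to a pluggable provider. The production-style
provider wraps the external transformer-based mapper (imported lazily; an
informative error is raised if the package is absent). The passthrough
provider trusts atom-map numbers already present in the reaction SMILES,
which makes the entire pipeline runnable on pre-mapped input with no model
dependency; all shipped fixtures are pre-mapped. Before mapping, sides are
oriented so the heavier side is on the left (the convention the external
mapper expects for unbalanced reactions) and re-oriented afterwards.
Compounds whose SMILES contain the `*` wildcard, unparseable compounds,
provider failures, and inputs with no shared map numbers all mark the
reaction non-mappable; such reactions remain fully searchable by
sim_2018, with the RF column reported unavailable.

An atom is reacting iff (a) it has no mapped partner on the opposite side,
or (b) the multiset of (neighbour map number, bond order) over its mapped
neighbours differs between sides, or (c) its total hydrogen count differs,
or (d) its formal charge differs. This captures bond formation, breaking
and order change, group transfer, protonation and charge changes.
Ring-perception changes alone do not flag an atom, consistent with the
ring-free fingerprint invariants. Two consequences worth knowing: a
transferred intact group (e.g. the methyl in an acyl-cleavage ester
hydrolysis) is not flagged, and substitution of one *unmapped* group by
another that leaves H counts unchanged flags only the leaving/entering
atoms, not the attachment atom. The rule is cross-checked in the test
suite against an independent per-atom environment-diff oracle.

## Numerical and tie-break choices

* Fragment x is computed within the fragment: multi-source BFS from the
  in-fragment reacting atoms over bonds whose endpoints both belong to the
  fragment. Computing x against the whole compound instead would hand all
  fragments of a compound nearly equal weights and defeat the purpose of
  favouring localised fragments.
* Duplicate fragment keys in a compound keep the minimal x (the most
  localised occurrence). Fragment identity across compounds is the hashed
  environment key; hash collisions are accepted as in any hashed
  fingerprint scheme.
* Greedy-pairing ties resolve by lower query index, then lower database
  index. Ranked output is totally ordered: chosen score descending,
  unavailable RF scores last, then reaction id, then enzyme id.
* Compounds with empty RF weight vectors are excluded from S̄/P̄ rather
  than scored 0; a side with no contributing compound makes sim_RF
  *unavailable* (a value, not an error). Both-empty fingerprints get
  Tanimoto 0.
* Scores are kept at full precision internally; the evaluation protocol
  rounds to 4 decimal places only when grouping tied best matches. Note
  that 0.87004 and 0.86996 both round to 0.8700 and therefore tie.
* The identity threshold (sim_2018 > 0.99) and the number of returned
  rows (default 5000) are configurable.

## Evaluation protocol

For each query: database reactions with sim_2018 above the identity
threshold supply the reference EC numbers (union over all identical
matches); the remaining rows tying at 4 decimal places for the best score
are the closest non-identical suggestions; accuracy is the count of
consecutive leading EC fields shared between reference and suggestion,
taking the best comparison when several ECs or tied reactions exist.
Non-numeric EC fields (letters, `-`) terminate the comparison. Queries
whose RF score is unavailable fall into a separate UA bin, which is
included in marginal denominators by default (configurable). The
parameter sweep re-evaluates the RF metric over a (k, i) grid restricted
to the top-50 ranked rows; only the weights are re-derived from the stored
per-key distances — fragments and mappings are computed once.

## Synthetic fixtures

The planted database emulates the core design question — whole-molecule
resemblance versus shared reaction chemistry — with bifunctional scaffolds
(an alcohol/amide chain and an acetate-ester/amine chain, two reactive
sites ≥ 11 bonds apart). Four families of five reactions each transform
one site; members share the centre and everything within 6 bonds of it,
differing only in distal chain length and branches; each query's *decoy*
is the other transformation on the same scaffold (near-identical
compounds, unrelated EC), and a per-family aromatic "trap" shares only the
radius-0/1 centre fragments and 2 EC digits. EC labels are planted so that
within-family neighbours share exactly 3 digits. The fixture also
exercises every degradation path (wildcard compound, unparseable SMILES,
transport row, zero-enzyme reaction, fully-mapped spectator). Generation
is a pure function of the seed, which only permutes the assignment of
distal-variation plans to members. What passing on this fixture does not
show: behaviour under cofactor-dominated similarity, tautomerism, stereo
chemistry, hash-collision rates at database scale, or the quality of a
learned atom mapper.

Case-study structures (steroid 11β-hydroxylation, tocopherol ring
methylation, homogentisate ring cleavage) ship as a hand-curated
constitutional SMILES table; stereo-descriptors are omitted because the
achiral fingerprints cannot see them. These reactions are pre-mapped at
run time by a maximum-common-substructure mapper (a synthetic stand-in for
a learned mapper that is adequate when substrate and product share one
large scaffold); atoms outside the MCS stay unmapped and are therefore
reacting.

Problem sizes used throughout the tests and the acceptance script — a
27-reaction planted database, 4 queries, a 9-reaction case-study set,
1000-molecule weight-normalisation sweeps and 1000 random pairing
matrices — were chosen so every oracle stays hand-checkable and the whole
suite runs in seconds while still covering every code path.

## Known limitations

* The reacting-atom rule is a documented reconstruction (the choice of
  which environment differences count is otherwise a library-internal
  detail); it is validated against the curated toys and the case-study
  reacting centres, not against a mapped gold standard.
* Whole-compound scores for the literature steroid case reproduce the
  printed RF-best value (0.68) exactly but give 0.72 rather than 0.77 for
  the cortisone comparison; the exact database entry behind that printed
  value (structure conventions, possible cofactors) is not recoverable
  from the published description.
* Greedy pairing is a heuristic, not an optimal assignment, by design.
* Stoichiometric coefficients expand to repeated instances for pairing;
  how coefficients should interact with pairing is otherwise unspecified.
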