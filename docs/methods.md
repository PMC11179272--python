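# Methods

## Feature schema

The featurization reduces a molecule to integer counts of local atom and bond
environments. The default schema has 386 fixed dimensions:

* **Carbon classes** (10): carbons keyed by the number of carbon neighbours —
  isolated (0), primary (1), secondary (2), tertiary (3), quaternary (4) —
  crossed with the aromatic flag. (Quaternary-aromatic is chemically
  unreachable but kept so the dimension count never depends on the data.)
* **Element counts** (12): H, B, N, O, F, Si, P, S, Cl, Se, Br, I. Hydrogen is
  counted explicitly (implicit hydrogens included) because amine/oxime/carbonyl
  interconversions change hydrogen counts, and deltas must balance exactly.
* **Bond counts** (364): one key per unordered element pair × bond order
  (single/double/triple/aromatic), including bonds to implicit hydrogens.

Bond keys deliberately use *bare element pairs*, not substitution-refined atom
types. This is the property that makes reaction deltas transferable between
analog contexts: the oxime→carbonyl delta extracted from acetophenone oxime
(a ketoxime, secondary carbon) applies without residue to DHPAA-oxime (an
aldoxime, primary carbon), because the C=N→C=O rewrite touches no carbon-class
key. Refining bond keys by substitution class would break exactly this.
Formal charge is carried on atoms but not keyed; the packaged chemistry is
neutral.

The schema is explicit, versioned (`pathminer-schema/1`) and serialized to
JSON beside any saved knowledge base, so vectors are comparable across runs.
A historical dimension count of a few hundred features is in the same regime,
but no attempt is made to replicate any particular legacy fingerprint
dimension; the schema here is defined by the transfer property above.

## Similarity

Count-vector Tanimoto, `Σ min / Σ max`, over nonnegative vectors. Chosen over
the binary (support-Jaccard) variant because count changes — one extra
hydroxyl, one fewer carbon — are precisely what distinguish near-analog
substrates; a binary variant is available via `tanimoto(..., variant="binary")`.
Conventions: two all-zero vectors score 1.0 (identical nothing), zero vs
nonzero scores 0.0; negative (delta) vectors are rejected. Published scores
from other fingerprint definitions are not digit-comparable with these values;
only orderings are.

## Combination search

Variables `x_j ∈ {0..c_max}` per reaction feature, equality constraint per
feature dimension (restricted to the union support of the deltas and the
query), `Σ x_j ≤ k_max`. Multiplicities are binarized into ordered copies
(`y_{j,t+1} ≤ y_{j,t}`) so each multiset has a unique binary encoding and a
standard binary no-good cut (`Σ_{y*=1} y − Σ_{y*=0} y ≤ |y*| − 1`) excludes
exactly one solution per iteration; enumeration continues until infeasibility
or a solution cap (default 10 000). The solver is SciPy's `milp` (HiGHS).
Solver infeasibility (normal termination of the enumeration) is distinguished
from solver failure, which is logged with the solver message.

Defaults: `k_max = 3`, `c_max = 1` (each reaction type used once per pathway —
the shortest-bypass use case, and it excludes degenerate cycles), score
threshold θ = 0.7, 200 iterations × subset size 20 for the random-subsampling
mode. The subsampling iteration count and subset size have no canonical
values; they are exposed and seeded. When the library is no larger than the
subset size, or with `exhaustive=True`, a single enumeration over the full
library runs instead and is provably complete within the bounds (verified
against an independent depth-first oracle on randomized libraries).

A zero query delta returns only the empty solution (when explicitly allowed):
nonempty multisets summing to zero are cancelling cycles, not pathways.

## Ordering, matching, scoring

Every permutation of a solution multiset (≤ 3! = 6 at defaults) is walked from
f(source). An order survives if every partial sum is elementwise nonnegative —
a negative count cannot be a molecule — and terminates exactly at f(target).
Intermediate vectors are matched against the compound index by **exact vector
equality**; a near-match tolerance is deliberately not offered, since it would
silently break the integer-exactness invariant the search is built on.
Unmatched intermediates are reported as putative compounds (vector only).

Step score: the query-side pair (q_s → q_p) is compared against every known
reaction sharing the step's delta; for each, the score is the mean of the
substrate-side and product-side Tanimoto similarities (a min-of-sides mode is
available). The best-scoring known reaction is the step's assignment; the
full candidate list is retained, with candidates below θ flagged
(`below_threshold`) rather than deleted, so a pathway is never silently lost
to a low-similarity middle step — θ is a reporting filter on per-step
candidates, and a separate optional `pathway_threshold` drops whole pathways.
Pathway score: arithmetic mean of step scores. Ranking: score descending,
then fewer steps, fewer putative intermediates, lexicographic pair-id
sequence — fully deterministic.

## Demonstration knowledge base

`build_demo_kb(seed)` emulates, at desk scale, a reaction-pair database around
the L-DOPA → DHPAA query: 7 named compounds, 4 template reactions (EC
1.14.14.36, 1.2.3.1, 4.1.1.28, 1.4.3.4), the DHPAA-oxime structure as a
holdout excluded from matching, 12 decoy aromatics drawn seeded from a pool of
16, and 6 decoy reactions between random decoy pairs. Decoy construction
rejects any delta equal to the query delta, to zero, or to a primary-reaction
delta, so decoys enlarge the search space without solving the query alone or
duplicating template chemistry — this is checked at build time. Reaction pairs
default to irreversible (directionality of curated pair databases is not
modelled); a `reversible` flag adds the negated delta. What this fixture does
**not** emulate: database scale (tens of thousands of reactions, where the
random-subsampling mode matters), multi-substrate reactions (main-pair-only is
assumed), cofactor bookkeeping (O2, CO2, H2O are outside the main-pair delta),
or noisy/erroneous structures. Passing tests therefore demonstrate algorithmic
correctness and the case-study chemistry, not retrieval performance at scale.

## Mass utilities

Monoisotopic m/z sums most-abundant-isotope masses (RDKit periodic table) plus
a proton (1.007276 Da) for [M+H]+; rounding is half-even at 4 decimals, the
usual high-resolution reporting precision. Nominal m/z uses integer mass
numbers. The MRM table separates instrument settings (unit-resolution
transitions, stored as constants) from computed exact masses, and refuses
transitions whose precursor does not exceed the product. Double-bond
stereoisomer counting returns 2^k over stereogenic C=C/C=N bonds (RDKit's
potential-stereo perception; the oxime nitrogen's lone pair counts as a
distinguishable substituent); tetrahedral centers are excluded by
construction.

## Enzyme screening

* **Ortholog filtering**: strict inequalities (score > 1030, similarity >
  39%) by default — "over" means over; both thresholds are parameters.
  The score column is treated as an opaque numeric (alignment-score-like)
  quantity.
* **Neighbor joining**: classical Saitou–Nei agglomeration. Tie-breaking on
  the Q-criterion is by lexicographically lowest label pair (within 1e-12),
  making output stable across runs. Negative branch lengths, which only arise
  on non-additive inputs, are clamped to zero and counted on the tree object.
  On additive matrices the reconstruction is exact in topology and branch
  lengths; the tests verify leaf-to-leaf tree distances against the input to
  1e-9 and cross-check against an independent implementation. Input distances
  are arbitrary (p-distance from an alignment is provided as a convenience);
  multiple sequence alignment itself is out of scope.
* **Anchor detection**: Kyte–Doolittle windowed mean, window 19, threshold
  1.6, search limited to the first 60 residues — a standard transmembrane-
  segment surrogate; all three parameters configurable. The contract is "find
  the hydrophobic N-terminal region", not "replicate any specific predictor".
  The first maximal run of windows at or above threshold is expanded to
  1-based inclusive residue coordinates. Truncation removes residues
  1..segment-end and restores an initiator methionine; truncation coordinates
  are parameterized, never hard-coded per enzyme.

## Determinism

All randomness (decoy selection, delta subsampling, test matrices) flows
through `numpy.random.default_rng` seeded from a single user-supplied seed.
Identical seed and configuration produce byte-identical knowledge-base files
and demo reports; JSON output is written with sorted keys and no timestamps.

## Known limitations

Delta-vector search is necessary, not sufficient: a combination of deltas
summing to the query proves feature-count balance, not mechanistic
feasibility. Thermodynamics, kinetics, atom mapping and enzyme promiscuity
are out of scope. Exact-equality intermediate matching means a single
tautomer/charge-state discrepancy between a KB structure and an intermediate
vector prevents a match (the intermediate then appears as putative — a
conservative failure). The featurization ignores stereochemistry, so
stereoisomers are indistinguishable in feature space. The problem sizes used
throughout (tens of deltas, ≤ 3 steps, 50 randomized oracle trials, additive
matrices of 4–8 taxa) are the package's own desk-scale validation conditions.
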