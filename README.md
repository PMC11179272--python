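# pathminer

Chemical-structure-based mining of enzymatic bypass pathways, with a packaged
case study: finding a two-enzyme arylacetaldoxime route from L-DOPA to
3,4-dihydroxyphenylacetaldehyde (DHPAA), the unstable aldehyde bottleneck of
benzylisoquinoline-alkaloid production in *E. coli*.

## Who this is for

Metabolic engineers and cheminformaticians who want to ask: *given a database
of known enzymatic substrate→product pairs, which combinations of reaction
types could transform compound A into compound B — including steps through
intermediates nobody has catalogued?* Network searches only walk known
metabolites; this package instead works in reaction-feature space, so it can
propose putative intermediates defined only by their chemistry.

## The model

Every molecule `c` is featurized as a sparse nonnegative integer count vector
`f(c)` over a fixed schema: carbon atoms classified by carbon-substitution
(primary/secondary/tertiary/quaternary, crossed with aromaticity), plain
counts for all other elements including hydrogen, and one count per
(element-pair × bond-order) covalent bond, bonds to implicit hydrogens
included. A reaction pair (s → p) becomes a delta vector `r = f(p) − f(s)`;
a query transformation (source → target) becomes `d = f(target) − f(source)`.

Mining solves the integer program

```
find x ∈ {0..c_max}^J  with  Σⱼ xⱼ·rⱼ = d  and  Σⱼ xⱼ ≤ k_max
```

enumerating all solutions by adding a no-good cut after each one. On large
delta libraries, the enumeration runs repeatedly on seeded random subsets of
the library and pools the solutions; `exhaustive=True` solves over the full
library. Each solution multiset is then ordered: permutations whose
partial-sum intermediates stay elementwise nonnegative are kept, intermediates
are matched to knowledge-base compounds by exact vector equality or reported
as *putative* compounds, and each step is scored by the count-vector Tanimoto
similarity

```
T(a, b) = Σᵢ min(aᵢ, bᵢ) / Σᵢ max(aᵢ, bᵢ)
```

between the query-side and template-reaction-side substrate/product vectors
(mean of the two sides). Pathways are ranked by the average step score.

A companion module supports candidate-enzyme screening: strict
score/similarity homology thresholds, Saitou–Nei neighbor-joining phylogeny
(exact on additive distance matrices), and Kyte–Doolittle hydropathy scanning
to locate and excise the hydrophobic N-terminal membrane anchor of cytochrome
P450s for soluble bacterial expression.

## Worked example

The packaged demonstration knowledge base contains the case-study compounds
(L-DOPA, DHPAA, L-tyrosine, 4HPAA-oxime, acetophenone oxime, acetophenone,
dopamine), four template reactions — tyrosine *N*-monooxygenase
(EC 1.14.14.36), aldehyde oxidase (EC 1.2.3.1), DOPA decarboxylase
(EC 4.1.1.28), monoamine oxidase (EC 1.4.3.4) — and seeded aromatic decoys.
DHPAA-oxime itself is packaged only as a *holdout* structure, excluded from
matching, so the miner must rediscover it as a putative intermediate.

```sh
$ pathminer demo --seed 42
pathways found: 3
top pathway: 2 steps, score 1.000, EC 4.1.1.28 -> 1.4.3.4
oxime bypass route: found (step scores [0.914273, 0.809091]), intermediate matches holdout DHPAA-oxime
delta transfer: aldoxime formation transfers from tyrosine to L-DOPA: ok
delta transfer: oxime-to-carbonyl transfers from acetophenone oxime to DHPAA-oxime: ok
DHPAA-oxime [M+H]+ exact: 168.0655
DHPAA-oxime [M+H]+ nominal: 168
reticuline [M+H]+ exact: 330.17
reticuline [M+H]+ nominal: 330
```

Reading the output: the known decarboxylase + amine-oxidase route scores a
perfect 1.0 (both steps are exact database reactions through dopamine). The
interesting result is the *bypass*: applying the tyrosine→4HPAA-oxime delta
to L-DOPA and then the acetophenone-oxime→acetophenone delta lands exactly on
DHPAA, and the putative intermediate's feature vector is identical to the
held-out DHPAA-oxime structure — the aldoxime route a P450 plus an aldehyde
oxidase would realize. The first step is templated on near-identical chemistry
(score 0.914, tyrosine vs L-DOPA differ by one ring hydroxyl) and the second
on a more distant ketoxime template (score 0.809), so step 1 outranks step 2.
The mass lines are the identification handles for the predicted intermediate:
exact [M+H]+ 168.0655 for high-resolution work and nominal *m/z* 168 for
selected-ion monitoring.

The same pieces are available programmatically:

```python
from pathminer import Query, build_demo_kb, mine

kb = build_demo_kb(seed=42)
paths = mine(Query(source="C00355", target="C04043", max_steps=3, seed=42), kb)
paths[0].ec_sequence          # ('4.1.1.28', '1.4.3.4')
paths[1].ec_sequence          # ('1.14.14.36', '1.2.3.1')  — the oxime bypass
```

Other subcommands: `pathminer featurize`, `pathminer mass`,
`pathminer demo-kb`, `pathminer mine`, `pathminer mrm`, and
`pathminer enzyme nj|hydropathy|filter` for the screening utilities.

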