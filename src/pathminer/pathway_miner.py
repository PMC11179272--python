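"""Pathway mining: combination search, ordering, intermediate matching, scoring.

The search problem: given a query delta d = f(target) - f(source) and a
library of reaction deltas r_j, find multisets {x_j} with sum_j x_j <= k_max
and sum_j x_j * r_j = d (exact integer equality in every feature dimension).
This is solved as an integer linear program; solutions are enumerated by
adding a no-good cut after each one until the program is infeasible. Search
space on large libraries is controlled by iterative random subsampling of the
delta library (seeded); an exhaustive mode solves over the full library.

Each solution is then ordered: every permutation of its multiset is walked
from f(source), keeping orders whose partial-sum intermediate vectors are
elementwise nonnegative (a negative count is not a molecule). Intermediates
are matched to knowledge-base compounds by exact vector equality or reported
as putative compounds (feature vector only). Pathways are scored per step as
the mean Tanimoto similarity between the query-side and known-reaction-side
substrate and product vectors, and ranked by average step score.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .chem_core import FeatureVector, tanimoto
from .reaction_kb import KnowledgeBase, ReactionFeature

__all__ = [
    "Query",
    "CombinationSolution",
    "PathwayStep",
    "PathwayCandidate",
    "ScoredPathway",
    "query_delta",
    "find_combinations",
    "order_and_match",
    "score_pathway",
    "mine",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Query:
    """Search parameters for a source -> target transformation."""

    source: str
    target: str
    max_steps: int = 3
    threshold: float = 0.7  # per-step compound-similarity reporting threshold
    iterations: int = 200
    subset_size: int = 20
    c_max: int = 1  # max multiplicity of one reaction feature per pathway
    seed: int | None = None
    exhaustive: bool = False
    pathway_threshold: float | None = None  # optional pathway-level filter

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")
        if self.c_max < 1:
            raise ValueError("c_max must be >= 1")


@dataclass(frozen=True)
class CombinationSolution:
    """Multiset of reaction features: ((pair_id, direction), multiplicity)."""

    items: tuple[tuple[tuple[str, str], int], ...]

    @classmethod
    def from_counts(cls, counts: dict[tuple[str, str], int]) -> "CombinationSolution":
        return cls(tuple(sorted((k, v) for k, v in counts.items() if v > 0)))

    @property
    def n_steps(self) -> int:
        return sum(m for _, m in self.items)


@dataclass(frozen=True)
class PutativeCompound:
    """An intermediate known only by its feature vector."""

    vector: FeatureVector

    @property
    def label(self) -> str:
        return "putative"


@dataclass
class ReactionMatch:
    pair_id: str
    direction: str
    ec: str
    score: float
    below_threshold: bool = False


@dataclass
class PathwayStep:
    position: int
    feature: ReactionFeature
    intermediate_ids: tuple[str, ...]  # exact-matching KB compounds ('' if putative)
    intermediate: object  # CompoundRecord-like id string or PutativeCompound
    vector_after: FeatureVector
    matches: list[ReactionMatch] = field(default_factory=list)

    @property
    def best_match(self) -> ReactionMatch:
        return self.matches[0]

    @property
    def step_score(self) -> float:
        return self.matches[0].score


@dataclass
class PathwayCandidate:
    solution: CombinationSolution
    ordered_features: tuple[ReactionFeature, ...]
    vectors: tuple[FeatureVector, ...]  # f(source), intermediates..., f(target)
    intermediate_matches: tuple[tuple[str, ...], ...]  # per internal node


@dataclass
class ScoredPathway:
    steps: list[PathwayStep]
    score: float
    n_putative: int
    provenance: dict

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def ec_sequence(self) -> tuple[str, ...]:
        return tuple(s.best_match.ec for s in self.steps)

    @property
    def pair_sequence(self) -> tuple[str, ...]:
        return tuple(s.best_match.pair_id for s in self.steps)

    def sort_key(self) -> tuple:
        return (-self.score, self.n_steps, self.n_putative, self.pair_sequence)

    def to_dict(self) -> dict:
        steps = []
        for s in self.steps:
            inter: dict
            if isinstance(s.intermediate, PutativeCompound):
                inter = {"putative": True, "vector": s.intermediate.vector.to_dict()}
            else:
                inter = {"putative": False, "id": s.intermediate}
            steps.append(
                {
                    "position": s.position,
                    "pair_id": s.best_match.pair_id,
                    "direction": s.best_match.direction,
                    "ec": s.best_match.ec,
                    "step_score": round(s.step_score, 6),
                    "intermediate": inter,
                    "candidates": [
                        {
                            "pair_id": m.pair_id,
                            "ec": m.ec,
                            "score": round(m.score, 6),
                            "below_threshold": m.below_threshold,
                        }
                        for m in s.matches
                    ],
                }
            )
        return {
            "score": round(self.score, 6),
            "n_steps": self.n_steps,
            "n_putative": self.n_putative,
            "steps": steps,
            "provenance": self.provenance,
        }


# ---------------------------------------------------------------------------
# Query delta
# ---------------------------------------------------------------------------


def query_delta(query: Query, kb: KnowledgeBase) -> FeatureVector:
    """d = f(target) - f(source); errors if either compound is missing."""
    return kb.vector(query.target) - kb.vector(query.source)


# ---------------------------------------------------------------------------
# ILP combination search
# ---------------------------------------------------------------------------


def _as_features(kb_or_deltas) -> list[ReactionFeature]:
    if hasattr(kb_or_deltas, "delta_index"):
        return list(kb_or_deltas.delta_index)
    return list(kb_or_deltas)


def _enumerate_ilp(
    d: FeatureVector,
    features: Sequence[ReactionFeature],
    k_max: int,
    c_max: int,
    solution_cap: int,
) -> list[CombinationSolution]:
    """Enumerate all multisets of ``features`` (multiplicity <= c_max, total
    size <= k_max) whose deltas sum exactly to ``d``, via ILP + no-good cuts.

    Multiplicities are binarized into min(c_max, k_max) ordered copies per
    feature so that each multiset has a unique binary encoding and a standard
    binary no-good cut excludes exactly one solution at a time.
    """
    if not features:
        return []
    c_eff = min(c_max, k_max)
    # columns: (feature index, copy index)
    cols = [(j, t) for j in range(len(features)) for t in range(c_eff)]
    dims = sorted(
        set(d.counts) | {k for f in features for k in f.delta.counts}
    )
    if any(k not in {kk for f in features for kk in f.delta.counts} for k in d.counts):
        return []  # d has support no delta can touch
    dim_ix = {k: i for i, k in enumerate(dims)}
    A = np.zeros((len(dims), len(cols)))
    for c, (j, _) in enumerate(cols):
        for k, v in features[j].delta.counts.items():
            A[dim_ix[k], c] = v
    rhs = np.zeros(len(dims))
    for k, v in d.counts.items():
        rhs[dim_ix[k]] = v

    constraints = [LinearConstraint(A, rhs, rhs)]
    constraints.append(LinearConstraint(np.ones((1, len(cols))), 1, k_max))
    # symmetry breaking: copy t+1 may be used only if copy t is
    sym_rows = []
    for j in range(len(features)):
        for t in range(c_eff - 1):
            row = np.zeros(len(cols))
            row[cols.index((j, t + 1))] = 1
            row[cols.index((j, t))] = -1
            sym_rows.append(row)
    if sym_rows:
        constraints.append(
            LinearConstraint(np.array(sym_rows), -np.inf, 0)
        )

    integrality = np.ones(len(cols))
    bounds = (0, 1)
    cost = np.zeros(len(cols))
    cuts: list[np.ndarray] = []
    cut_rhs: list[float] = []
    solutions: list[CombinationSolution] = []

    while len(solutions) < solution_cap:
        cons = list(constraints)
        if cuts:
            cons.append(
                LinearConstraint(np.array(cuts), -np.inf, np.array(cut_rhs))
            )
        res = milp(c=cost, constraints=cons, integrality=integrality, bounds=Bounds(*bounds))
        if res.status == 2:  # infeasible: enumeration complete
            break
        if not res.success:
            logger.warning("MILP solver failure (status %s): %s", res.status, res.message)
            break
        y = np.round(res.x).astype(int)
        counts: dict[tuple[str, str], int] = {}
        for c, (j, _) in enumerate(cols):
            if y[c]:
                fid = features[j].feature_id
                counts[fid] = counts.get(fid, 0) + 1
        solutions.append(CombinationSolution.from_counts(counts))
        # no-good cut: sum_{y=1} y - sum_{y=0} y <= |ones| - 1
        cut = np.where(y == 1, 1.0, -1.0)
        cuts.append(cut)
        cut_rhs.append(float(y.sum()) - 1.0)
    return solutions


def find_combinations(
    d: FeatureVector,
    kb: KnowledgeBase | Iterable[ReactionFeature],
    *,
    k_max: int = 3,
    c_max: int = 1,
    exhaustive: bool = False,
    iterations: int = 200,
    subset_size: int = 20,
    seed: int | None = None,
    solution_cap: int = 10000,
    allow_empty: bool = False,
) -> list[CombinationSolution]:
    """Find multisets of reaction deltas summing exactly to ``d``.

    In exhaustive mode a single ILP enumeration runs over the full delta
    library and the result is complete within the bounds. Otherwise,
    ``iterations`` random subsets of ``subset_size`` deltas are drawn with a
    seeded generator, each subset is enumerated, and the pooled solutions are
    deduplicated. A zero query delta returns the empty solution (if allowed)
    rather than cycles that cancel. An empty result means no solution exists
    within the bounds — it is not an error.
    """
    features = _as_features(kb)
    if not d:
        return [CombinationSolution(())] if allow_empty else []

    if exhaustive or len(features) <= subset_size:
        sols = _enumerate_ilp(d, features, k_max, c_max, solution_cap)
    else:
        rng = np.random.default_rng(seed)
        pooled: set[CombinationSolution] = set()
        for it in range(iterations):
            idx = rng.choice(len(features), size=subset_size, replace=False)
            subset = [features[i] for i in sorted(idx)]
            found = _enumerate_ilp(d, subset, k_max, c_max, solution_cap)
            if found:
                logger.debug("iteration %d: %d solutions", it, len(found))
            pooled.update(found)
        sols = list(pooled)
    sols = sorted(set(sols), key=lambda s: (s.n_steps, s.items))
    logger.info("combination search: %d solutions (k_max=%d)", len(sols), k_max)
    return sols


def brute_force_combinations(
    d: FeatureVector,
    kb: KnowledgeBase | Iterable[ReactionFeature],
    k_max: int = 3,
    c_max: int = 1,
) -> list[CombinationSolution]:
    """Independent depth-first enumeration of all delta multisets summing to
    ``d``. Exponential in k_max; intended for small libraries and as a
    cross-check of the ILP enumeration."""
    features = _as_features(kb)
    out: list[CombinationSolution] = []
    n = len(features)

    def rec(start: int, remaining: FeatureVector, budget: int, picked: dict) -> None:
        if not remaining:
            if picked:
                out.append(CombinationSolution.from_counts(dict(picked)))
            return
        if budget == 0 or start >= n:
            return
        for j in range(start, n):
            fid = features[j].feature_id
            for mult in range(1, min(c_max, budget) + 1):
                delta_sum = features[j].delta
                for _ in range(mult - 1):
                    delta_sum = delta_sum + features[j].delta
                picked[fid] = mult
                rec(j + 1, remaining - delta_sum, budget - mult, picked)
                del picked[fid]

    if d:
        rec(0, d, k_max, {})
    return sorted(set(out), key=lambda s: (s.n_steps, s.items))


# ---------------------------------------------------------------------------
# Ordering and intermediate matching
# ---------------------------------------------------------------------------


def order_and_match(
    solution: CombinationSolution, query: Query, kb: KnowledgeBase
) -> list[PathwayCandidate]:
    """Expand a solution multiset into admissible ordered pathways.

    Every distinct permutation is walked from f(source); an order survives if
    every partial-sum intermediate is elementwise nonnegative (negative counts
    cannot be molecules) and the chain terminates exactly at f(target).
    Intermediates are matched against the compound index by exact vector
    equality; unmatched vectors become putative compounds.
    """
    f_source = kb.vector(query.source)
    f_target = kb.vector(query.target)
    feat_by_id = {f.feature_id: f for f in kb.delta_index}
    items: list[ReactionFeature] = []
    for fid, mult in solution.items:
        items.extend([feat_by_id[fid]] * mult)

    candidates: list[PathwayCandidate] = []
    seen_orders: set[tuple] = set()
    for perm in itertools.permutations(range(len(items))):
        order_ids = tuple(items[i].feature_id for i in perm)
        if order_ids in seen_orders:
            continue
        seen_orders.add(order_ids)
        vectors = [f_source]
        ok = True
        for i in perm:
            nxt = vectors[-1] + items[i].delta
            if not nxt.is_nonnegative:
                ok = False
                break
            vectors.append(nxt)
        if not ok or vectors[-1] != f_target:
            continue
        inter_matches = tuple(
            tuple(rec.id for rec in kb.match_vector(v)) for v in vectors[1:-1]
        )
        candidates.append(
            PathwayCandidate(
                solution=solution,
                ordered_features=tuple(items[i] for i in perm),
                vectors=tuple(vectors),
                intermediate_matches=inter_matches,
            )
        )
    return candidates


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _step_similarity(
    q_sub: FeatureVector,
    q_prod: FeatureVector,
    k_sub: FeatureVector,
    k_prod: FeatureVector,
    side_mode: str,
) -> float:
    t_s = tanimoto(q_sub, k_sub)
    t_p = tanimoto(q_prod, k_prod)
    return min(t_s, t_p) if side_mode == "min" else 0.5 * (t_s + t_p)


def score_pathway(
    candidate: PathwayCandidate,
    kb: KnowledgeBase,
    threshold: float = 0.7,
    side_mode: str = "mean",
    provenance: dict | None = None,
) -> ScoredPathway:
    """Score an ordered pathway candidate.

    For each step mapping the query-side pair (q_s -> q_p) onto a known
    reaction (k_s -> k_p), the step score is the mean (or min) of the
    substrate-side and product-side Tanimoto similarities. Every known
    reaction sharing the step's delta is evaluated; the best is reported as
    the step's assignment and alternatives below ``threshold`` are flagged.
    The pathway score is the arithmetic mean of the best step scores.
    """
    steps: list[PathwayStep] = []
    n_putative = 0
    for pos, feat in enumerate(candidate.ordered_features):
        q_sub = candidate.vectors[pos]
        q_prod = candidate.vectors[pos + 1]
        matches = []
        for alt in kb.features_with_delta(feat.delta):
            k_sub, k_prod = kb.oriented_pair_vectors(alt)
            s = _step_similarity(q_sub, q_prod, k_sub, k_prod, side_mode)
            matches.append(
                ReactionMatch(
                    pair_id=alt.pair_id,
                    direction=alt.direction,
                    ec=kb.reactions[alt.pair_id].ec,
                    score=s,
                    below_threshold=s < threshold,
                )
            )
        matches.sort(key=lambda m: (-m.score, m.pair_id))
        if pos < len(candidate.ordered_features) - 1:
            match_ids = candidate.intermediate_matches[pos]
            if match_ids:
                intermediate: object = match_ids[0]
            else:
                intermediate = PutativeCompound(q_prod)
                n_putative += 1
            inter_ids = match_ids
        else:
            intermediate = None  # terminal node is the target itself
            inter_ids = ()
        steps.append(
            PathwayStep(
                position=pos + 1,
                feature=feat,
                intermediate_ids=inter_ids,
                intermediate=intermediate if intermediate is not None else "",
                vector_after=q_prod,
                matches=matches,
            )
        )
    score = float(np.mean([s.step_score for s in steps])) if steps else 1.0
    return ScoredPathway(
        steps=steps,
        score=score,
        n_putative=n_putative,
        provenance=provenance or {},
    )


# ---------------------------------------------------------------------------
# Top-level mining
# ---------------------------------------------------------------------------


def mine(query: Query, kb: KnowledgeBase) -> list[ScoredPathway]:
    """Full pipeline: query delta -> combinations -> ordering/matching ->
    scoring -> deterministic ranking.

    Ranking is by score (descending), then fewer steps, fewer putative
    intermediates, and lexicographic pair-id sequence.
    """
    for cid in (query.source, query.target):
        if cid not in kb.compounds:
            raise KeyError(f"query compound {cid!r} not in knowledge base")
    d = query_delta(query, kb)
    solutions = find_combinations(
        d,
        kb,
        k_max=query.max_steps,
        c_max=query.c_max,
        exhaustive=query.exhaustive,
        iterations=query.iterations,
        subset_size=query.subset_size,
        seed=query.seed,
    )
    provenance = {
        "source": query.source,
        "target": query.target,
        "max_steps": query.max_steps,
        "threshold": query.threshold,
        "c_max": query.c_max,
        "seed": query.seed,
        "exhaustive": query.exhaustive,
        "n_solutions": len(solutions),
    }
    scored: list[ScoredPathway] = []
    for sol in solutions:
        for cand in order_and_match(sol, query, kb):
            scored.append(
                score_pathway(
                    cand, kb, threshold=query.threshold, provenance=provenance
                )
            )
    if query.pathway_threshold is not None:
        scored = [p for p in scored if p.score >= query.pathway_threshold]
    scored.sort(key=ScoredPathway.sort_key)
    logger.info(
        "mined %d pathways for %s -> %s", len(scored), query.source, query.target
    )
    return scored
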