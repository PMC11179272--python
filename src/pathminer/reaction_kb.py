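"""Compound and reaction-pair storage with precomputed reaction delta vectors.

A knowledge base indexes compounds (with cached feature vectors) and
substrate->product reaction pairs labelled with EC numbers. Each pair yields a
reaction feature: the delta vector f(product) - f(substrate). Reversible pairs
additionally contribute the exact negation as a reverse feature.

``build_demo_kb`` packages a small, fully deterministic knowledge base around
the L-DOPA -> DHPAA case study: the tyrosine N-monooxygenase (EC 1.14.14.36)
and aldehyde oxidase (EC 1.2.3.1) template reactions, the conventional
decarboxylase (DODC, EC 4.1.1.28) + monoamine oxidase (MAO, EC 1.4.3.4) route,
and seeded aromatic decoys that make ranking non-trivial without ever solving
the query on their own.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem_core import (
    FeatureSchema,
    FeatureVector,
    default_schema,
    featurize,
    parse_structure,
)

__all__ = [
    "CompoundRecord",
    "ReactionPair",
    "ReactionFeature",
    "KnowledgeBase",
    "KnowledgeBaseError",
    "load_compounds",
    "load_reaction_pairs",
    "build_demo_kb",
    "DEMO_QUERY",
]

logger = logging.getLogger(__name__)

_EC_PATTERN = re.compile(r"^(\d+|-)\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


class KnowledgeBaseError(ValueError):
    """Raised for structural problems in compound/reaction tables."""


@dataclass(frozen=True)
class CompoundRecord:
    id: str
    name: str
    smiles: str
    source: str = "fixture"
    in_kb: bool = True  # holdout structures are stored but excluded from matching


@dataclass(frozen=True)
class ReactionPair:
    pair_id: str
    substrate_id: str
    product_id: str
    ec: str
    reversible: bool = False

    def __post_init__(self) -> None:
        if not _EC_PATTERN.match(self.ec):
            raise KnowledgeBaseError(
                f"pair {self.pair_id}: EC {self.ec!r} does not match d.d.d.d"
            )


@dataclass(frozen=True)
class ReactionFeature:
    """One usable direction of a reaction pair: delta = f(product) - f(substrate)."""

    pair_id: str
    direction: str  # "forward" | "reverse"
    delta: FeatureVector

    @property
    def feature_id(self) -> tuple[str, str]:
        return (self.pair_id, self.direction)


@dataclass
class KnowledgeBase:
    schema: FeatureSchema
    compounds: dict[str, CompoundRecord] = field(default_factory=dict)
    vectors: dict[str, FeatureVector] = field(default_factory=dict)
    reactions: dict[str, ReactionPair] = field(default_factory=dict)
    delta_index: list[ReactionFeature] = field(default_factory=list)

    # -- construction --------------------------------------------------------

    def add_compound(self, record: CompoundRecord) -> None:
        if record.id in self.compounds:
            raise KnowledgeBaseError(f"duplicate compound id {record.id!r}")
        vec = featurize(parse_structure(record.smiles), self.schema)
        self.compounds[record.id] = record
        self.vectors[record.id] = vec

    def add_reaction(self, pair: ReactionPair) -> None:
        if pair.pair_id in self.reactions:
            raise KnowledgeBaseError(f"duplicate pair id {pair.pair_id!r}")
        for cid in (pair.substrate_id, pair.product_id):
            if cid not in self.compounds:
                raise KnowledgeBaseError(
                    f"pair {pair.pair_id} references unknown compound {cid!r}"
                )
        delta = self.vectors[pair.product_id] - self.vectors[pair.substrate_id]
        self.reactions[pair.pair_id] = pair
        self.delta_index.append(ReactionFeature(pair.pair_id, "forward", delta))
        if pair.reversible:
            self.delta_index.append(ReactionFeature(pair.pair_id, "reverse", -delta))

    # -- lookup ---------------------------------------------------------------

    def vector(self, compound_id: str) -> FeatureVector:
        try:
            return self.vectors[compound_id]
        except KeyError:
            raise KnowledgeBaseError(f"unknown compound id {compound_id!r}") from None

    def match_vector(self, vec: FeatureVector) -> list[CompoundRecord]:
        """Compounds whose feature vector equals ``vec`` exactly (holdouts excluded)."""
        sig = vec.signature()
        return [
            self.compounds[cid]
            for cid, v in sorted(self.vectors.items())
            if v.signature() == sig and self.compounds[cid].in_kb
        ]

    def oriented_pair_vectors(
        self, feature: ReactionFeature
    ) -> tuple[FeatureVector, FeatureVector]:
        """(substrate, product) vectors of a feature, respecting its direction."""
        pair = self.reactions[feature.pair_id]
        s, p = self.vector(pair.substrate_id), self.vector(pair.product_id)
        return (s, p) if feature.direction == "forward" else (p, s)

    def features_with_delta(self, delta: FeatureVector) -> list[ReactionFeature]:
        sig = delta.signature()
        return [f for f in self.delta_index if f.delta.signature() == sig]

    # -- serialization --------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format": "pathminer-kb/1",
            "schema": {"version": self.schema.version, "keys": list(self.schema.keys)},
            "compounds": [
                {
                    "id": c.id,
                    "name": c.name,
                    "smiles": c.smiles,
                    "source": c.source,
                    "in_kb": c.in_kb,
                }
                for c in self.compounds.values()
            ],
            "reactions": [
                {
                    "pair_id": r.pair_id,
                    "ec": r.ec,
                    "substrate_id": r.substrate_id,
                    "product_id": r.product_id,
                    "reversible": r.reversible,
                }
                for r in self.reactions.values()
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "KnowledgeBase":
        doc = json.loads(text)
        schema = FeatureSchema(doc["schema"]["keys"], version=doc["schema"]["version"])
        kb = cls(schema=schema)
        for c in doc["compounds"]:
            kb.add_compound(CompoundRecord(**c))
        for r in doc["reactions"]:
            kb.add_reaction(ReactionPair(**r))
        return kb

    def save(self, out_dir: str | Path) -> None:
        """Write compounds.tsv, reactions.tsv, schema.json and kb.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "compounds.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["id", "name", "smiles", "source", "in_kb"])
            for c in self.compounds.values():
                w.writerow([c.id, c.name, c.smiles, c.source, int(c.in_kb)])
        with open(out / "reactions.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["pair_id", "ec", "substrate_id", "product_id", "reversible"])
            for r in self.reactions.values():
                w.writerow(
                    [r.pair_id, r.ec, r.substrate_id, r.product_id, int(r.reversible)]
                )
        self.schema.save(out / "schema.json")
        with open(out / "kb.json", "w") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "KnowledgeBase":
        """Load from a kb.json file or a directory containing one."""
        p = Path(path)
        if p.is_dir():
            p = p / "kb.json"
        return cls.from_json(p.read_text())


# ---------------------------------------------------------------------------
# TSV loaders
# ---------------------------------------------------------------------------


def load_compounds(
    path: str | Path, schema: FeatureSchema | None = None
) -> KnowledgeBase:
    """Load a compound TSV (columns: id, name, smiles[, source, in_kb]) into a
    new knowledge base. Duplicate ids and unparseable structures are reported
    with their row numbers."""
    schema = schema or default_schema()
    kb = KnowledgeBase(schema=schema)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            logger.warning("compound table %s is empty", path)
            return kb
        missing = {"id", "name", "smiles"} - set(reader.fieldnames)
        if missing:
            raise KnowledgeBaseError(f"compound table missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            rec = CompoundRecord(
                id=row["id"],
                name=row["name"],
                smiles=row["smiles"],
                source=row.get("source") or "file",
                in_kb=bool(int(row.get("in_kb") or 1)),
            )
            try:
                kb.add_compound(rec)
            except KnowledgeBaseError as exc:
                raise KnowledgeBaseError(f"row {lineno}: {exc}") from None
            except ValueError as exc:
                raise KnowledgeBaseError(
                    f"row {lineno} ({rec.id}): unparseable structure: {exc}"
                ) from None
    logger.info("loaded %d compounds from %s", len(kb.compounds), path)
    return kb


def load_reaction_pairs(path: str | Path, kb: KnowledgeBase) -> KnowledgeBase:
    """Add reaction pairs from a TSV (pair_id, ec, substrate_id, product_id,
    reversible) to an existing compound index, computing delta vectors."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            logger.warning("reaction table %s is empty", path)
            return kb
        required = {"pair_id", "ec", "substrate_id", "product_id"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise KnowledgeBaseError(f"reaction table missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                kb.add_reaction(
                    ReactionPair(
                        pair_id=row["pair_id"],
                        ec=row["ec"],
                        substrate_id=row["substrate_id"],
                        product_id=row["product_id"],
                        reversible=bool(int(row.get("reversible") or 0)),
                    )
                )
            except KnowledgeBaseError as exc:
                raise KnowledgeBaseError(f"row {lineno}: {exc}") from None
    logger.info("loaded %d reaction pairs from %s", len(kb.reactions), path)
    return kb


# ---------------------------------------------------------------------------
# Demonstration knowledge base
# ---------------------------------------------------------------------------

# Canonical structures for the compounds of the case study. Ids are opaque
# strings (KEGG C-numbers / a PubChem CID where the compound has one); the
# SMILES are the standard structures for those ids and are independently
# checkable against the stated formulas.
PRIMARY_COMPOUNDS = [
    # id, name, smiles (formula)
    CompoundRecord("C00355", "L-DOPA", "NC(Cc1ccc(O)c(O)c1)C(=O)O"),  # C9H11NO4
    CompoundRecord("C04043", "DHPAA", "O=CCc1ccc(O)c(O)c1"),  # C8H8O3
    CompoundRecord("C00082", "L-tyrosine", "NC(Cc1ccc(O)cc1)C(=O)O"),  # C9H11NO3
    CompoundRecord("C04353", "4HPAA-oxime", "ON=CCc1ccc(O)cc1"),  # C8H9NO2
    CompoundRecord("CID5464950", "acetophenone oxime", "CC(=NO)c1ccccc1"),  # C8H9NO
    CompoundRecord("C07113", "acetophenone", "CC(=O)c1ccccc1"),  # C8H8O
    CompoundRecord("C03758", "dopamine", "NCCc1ccc(O)c(O)c1"),  # C8H11NO2
]

# The predicted bypass intermediate; packaged as a holdout so the miner must
# rediscover its feature vector as a putative compound.
HOLDOUT_COMPOUND = CompoundRecord(
    "X-DHPAAOX", "DHPAA-oxime", "ON=CCc1ccc(O)c(O)c1", in_kb=False  # C8H9NO3
)

PRIMARY_REACTIONS = [
    ReactionPair("RP001", "C00082", "C04353", "1.14.14.36"),  # tyrosine N-monooxygenase
    ReactionPair("RP002", "CID5464950", "C07113", "1.2.3.1"),  # aldehyde oxidase
    ReactionPair("RP003", "C00355", "C03758", "4.1.1.28"),  # DODC
    ReactionPair("RP004", "C03758", "C04043", "1.4.3.4"),  # MAO
]

# Aromatic decoy pool: search-space chaff for the demonstration KB.
DECOY_POOL = [
    ("D001", "phenol", "Oc1ccccc1"),
    ("D002", "catechol", "Oc1ccccc1O"),
    ("D003", "benzoic acid", "OC(=O)c1ccccc1"),
    ("D004", "benzaldehyde", "O=Cc1ccccc1"),
    ("D005", "toluene", "Cc1ccccc1"),
    ("D006", "styrene", "C=Cc1ccccc1"),
    ("D007", "anisole", "COc1ccccc1"),
    ("D008", "4-hydroxybenzaldehyde", "O=Cc1ccc(O)cc1"),
    ("D009", "vanillin", "COc1cc(C=O)ccc1O"),
    ("D010", "2-phenylethylamine", "NCCc1ccccc1"),
    ("D011", "tyramine", "NCCc1ccc(O)cc1"),
    ("D012", "phenylacetaldehyde", "O=CCc1ccccc1"),
    ("D013", "benzylamine", "NCc1ccccc1"),
    ("D014", "cinnamaldehyde", "O=CC=Cc1ccccc1"),
    ("D015", "phenylpyruvate", "O=C(O)C(=O)Cc1ccccc1"),
    ("D016", "L-phenylalanine", "NC(Cc1ccccc1)C(=O)O"),
]

DEMO_QUERY = ("C00355", "C04043")  # L-DOPA -> DHPAA

_N_DECOY_COMPOUNDS = 12
_N_DECOY_REACTIONS = 6


def build_demo_kb(
    seed: int = 42,
    out_dir: str | Path | None = None,
    include_decoys: bool = True,
    schema: FeatureSchema | None = None,
) -> KnowledgeBase:
    """Build the packaged demonstration knowledge base.

    Contains the case-study compounds and the four pathway-relevant reaction
    pairs, plus (by default) 12 seeded decoy aromatics and 6 decoy reaction
    pairs among them. Build-time checks guarantee that no decoy delta equals
    the query delta (or solves the query alone) and that no decoy duplicates a
    primary reaction delta. With the same seed the construction — and any
    files written — are byte-identical across runs.
    """
    schema = schema or default_schema()
    kb = KnowledgeBase(schema=schema)
    for rec in PRIMARY_COMPOUNDS:
        kb.add_compound(rec)
    kb.add_compound(HOLDOUT_COMPOUND)

    for pair in PRIMARY_REACTIONS:
        kb.add_reaction(pair)
    primary_deltas = {f.delta.signature() for f in kb.delta_index}

    query_delta = kb.vector(DEMO_QUERY[1]) - kb.vector(DEMO_QUERY[0])

    if include_decoys:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(DECOY_POOL))
        chosen = sorted(order[:_N_DECOY_COMPOUNDS])
        decoy_ids = []
        for idx in chosen:
            cid, name, smi = DECOY_POOL[idx]
            kb.add_compound(CompoundRecord(cid, name, smi, source="decoy"))
            decoy_ids.append(cid)

        n_added = 0
        used: set[tuple[str, str]] = set()
        zero_sig = FeatureVector(schema).signature()
        while n_added < _N_DECOY_REACTIONS:
            i, j = rng.choice(len(decoy_ids), size=2, replace=False)
            s, p = decoy_ids[i], decoy_ids[j]
            if (s, p) in used:
                continue
            used.add((s, p))
            delta = kb.vector(p) - kb.vector(s)
            sig = delta.signature()
            # decoys must never solve the query alone nor clone a primary delta
            if sig == query_delta.signature() or sig == zero_sig or sig in primary_deltas:
                continue
            n_added += 1
            kb.add_reaction(
                ReactionPair(f"RPD{n_added:02d}", s, p, f"9.9.9.{n_added}")
            )

    # build-time verification of the fixture contract
    for feat in kb.delta_index:
        if kb.reactions[feat.pair_id].ec.startswith("9.9.9."):
            assert feat.delta.signature() != query_delta.signature()

    if out_dir is not None:
        kb.save(out_dir)
    return kb
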