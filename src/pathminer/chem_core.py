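"""Molecular structures, count-vector featurization, Tanimoto similarity and mass utilities.

A molecule is reduced to a sparse vector of nonnegative integer counts over a
fixed, serializable feature schema: carbon atoms are classified by their number
of carbon neighbours (isolated/primary/secondary/tertiary/quaternary) crossed
with aromaticity, every other element (including hydrogen) is counted as a
plain element feature, and every covalent bond — including bonds to implicit
hydrogens — is counted under an (element pair, bond order) key.

Bond keys deliberately use bare element pairs rather than substitution-refined
atom types: a reaction delta expressed this way transfers between analogous
substrate contexts (e.g. a ketoxime-to-ketone delta applies unchanged to an
aldoxime), which is what makes delta vectors reusable as reaction signatures.

Differences of these vectors (reaction deltas, query deltas) may carry
negative counts; real-molecule vectors never do.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from rdkit import Chem
from rdkit import rdBase

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "FeatureSchema",
    "FeatureVector",
    "MolecularFormula",
    "StructureParseError",
    "UnknownElementError",
    "SchemaMismatchError",
    "parse_structure",
    "write_structure",
    "featurize",
    "tanimoto",
    "monoisotopic_mz",
    "nominal_mz",
    "count_db_stereoisomers",
    "PROTON_MASS",
]

PROTON_MASS = 1.007276

BOND_ORDERS = ("single", "double", "triple", "aromatic")

_RD_BOND_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class StructureParseError(ValueError):
    """Raised when a structure string cannot be parsed."""


class UnknownElementError(KeyError):
    """Raised when a molecule contains an element the schema cannot represent."""


class SchemaMismatchError(ValueError):
    """Raised when two feature vectors do not share a schema."""


# ---------------------------------------------------------------------------
# Molecular graph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    element: str
    formal_charge: int
    aromatic: bool
    implicit_h: int


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: str  # one of BOND_ORDERS


@dataclass
class MolecularGraph:
    """Element-labelled graph with perceived aromaticity and implicit H counts."""

    atoms: list[Atom]
    bonds: list[Bond]
    rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) references a missing atom")
            if b.i == b.j:
                raise ValueError(f"self-bond on atom {b.i}")
            if b.order not in BOND_ORDERS:
                raise ValueError(f"unknown bond order {b.order!r}")

    @property
    def num_heavy_atoms(self) -> int:
        return sum(1 for a in self.atoms if a.element != "H")

    def total_hydrogens(self) -> int:
        """Explicit H atoms plus implicit hydrogens on heavy atoms."""
        return sum(a.implicit_h for a in self.atoms) + sum(
            1 for a in self.atoms if a.element == "H"
        )

    def formula(self) -> "MolecularFormula":
        counts: Counter[str] = Counter()
        for a in self.atoms:
            counts[a.element] += 1
            if a.implicit_h:
                counts["H"] += a.implicit_h
        return MolecularFormula(dict(counts))


def _graph_from_rdmol(mol: Chem.Mol) -> MolecularGraph:
    atoms = [
        Atom(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
            implicit_h=a.GetTotalNumHs(includeNeighbors=False),
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        order = _RD_BOND_ORDER.get(b.GetBondType())
        if order is None:
            raise StructureParseError(f"unsupported bond type {b.GetBondType()}")
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MolecularGraph(atoms=atoms, bonds=bonds, rdmol=mol)


def parse_structure(text: str, fmt: str | None = None) -> MolecularGraph:
    """Parse a SMILES string or an MDL mol block into a :class:`MolecularGraph`.

    Aromaticity is perceived and implicit hydrogens assigned. The format is
    auto-detected (a mol block contains ``M  END``) unless ``fmt`` is given as
    ``"smiles"`` or ``"molblock"``.
    """
    if fmt is None:
        fmt = "molblock" if "M  END" in text or "V2000" in text else "smiles"
    with rdBase.BlockLogs():
        if fmt == "smiles":
            mol = Chem.MolFromSmiles(text)
        elif fmt == "molblock":
            mol = Chem.MolFromMolBlock(text)
        else:
            raise ValueError(f"unknown structure format {fmt!r}")
    if mol is None:
        raise StructureParseError(f"could not parse {fmt} input: {text.strip()!r}")
    return _graph_from_rdmol(mol)


def write_structure(mol: MolecularGraph) -> str:
    """Canonical SMILES for a parsed structure."""
    if mol.rdmol is None:
        raise ValueError("graph was not built from a parsed structure")
    return Chem.MolToSmiles(mol.rdmol)


# ---------------------------------------------------------------------------
# Feature schema and vectors
# ---------------------------------------------------------------------------

_SCHEMA_ELEMENTS = ("H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I")
_CARBON_CLASSES = ("isolated", "primary", "secondary", "tertiary", "quaternary")


def _carbon_key(n_carbon_neighbors: int, aromatic: bool) -> str:
    cls = _CARBON_CLASSES[n_carbon_neighbors]
    return f"C[{cls},ar]" if aromatic else f"C[{cls}]"


def _bond_key(el_a: str, el_b: str, order: str) -> str:
    ia, ib = _SCHEMA_ELEMENTS.index(el_a), _SCHEMA_ELEMENTS.index(el_b)
    if ia > ib:
        el_a, el_b = el_b, el_a
    return f"{el_a}-{el_b}:{order}"


class FeatureSchema:
    """Ordered, fixed-dimension set of feature keys.

    The default schema enumerates 10 carbon substitution classes, 12 plain
    element counts and all (element pair x bond order) keys over a fixed
    organic element alphabet, so that any two vectors built against it are
    directly comparable and the schema can be serialized alongside results.
    """

    VERSION = "pathminer-schema/1"

    def __init__(self, keys: Iterable[str], version: str | None = None) -> None:
        keys = tuple(keys)
        if len(set(keys)) != len(keys):
            dupes = [k for k, c in Counter(keys).items() if c > 1]
            raise ValueError(f"duplicate schema keys: {dupes}")
        self.keys = keys
        self.version = version or self.VERSION
        self._index = {k: i for i, k in enumerate(keys)}

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, key: str) -> bool:
        return key in self._index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FeatureSchema) and self.keys == other.keys

    def __hash__(self) -> int:
        return hash(self.keys)

    def index(self, key: str) -> int:
        return self._index[key]

    @classmethod
    def default(cls) -> "FeatureSchema":
        keys: list[str] = []
        for cls_name in _CARBON_CLASSES:
            keys.append(f"C[{cls_name}]")
        # quaternary aromatic carbon cannot exist but the dimension stays fixed
        for cls_name in _CARBON_CLASSES:
            keys.append(f"C[{cls_name},ar]")
        keys.extend(el for el in _SCHEMA_ELEMENTS if el != "C")
        for ia, el_a in enumerate(_SCHEMA_ELEMENTS):
            for el_b in _SCHEMA_ELEMENTS[ia:]:
                for order in BOND_ORDERS:
                    keys.append(f"{el_a}-{el_b}:{order}")
        return cls(keys)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({"version": self.version, "keys": list(self.keys)}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        doc = json.loads(text)
        return cls(doc["keys"], version=doc.get("version"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            return cls.from_json(fh.read())


_DEFAULT_SCHEMA: FeatureSchema | None = None


def default_schema() -> FeatureSchema:
    global _DEFAULT_SCHEMA
    if _DEFAULT_SCHEMA is None:
        _DEFAULT_SCHEMA = FeatureSchema.default()
    return _DEFAULT_SCHEMA


class FeatureVector:
    """Sparse integer count vector over a :class:`FeatureSchema`.

    Real-molecule vectors are nonnegative; differences of vectors (reaction
    and query deltas) may carry negative counts and are first-class citizens
    of the same type.
    """

    __slots__ = ("schema", "counts")

    def __init__(self, schema: FeatureSchema, counts: Mapping[str, int] | None = None):
        self.schema = schema
        clean: dict[str, int] = {}
        if counts:
            for k, v in counts.items():
                if k not in schema:
                    raise UnknownElementError(f"feature key {k!r} not in schema")
                v = int(v)
                if v != 0:
                    clean[k] = v
        self.counts = clean

    # -- algebra ------------------------------------------------------------

    def _check(self, other: "FeatureVector") -> None:
        if self.schema != other.schema:
            raise SchemaMismatchError("feature vectors use different schemas")

    def __add__(self, other: "FeatureVector") -> "FeatureVector":
        self._check(other)
        c = Counter(self.counts)
        c.update(other.counts)
        return FeatureVector(self.schema, {k: v for k, v in c.items() if v})

    def __sub__(self, other: "FeatureVector") -> "FeatureVector":
        return self + (-other)

    def __neg__(self) -> "FeatureVector":
        return FeatureVector(self.schema, {k: -v for k, v in self.counts.items()})

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, FeatureVector)
            and self.schema == other.schema
            and self.counts == other.counts
        )

    def __hash__(self) -> int:
        return hash(self.signature())

    def __getitem__(self, key: str) -> int:
        return self.counts.get(key, 0)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __repr__(self) -> str:
        items = ", ".join(f"{k}:{v:+d}" for k, v in sorted(self.counts.items()))
        return f"FeatureVector({items})"

    def signature(self) -> tuple:
        """Hashable canonical form used for exact matching and deduplication."""
        return tuple(sorted(self.counts.items()))

    @property
    def is_nonnegative(self) -> bool:
        return all(v >= 0 for v in self.counts.values())

    def total(self) -> int:
        return sum(self.counts.values())

    def to_dense(self) -> list[int]:
        dense = [0] * len(self.schema)
        for k, v in self.counts.items():
            dense[self.schema.index(k)] = v
        return dense

    def to_dict(self) -> dict[str, int]:
        return dict(sorted(self.counts.items()))


def featurize(mol: MolecularGraph, schema: FeatureSchema | None = None) -> FeatureVector:
    """Count every atom into exactly one atom-class key and every bond
    (including bonds to implicit hydrogens) into exactly one bond key.
    """
    schema = schema or default_schema()
    counts: Counter[str] = Counter()

    carbon_neighbors = [0] * len(mol.atoms)
    for b in mol.bonds:
        if mol.atoms[b.j].element == "C":
            carbon_neighbors[b.i] += 1
        if mol.atoms[b.i].element == "C":
            carbon_neighbors[b.j] += 1

    for idx, atom in enumerate(mol.atoms):
        el = atom.element
        if el == "C":
            key = _carbon_key(carbon_neighbors[idx], atom.aromatic)
        else:
            key = el
        if key not in schema:
            raise UnknownElementError(
                f"element {el!r} (key {key!r}) is not representable in the schema"
            )
        counts[key] += 1
        if atom.implicit_h:
            counts["H"] += atom.implicit_h
            if el not in _SCHEMA_ELEMENTS:
                raise UnknownElementError(f"element {el!r} not representable")
            counts[_bond_key(el, "H", "single")] += atom.implicit_h

    for b in mol.bonds:
        el_a = mol.atoms[b.i].element
        el_b = mol.atoms[b.j].element
        try:
            key = _bond_key(el_a, el_b, b.order)
        except ValueError as exc:
            raise UnknownElementError(str(exc)) from exc
        if key not in schema:
            raise UnknownElementError(f"bond key {key!r} not in schema")
        counts[key] += 1

    return FeatureVector(schema, counts)


def tanimoto(a: FeatureVector, b: FeatureVector, variant: str = "count") -> float:
    """Tanimoto similarity between two nonnegative feature vectors.

    ``count`` (default): sum(min) / sum(max) over all features. ``binary``:
    Jaccard index of the feature supports. Two all-zero vectors are defined
    as identical (similarity 1.0).
    """
    if a.schema != b.schema:
        raise SchemaMismatchError("cannot compare vectors from different schemas")
    if not (a.is_nonnegative and b.is_nonnegative):
        raise ValueError("tanimoto is defined for nonnegative (molecule) vectors")
    keys = set(a.counts) | set(b.counts)
    if not keys:
        return 1.0
    if variant == "binary":
        inter = len(set(a.counts) & set(b.counts))
        return inter / len(keys)
    if variant != "count":
        raise ValueError(f"unknown tanimoto variant {variant!r}")
    num = sum(min(a[k], b[k]) for k in keys)
    den = sum(max(a[k], b[k]) for k in keys)
    return num / den


# ---------------------------------------------------------------------------
# Molecular formula and mass utilities
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

_ADDUCTS = {"+H": 1, "-H": -1, "neutral": 0}


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map, e.g. C8H9NO3."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("empty molecular formula")
        for el, n in self.counts.items():
            if n < 1:
                raise ValueError(f"count for {el} must be >= 1, got {n}")

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        counts: Counter[str] = Counter()
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos or not m.group(1):
                raise ValueError(f"malformed formula {text!r} at position {pos}")
            counts[m.group(1)] += int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text) or not counts:
            raise ValueError(f"malformed formula {text!r}")
        return cls(dict(counts))

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical
        parts = []
        for el in ("C", "H"):
            if el in self.counts:
                n = self.counts[el]
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(k for k in self.counts if k not in ("C", "H")):
            n = self.counts[el]
            parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)


def _periodic_table():
    return Chem.GetPeriodicTable()


def _resolve_formula(formula: MolecularFormula | str | MolecularGraph) -> MolecularFormula:
    if isinstance(formula, MolecularGraph):
        return formula.formula()
    if isinstance(formula, str):
        return MolecularFormula.parse(formula)
    return formula


def monoisotopic_mz(
    formula: MolecularFormula | str | MolecularGraph,
    adduct: str = "neutral",
    decimals: int = 4,
) -> float:
    """Monoisotopic m/z: sum of most-abundant-isotope masses plus the adduct.

    ``+H`` adds one proton (1.007276 Da); rounding is half-even to
    ``decimals`` places (default 4, matching high-resolution MS reporting).
    """
    formula = _resolve_formula(formula)
    if adduct not in _ADDUCTS:
        raise ValueError(f"unknown adduct {adduct!r}; expected one of {sorted(_ADDUCTS)}")
    pt = _periodic_table()
    mass = 0.0
    for el, n in formula.counts.items():
        try:
            m = pt.GetMostCommonIsotopeMass(el)
        except Exception as exc:  # rdkit raises on unknown symbols
            raise ValueError(f"unknown element symbol {el!r}") from exc
        if m <= 0:
            raise ValueError(f"unknown element symbol {el!r}")
        mass += n * m
    mass += _ADDUCTS[adduct] * PROTON_MASS
    return round(mass, decimals)


def nominal_mz(
    formula: MolecularFormula | str | MolecularGraph, adduct: str = "neutral"
) -> int:
    """Integer nominal mass (most-abundant-isotope mass numbers) plus adduct."""
    formula = _resolve_formula(formula)
    if adduct not in _ADDUCTS:
        raise ValueError(f"unknown adduct {adduct!r}; expected one of {sorted(_ADDUCTS)}")
    pt = _periodic_table()
    mass = 0
    for el, n in formula.counts.items():
        try:
            iso = pt.GetMostCommonIsotope(el)
        except Exception as exc:
            raise ValueError(f"unknown element symbol {el!r}") from exc
        if iso <= 0:
            raise ValueError(f"unknown element symbol {el!r}")
        mass += n * iso
    return mass + _ADDUCTS[adduct]


# ---------------------------------------------------------------------------
# Double-bond stereoisomer enumeration
# ---------------------------------------------------------------------------


def count_db_stereoisomers(mol: MolecularGraph) -> int:
    """Number of E/Z double-bond stereoisomers, as 2**k over stereogenic
    C=C and C=N double bonds.

    A double bond is stereogenic when each terminus carries two
    distinguishable substituents; for an oxime/imine nitrogen the lone pair
    counts as distinguishable from the single substituent. Tetrahedral
    stereocenters are deliberately not counted.
    """
    if mol.rdmol is None:
        raise ValueError("graph was not built from a parsed structure")
    rdmol = Chem.Mol(mol.rdmol)
    k = 0
    for element in Chem.FindPotentialStereo(rdmol):
        if element.type != Chem.StereoType.Bond_Double:
            continue
        bond = rdmol.GetBondWithIdx(element.centeredOn)
        symbols = {bond.GetBeginAtom().GetSymbol(), bond.GetEndAtom().GetSymbol()}
        if symbols <= {"C", "N"}:
            k += 1
    return 2**k
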