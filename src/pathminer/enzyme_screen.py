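"""Candidate-enzyme screening: ortholog thresholding, neighbor-joining
phylogeny, and hydropathy-based N-terminal membrane-anchor truncation design.

Cytochrome P450s such as the CYP79 family carry a hydrophobic N-terminal
membrane anchor that hampers soluble expression in bacteria; removing it (and
restoring an initiator methionine) is a standard engineering move. The anchor
is located here with a Kyte-Doolittle sliding-window scan (window 19,
threshold 1.6, searched within the first 60 residues) — a conventional
transmembrane-segment surrogate with all three parameters exposed.

The neighbor-joining implementation is the classical Saitou-Nei agglomeration
with deterministic tie-breaking (lexicographically lowest label pair), exact
on additive distance matrices.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "TreeNode",
    "HydropathyProfile",
    "KYTE_DOOLITTLE",
    "filter_orthologs",
    "p_distance",
    "nj_tree",
    "hydropathy_profile",
    "detect_nterm_anchor",
    "truncate_nterm",
]

# Kyte & Doolittle hydropathy index, kcal/mol-free-energy-derived scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_GAP_CHARS = {"-", "."}


# ---------------------------------------------------------------------------
# Ortholog filtering
# ---------------------------------------------------------------------------


def filter_orthologs(
    table: str | Path | Iterable[dict],
    score_threshold: float = 1030.0,
    similarity_threshold: float = 39.0,
) -> list[dict]:
    """Keep pairwise-homology rows with score strictly over ``score_threshold``
    AND percent similarity strictly over ``similarity_threshold``.

    ``table`` is a TSV path (columns: query, subject, score, similarity) or an
    iterable of dicts with those keys. Malformed rows raise with their line
    number.
    """
    if isinstance(table, (str, Path)):
        rows = []
        with open(table, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None:
                return []
            missing = {"query", "subject", "score", "similarity"} - set(reader.fieldnames)
            if missing:
                raise ValueError(f"homology table missing columns: {sorted(missing)}")
            for lineno, row in enumerate(reader, start=2):
                try:
                    row = dict(row)
                    row["score"] = float(row["score"])
                    row["similarity"] = float(row["similarity"])
                except (TypeError, ValueError):
                    raise ValueError(f"malformed homology row at line {lineno}: {row}")
                rows.append(row)
    else:
        rows = [dict(r) for r in table]
    return [
        r
        for r in rows
        if float(r["score"]) > score_threshold
        and float(r["similarity"]) > similarity_threshold
    ]


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate taxon labels")
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValueError("distance matrix has a nonzero diagonal")
        if (self.matrix < -1e-12).any():
            raise ValueError("distance matrix has negative entries")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        """Square TSV with a header row and a label column."""
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh, delimiter="\t"))
        labels = tuple(rows[0][1:])
        mat = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
        return cls(labels, mat)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow([""] + list(self.labels))
            for lab, row in zip(self.labels, self.matrix):
                w.writerow([lab] + [f"{x:.10g}" for x in row])


def p_distance(records) -> DistanceMatrix:
    """Uncorrected p-distance from an aligned FASTA (path or SeqRecord list).

    d(i,j) = mismatches / positions compared, with columns containing a gap in
    either sequence excluded pairwise.
    """
    if isinstance(records, (str, Path)):
        records = list(SeqIO.parse(str(records), "fasta"))
    else:
        records = list(records)
    if len(records) < 3:
        raise ValueError("need at least 3 sequences")
    labels = tuple(r.id for r in records)
    seqs = [str(r.seq).upper() for r in records]
    length = len(seqs[0])
    for lab, s in zip(labels, seqs):
        if len(s) != length:
            raise ValueError(f"sequence {lab} length {len(s)} != {length}")
    n = len(seqs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            compared = mismatch = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in _GAP_CHARS or b in _GAP_CHARS:
                    continue
                compared += 1
                mismatch += a != b
            if compared == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]} and {labels[j]}"
                )
            mat[i, j] = mat[j, i] = mismatch / compared
    return DistanceMatrix(labels, mat)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def newick_fragment(self) -> str:
        if self.is_leaf:
            return self.name or ""
        inner = ",".join(
            f"{child.newick_fragment()}:{length:.10g}"
            for child, length in self.children
        )
        return f"({inner})"


@dataclass
class PhyloTree:
    """Unrooted tree represented with a trifurcating root node."""

    root: TreeNode
    labels: tuple[str, ...]
    clamped_negative_branches: int = 0

    def newick(self) -> str:
        return self.root.newick_fragment() + ";"

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Sum of branch lengths along the path between every leaf pair."""
        depth: dict[int, float] = {id(self.root): 0.0}
        ancestors: dict[str, list[TreeNode]] = {}

        def walk(node: TreeNode, trail: list[TreeNode]) -> None:
            if node.is_leaf:
                ancestors[node.name] = trail + [node]
            for child, length in node.children:
                depth[id(child)] = depth[id(node)] + length
                walk(child, trail + [node])

        walk(self.root, [])
        out: dict[tuple[str, str], float] = {}
        for i, a in enumerate(self.labels):
            for b in self.labels[i + 1 :]:
                pa, pb = ancestors[a], ancestors[b]
                in_b = {id(n) for n in pb}
                lca = next(n for n in reversed(pa) if id(n) in in_b)
                dist = depth[id(pa[-1])] + depth[id(pb[-1])] - 2 * depth[id(lca)]
                out[(a, b)] = out[(b, a)] = dist
        return out


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each agglomeration the Q-criterion
    Q(i,j) = (n-2) d(i,j) - r_i - r_j is minimized; ties are broken by the
    lexicographically lowest (label_i, label_j) pair, so the output is stable
    across runs. Negative branch lengths (possible on non-additive inputs)
    are clamped to zero and counted. On an additive matrix the reconstruction
    is exact in both topology and branch lengths.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    names: list[str] = list(dm.labels)  # tie-break key per active node
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = tuple(sorted((names[i], names[j])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and best is not None and key < best[2]
                ):
                    best_q = q
                    best = (i, j, key)
        i, j, _ = best
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = D[i, j] - vi
        vi, vj = clamp(vi), clamp(vj)
        new = TreeNode(children=[(nodes[i], vi), (nodes[j], vj)])
        new_name = min(names[i], names[j])
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [new_name]

    # closed-form resolution of the final three nodes around a trifurcation
    (a, b, c) = range(3)
    la = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    lb = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    lc = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    root = TreeNode(
        children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)]
    )
    return PhyloTree(root=root, labels=dm.labels, clamped_negative_branches=clamped)


# ---------------------------------------------------------------------------
# Hydropathy and truncation design
# ---------------------------------------------------------------------------


@dataclass
class HydropathyProfile:
    sequence: str
    window: int
    values: np.ndarray  # length = len(sequence) - window + 1


def hydropathy_profile(sequence: str, window: int = 19) -> HydropathyProfile:
    """Kyte-Doolittle windowed-mean hydropathy profile."""
    sequence = sequence.upper()
    if len(sequence) < window:
        raise ValueError(f"sequence shorter than window ({len(sequence)} < {window})")
    try:
        vals = np.array([KYTE_DOOLITTLE[aa] for aa in sequence])
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in sequence") from None
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    return HydropathyProfile(sequence=sequence, window=window, values=means)


def detect_nterm_anchor(
    sequence: str,
    window: int = 19,
    threshold: float = 1.6,
    search_limit: int = 60,
) -> tuple[int, int] | None:
    """Locate the N-terminal hydrophobic membrane anchor, if any.

    Returns the first maximal run of windows with mean Kyte-Doolittle
    hydropathy >= ``threshold`` whose run starts within the first
    ``search_limit`` residues, expanded to 1-based inclusive residue
    coordinates; ``None`` when no such segment exists.
    """
    prof = hydropathy_profile(sequence, window=window)
    above = prof.values >= threshold
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            if i >= search_limit:
                return None
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            return (i + 1, j + window)
        i += 1
    return None


def truncate_nterm(sequence: str, segment: tuple[int, int] | None) -> str:
    """Remove residues 1..segment_end and restore an initiator methionine.

    With ``segment=None`` the sequence is returned unchanged. The result has
    length len(sequence) - end + 1.
    """
    if segment is None:
        return sequence
    start, end = segment
    if not (1 <= start <= end <= len(sequence)):
        raise ValueError(f"segment {segment} out of bounds for length {len(sequence)}")
    return "M" + sequence[end:]
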