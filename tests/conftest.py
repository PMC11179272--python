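import numpy as np
import pytest

from pathminer import build_demo_kb, default_schema, featurize, parse_structure
from pathminer.enzyme_screen import DistanceMatrix

CASE_STUDY_SMILES = {
    "L-DOPA": "NC(Cc1ccc(O)c(O)c1)C(=O)O",
    "DHPAA": "O=CCc1ccc(O)c(O)c1",
    "L-tyrosine": "NC(Cc1ccc(O)cc1)C(=O)O",
    "4HPAA-oxime": "ON=CCc1ccc(O)cc1",
    "acetophenone oxime": "CC(=NO)c1ccccc1",
    "acetophenone": "CC(=O)c1ccccc1",
    "dopamine": "NCCc1ccc(O)c(O)c1",
    "DHPAA-oxime": "ON=CCc1ccc(O)c(O)c1",
}


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def demo_kb():
    return build_demo_kb(42)


@pytest.fixture(scope="session")
def vectors(schema):
    return {
        name: featurize(parse_structure(smi), schema)
        for name, smi in CASE_STUDY_SMILES.items()
    }


def brute_force_multisets(d, features, k_max, c_max=1):
    """Independent depth-first oracle: all multisets of reaction features whose
    deltas sum exactly to d, with total multiplicity <= k_max."""
    out = set()
    n = len(features)

    def rec(start, current, budget, picked):
        if current == d and picked:
            out.add(tuple(sorted(picked.items())))
        if budget == 0 or start >= n:
            return
        for j in range(start, n):
            fid = features[j].feature_id
            for mult in range(1, min(c_max, budget) + 1):
                acc = current
                for _ in range(mult):
                    acc = acc + features[j].delta
                picked[fid] = mult
                rec(j + 1, acc, budget - mult, picked)
                del picked[fid]

    zero = d - d
    rec(0, zero, k_max, {})
    return out


def random_additive_matrix(n, rng):
    """Distance matrix generated from a random binary tree with positive branch
    lengths; additive by construction. Returns (DistanceMatrix, None)."""
    depth = [{f"T{i}": 0.0} for i in range(n)]
    dist = {}
    while len(depth) > 1:
        i, j = sorted(rng.choice(len(depth), size=2, replace=False))
        la, lb = rng.uniform(0.5, 3.0, size=2)
        for x, dx in depth[i].items():
            for y, dy in depth[j].items():
                dist[(x, y)] = dist[(y, x)] = dx + la + dy + lb
        merged = {k: v + la for k, v in depth[i].items()}
        merged.update({k: v + lb for k, v in depth[j].items()})
        depth = [depth[k] for k in range(len(depth)) if k not in (i, j)] + [merged]
    labels = tuple(sorted(depth[0], key=lambda s: int(s[1:])))
    mat = np.array(
        [[0.0 if a == b else dist[(a, b)] for b in labels] for a in labels]
    )
    return DistanceMatrix(labels, mat)
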