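"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check.
"""

from __future__ import annotations

import numpy as np


def mcs_atoms_bruteforce(mol_a, mol_b) -> int:
    """Size (atom count) of the largest connected common subgraph.

    Exhaustive growth over consistent atom-pair sets connected through
    shared bonds; element equality, exact bond order (aromatic distinct)
    and ring-flag equality for both atoms and bonds.
    """
    na, nb = mol_a.GetNumAtoms(), mol_b.GetNumAtoms()

    def atom_ok(i, j):
        ai, bj = mol_a.GetAtomWithIdx(i), mol_b.GetAtomWithIdx(j)
        return (ai.GetSymbol() == bj.GetSymbol()
                and ai.IsInRing() == bj.IsInRing())

    def bond_ok(i1, i2, j1, j2):
        ba = mol_a.GetBondBetweenAtoms(i1, i2)
        bb = mol_b.GetBondBetweenAtoms(j1, j2)
        if ba is None or bb is None:
            return False
        return (ba.GetBondType() == bb.GetBondType()
                and ba.IsInRing() == bb.IsInRing())

    pairs = [(i, j) for i in range(na) for j in range(nb) if atom_ok(i, j)]
    best = 0
    ceiling = min(na, nb)

    def extend(mapped: dict, candidates: list):
        # include/exclude branching on the first candidate linked to the
        # current mapping: complete and duplication-free
        nonlocal best
        best = max(best, len(mapped))
        if best == ceiling:
            return
        usable = [(i, j) for (i, j) in candidates
                  if i not in mapped and j not in mapped.values()]
        if len(mapped) + len({i for i, _ in usable}) <= best:
            return
        pick = None
        for idx, (i, j) in enumerate(usable):
            if any(bond_ok(i, im, j, jm) for im, jm in mapped.items()):
                pick = (idx, i, j)
                break
        if pick is None:
            return
        idx, i, j = pick
        rest = usable[:idx] + usable[idx + 1:]
        new_mapped = dict(mapped)
        new_mapped[i] = j
        extend(new_mapped, rest)   # include
        extend(mapped, rest)       # exclude

    for (i, j) in pairs:
        # the seed holds the smallest mapped target-atom index, so only
        # pairs with a larger target index may join this branch
        allowed = [p for p in pairs if p[0] > i and p[1] != j]
        extend({i: j}, allowed)
        if best == ceiling:
            break
    return best


def butina_bruteforce(dist: np.ndarray, cutoff: float) -> list[list[int]]:
    """Literal Butina procedure on a precomputed distance matrix."""
    n = dist.shape[0]
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        counts = {}
        for i in sorted(unassigned):
            counts[i] = sum(1 for j in unassigned if dist[i, j] <= cutoff)
        seed = max(sorted(counts), key=lambda i: counts[i])
        # max() keeps the first (lowest index) on ties because of sorting
        members = sorted(j for j in unassigned if dist[seed, j] <= cutoff)
        clusters.append(members)
        unassigned -= set(members)
    return clusters
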