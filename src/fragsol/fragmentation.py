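"""One-cut fragmentation of molecular graphs at acyclic single bonds.

Every bond of order one that is not aromatic and not part of a ring is a
breakable ("fragile") bond.  Deleting one such bond always separates the
graph into exactly two connected components; enumerating all breakable bonds
yields the molecule's m fragment pairs.  Fragments inherit their atom and
bond feature vectors unchanged from the parent — no caps or re-featurization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import MolecularGraph


class NotBreakableError(ValueError):
    """Requested split on a bond that is not an acyclic single bond."""


@dataclass(frozen=True)
class BreakableBond:
    bond_index: int
    endpoints: tuple  # (u, v) with u < v


@dataclass
class FragmentPair:
    """Two disjoint fragment subgraphs from deleting one breakable bond.

    ``atom_maps`` give, per fragment, the parent atom index of each fragment
    atom; together they partition the parent's atom set.  Fragment 1 contains
    the smaller-indexed endpoint of the broken bond.
    """

    frag1: MolecularGraph
    frag2: MolecularGraph
    broken_bond: BreakableBond
    atom_maps: tuple  # (list[int], list[int])


def enumerate_breakable_bonds(g: MolecularGraph) -> list:
    """All non-ring single (non-aromatic) bonds, in bond-index order."""
    out = []
    for idx, (pair, order) in enumerate(zip(g.bonds, g.bond_order)):
        if order == "single" and not g.ring_membership[idx]:
            out.append(BreakableBond(bond_index=idx, endpoints=pair))
    return out


def _connected_component(g: MolecularGraph, start: int, skip_bond: int) -> list:
    adj = {i: [] for i in range(g.n_atoms)}
    for idx, (u, v) in enumerate(g.bonds):
        if idx == skip_bond:
            continue
        adj[u].append(v)
        adj[v].append(u)
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return sorted(seen)


def _subgraph(g: MolecularGraph, atoms: list) -> MolecularGraph:
    index_of = {a: i for i, a in enumerate(atoms)}
    bonds, feats, ring, order = [], [], [], []
    for idx, (u, v) in enumerate(g.bonds):
        if u in index_of and v in index_of:
            bonds.append((index_of[u], index_of[v]))
            feats.append(g.bond_features[idx])
            ring.append(g.ring_membership[idx])
            order.append(g.bond_order[idx])
    return MolecularGraph(
        n_atoms=len(atoms),
        atom_features=g.atom_features[atoms].copy(),
        bonds=bonds,
        bond_features=np.stack(feats) if feats else np.zeros((0, g.bond_features.shape[1]), dtype=np.float32),
        ring_membership=np.array(ring, dtype=bool),
        bond_order=order,
        smiles=None,
    )


def split_on_bond(g: MolecularGraph, b: BreakableBond) -> FragmentPair:
    """Split ``g`` into its two connected components after deleting bond ``b``."""
    idx = b.bond_index
    if not (
        0 <= idx < len(g.bonds)
        and g.bond_order[idx] == "single"
        and not g.ring_membership[idx]
        and g.bonds[idx] == b.endpoints
    ):
        raise NotBreakableError(f"bond {b} is not an acyclic single bond of this graph")
    u, v = b.endpoints
    atoms1 = _connected_component(g, u, skip_bond=idx)
    in1 = set(atoms1)
    atoms2 = [a for a in range(g.n_atoms) if a not in in1]
    return FragmentPair(
        frag1=_subgraph(g, atoms1),
        frag2=_subgraph(g, atoms2),
        broken_bond=b,
        atom_maps=(atoms1, atoms2),
    )


def enumerate_fragment_pairs(g: MolecularGraph) -> list:
    """One :class:`FragmentPair` per breakable bond, in deterministic bond order.

    Returns an empty list for molecules with no acyclic single bond (single
    atoms, pure ring systems); the model then falls back to its
    whole-molecule path.
    """
    return [split_on_bond(g, b) for b in enumerate_breakable_bonds(g)]
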