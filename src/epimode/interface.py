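"""Residue contacts across a binder/target partition and homodimer symmetry.

A residue pair is "in contact" when the minimum heavy-atom distance across the
partition is strictly below the cutoff (5 A by default, the usual native-
contact convention). Epitopes are the target-side projections of per-model
contact sets; a C2 homodimer target makes every designed mutation appear on
both protomers, which :func:`symmetry_expand` accounts for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .structio import ResidueKey, Structure

DEFAULT_CONTACT_CUTOFF = 5.0  # angstroms, min heavy-atom distance


@dataclass(frozen=True)
class ChainPartition:
    binder_chains: frozenset[str]
    target_chains: frozenset[str]

    def __post_init__(self) -> None:
        binder = frozenset(self.binder_chains)
        target = frozenset(self.target_chains)
        object.__setattr__(self, "binder_chains", binder)
        object.__setattr__(self, "target_chains", target)
        if not binder or not target:
            raise ValueError("both sides of the partition must be non-empty")
        if binder & target:
            raise ValueError(f"chains on both sides: {sorted(binder & target)}")

    def validate(self, s: Structure) -> None:
        missing = (self.binder_chains | self.target_chains) - s.chain_ids
        if missing:
            raise ValueError(f"partition chains {sorted(missing)} absent from structure {s.id!r}")

    def swapped(self) -> "ChainPartition":
        return ChainPartition(self.target_chains, self.binder_chains)


@dataclass(frozen=True)
class ContactSet:
    pairs: frozenset[tuple[ResidueKey, ResidueKey]]  # (binder, target)
    cutoff: float

    @property
    def binder_residues(self) -> frozenset[ResidueKey]:
        return frozenset(b for b, _ in self.pairs)

    @property
    def target_residues(self) -> frozenset[ResidueKey]:
        return frozenset(t for _, t in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SymmetryMap:
    """Groups of chain ids declared structurally equivalent (e.g. Fc protomers)."""

    equivalences: tuple[frozenset[str], ...] = ()

    def __post_init__(self) -> None:
        groups = tuple(frozenset(g) for g in self.equivalences)
        object.__setattr__(self, "equivalences", groups)
        seen: set[str] = set()
        for g in groups:
            if g & seen:
                raise ValueError("symmetry groups must be disjoint")
            seen |= g

    def equivalents(self, chain_id: str) -> frozenset[str]:
        for g in self.equivalences:
            if chain_id in g:
                return g
        return frozenset({chain_id})

    def orbit(self, key: ResidueKey) -> frozenset[ResidueKey]:
        cid, number, icode = key
        return frozenset((c, number, icode) for c in self.equivalents(cid))


def _side_arrays(s: Structure, chain_ids: Iterable[str]):
    coords, owners = [], []
    keys: list[ResidueKey] = []
    for r in s.residues(chain_ids):
        keys.append(r.key)
        for a in r.atoms:
            coords.append(a.xyz)
            owners.append(len(keys) - 1)
    return np.asarray(coords, dtype=float), np.asarray(owners, dtype=int), keys


def residue_contacts(s: Structure, part: ChainPartition,
                     cutoff: float = DEFAULT_CONTACT_CUTOFF) -> ContactSet:
    """All cross-partition residue pairs with min heavy-atom distance < cutoff."""
    part.validate(s)
    b_xyz, b_owner, b_keys = _side_arrays(s, sorted(part.binder_chains))
    t_xyz, t_owner, t_keys = _side_arrays(s, sorted(part.target_chains))
    if b_xyz.size == 0 or t_xyz.size == 0:
        raise ValueError("a side of the partition has no heavy atoms")
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    tree = cKDTree(t_xyz)
    neighbours = tree.query_ball_point(b_xyz, r=cutoff)
    for bi, hits in enumerate(neighbours):
        if not hits:
            continue
        d = np.linalg.norm(t_xyz[hits] - b_xyz[bi], axis=1)
        for ti, dist in zip(hits, d):
            if dist < cutoff:  # strict: atoms exactly at the cutoff do not count
                pairs.add((b_keys[b_owner[bi]], t_keys[t_owner[ti]]))
    return ContactSet(pairs=frozenset(pairs), cutoff=cutoff)


def min_residue_distance(s: Structure, key_a: ResidueKey, key_b: ResidueKey) -> float:
    a = s.residue(key_a).coords()
    b = s.residue(key_b).coords()
    return float(np.min(np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)))


def epitope_of_model(model: Structure, part: ChainPartition,
                     cutoff: float = DEFAULT_CONTACT_CUTOFF) -> frozenset[ResidueKey]:
    """Target-side contact residues of one docking model."""
    return residue_contacts(model, part, cutoff).target_residues


def symmetry_expand(positions: Iterable[ResidueKey], sym: SymmetryMap,
                    structure: Structure | None = None) -> frozenset[ResidueKey]:
    """Copy each position onto every symmetry-equivalent chain.

    If ``structure`` is given, copies that do not exist there are dropped with
    a warning (the original position is always kept).
    """
    out: set[ResidueKey] = set()
    for pos in positions:
        for copy in sym.orbit(pos):
            if structure is not None and copy != pos and not structure.has_residue(copy):
                warnings.warn(
                    f"symmetry copy {copy} of {pos} absent from structure; kept on existing chains",
                    stacklevel=2,
                )
                continue
            out.add(copy)
    return frozenset(out)


def contacts_under_symmetry(epitope: frozenset[ResidueKey], position: ResidueKey,
                            sym: SymmetryMap | None = None) -> bool:
    """True if any symmetry-equivalent copy of ``position`` is in the epitope.

    A dimer binder engages one protomer, so a position counts as contacted
    when either copy is.
    """
    if sym is None:
        return position in epitope
    return bool(sym.orbit(position) & epitope)


def contact_table(s: Structure, part: ChainPartition,
                  cutoff: float = DEFAULT_CONTACT_CUTOFF):
    """Contacts as a pandas DataFrame (binder_res, target_res, min_dist)."""
    import pandas as pd

    cs = residue_contacts(s, part, cutoff)
    rows = []
    for b, t in sorted(cs.pairs):
        rows.append({
            "binder_res": format_key(b),
            "target_res": format_key(t),
            "min_dist": round(min_residue_distance(s, b, t), 3),
        })
    return pd.DataFrame(rows, columns=["binder_res", "target_res", "min_dist"])


def format_key(key: ResidueKey) -> str:
    cid, number, icode = key
    return f"{cid}:{number}{icode}"


def parse_key(text: str) -> ResidueKey:
    cid, _, rest = text.partition(":")
    if not rest:
        raise ValueError(f"residue key {text!r} is not CHAIN:NUMBER[ICODE]")
    number = ""
    i = 0
    if rest[0] == "-":
        number, i = "-", 1
    while i < len(rest) and rest[i].isdigit():
        number += rest[i]
        i += 1
    return (cid, int(number), rest[i:])
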