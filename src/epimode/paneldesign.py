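"""Minimal variant-panel design over docking-model epitopes.

Every docking model hypothesises an epitope on the target; a variant carrying
a few binding-disruptive mutations inside one spatial patch tests all models
whose epitopes it touches. The design problem is an exact minimum set cover:
the smallest panel of variants (each with at most ``k`` mutations drawn from a
single patch) such that every docking model is covered by at least one
variant. Instances are small (tens of models, tens of candidate variants), so
the cover is solved exactly by depth-first branch and bound, with summed
disruption score and then lexicographic order breaking ties so panels are
reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ._aa import ONE_TO_THREE, THREE_TO_ONE, aa_class, default_substitution
from .interface import ChainPartition, ResidueKey
from .structio import Structure

DEFAULT_PATCH_RADIUS = 8.0  # angstroms, Cbeta-Cbeta single linkage
DEFAULT_MUTATIONS_PER_VARIANT = 3
_PATCH_POSITION_CAP = 15  # candidate subsets are enumerated; cap keeps that exact search small


@dataclass(frozen=True)
class Patch:
    residues: frozenset[ResidueKey]
    member_models: frozenset[str]


@dataclass(frozen=True, order=True)
class MutationSpec:
    position: ResidueKey
    wt: str
    sub: str

    def __post_init__(self) -> None:
        if self.wt == self.sub:
            raise ValueError(f"{self.position}: substitution equals wild type {self.wt!r}")

    def __str__(self) -> str:
        cid, number, icode = self.position
        return f"{cid}.{self.wt}{number}{icode}{self.sub}"


@dataclass(frozen=True)
class VariantDesign:
    mutations: tuple[MutationSpec, ...]
    covered_models: frozenset[str]

    @property
    def positions(self) -> frozenset[ResidueKey]:
        return frozenset(m.position for m in self.mutations)

    def __str__(self) -> str:
        return "/".join(str(m) for m in sorted(self.mutations))


@dataclass(frozen=True)
class Panel:
    variants: tuple[VariantDesign, ...]
    objective: tuple[int, float]  # (panel size, total disruption score)
    uncoverable_models: frozenset[str] = frozenset()

    @property
    def covered_models(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for v in self.variants:
            out |= v.covered_models
        return out


# ---------------------------------------------------------------------------
# patch clustering

def cluster_patches(epitopes: Mapping[str, frozenset[ResidueKey] | set],
                    s: Structure, radius: float = DEFAULT_PATCH_RADIUS) -> list[Patch]:
    """Single-linkage spatial clusters of the union of epitope residues.

    Two residues join the same patch when their side-chain representative
    points (Cbeta, Calpha for glycine) are within ``radius``; patches are the
    connected components of that graph.
    """
    if not epitopes or all(not e for e in epitopes.values()):
        raise ValueError("no epitope residues to cluster")
    union = sorted(set().union(*epitopes.values()))
    coords = []
    for key in union:
        try:
            coords.append(s.residue(key).rep_coord())
        except KeyError:
            raise KeyError(f"epitope residue {key} missing from structure {s.id!r}") from None
    xyz = np.asarray(coords)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    adj = csr_matrix(d <= radius)
    n_comp, labels = connected_components(adj, directed=False)
    patches = []
    for comp in range(n_comp):
        members = frozenset(union[i] for i in np.flatnonzero(labels == comp))
        owners = frozenset(mid for mid, epi in epitopes.items() if members & set(epi))
        patches.append(Patch(residues=members, member_models=owners))
    patches.sort(key=lambda p: sorted(p.residues)[0])
    return patches


# ---------------------------------------------------------------------------
# disruption scoring

def score_disruption(s: Structure, m: MutationSpec, part: ChainPartition,
                     table: Mapping[tuple[ResidueKey, str, str], float] | None = None,
                     cutoff: float = 5.0) -> float:
    """Predicted binding-disruption score of one mutation (higher = worse for binding).

    With an external ddG table (e.g. from a fast side-chain repacking scan)
    the tabulated value is returned verbatim. The builtin proxy counts the
    position's cross-partition heavy-atom contacts within ``cutoff`` and
    multiplies by a substitution-dissimilarity weight (0 when wild type and
    substitution share a physicochemical class, 1 otherwise).
    """
    residue = s.residue(m.position)
    wt_expected = THREE_TO_ONE.get(residue.name)
    if wt_expected is not None and wt_expected != m.wt:
        raise ValueError(
            f"{m.position}: structure has {residue.name} ({wt_expected}), mutation says {m.wt}")
    if table is not None:
        key = (m.position, m.wt, m.sub)
        if key not in table:
            raise KeyError(f"no tabulated ddG for {m}")
        return float(table[key])
    part.validate(s)
    own_side = part.binder_chains if m.position[0] in part.binder_chains else part.target_chains
    other_side = part.target_chains if own_side is part.binder_chains else part.binder_chains
    other_xyz = np.concatenate(
        [r.coords() for r in s.residues(sorted(other_side))], axis=0)
    own_xyz = residue.coords()
    dist = np.linalg.norm(own_xyz[:, None, :] - other_xyz[None, :, :], axis=-1)
    n_contacts = int(np.count_nonzero(dist < cutoff))
    weight = 0.0 if aa_class(m.wt) == aa_class(m.sub) else 1.0
    return n_contacts * weight


def propose_mutations(s: Structure, patch: Patch, part: ChainPartition,
                      table: Mapping[tuple[ResidueKey, str, str], float] | None = None,
                      exclude_positions: Iterable[ResidueKey] = (),
                      ) -> dict[ResidueKey, tuple[MutationSpec, float]]:
    """Default disruptive mutation + score for each patch position.

    ``exclude_positions`` is the hook for stability-risk positions a user
    wants kept out of designs.
    """
    excluded = set(exclude_positions)
    out: dict[ResidueKey, tuple[MutationSpec, float]] = {}
    for pos in sorted(patch.residues):
        if pos in excluded:
            continue
        wt = THREE_TO_ONE.get(s.residue(pos).name, "X")
        if wt == "X":
            continue
        spec = MutationSpec(position=pos, wt=wt, sub=default_substitution(wt))
        out[pos] = (spec, score_disruption(s, spec, part, table))
    return out


# ---------------------------------------------------------------------------
# exact set cover

def _coverage(positions: frozenset[ResidueKey],
              epitopes: Mapping[str, frozenset[ResidueKey] | set],
              rule: Literal["any", "all"]) -> frozenset[str]:
    if rule == "any":
        return frozenset(m for m, epi in epitopes.items() if positions & set(epi))
    return frozenset(m for m, epi in epitopes.items() if positions <= set(epi))


def _make_specs(positions: Iterable[ResidueKey],
                mutations: Mapping[ResidueKey, MutationSpec] | None
                ) -> tuple[MutationSpec, ...]:
    # "X>K" placeholders let the cover solver run on abstract instances
    # (epitopes only, no structure); real pipelines pass propose_mutations output.
    return tuple(sorted(
        mutations[p] if mutations is not None and p in mutations
        else MutationSpec(p, "X", "K")
        for p in positions))


def enumerate_candidate_variants(
    epitopes: Mapping[str, frozenset[ResidueKey] | set],
    patches: Sequence[Patch],
    k: int = DEFAULT_MUTATIONS_PER_VARIANT,
    disruption: Mapping[ResidueKey, float] | None = None,
    mutations: Mapping[ResidueKey, MutationSpec] | None = None,
    coverage_rule: Literal["any", "all"] = "any",
) -> list[tuple[VariantDesign, float]]:
    """All distinct-coverage candidate variants (<= k positions, one patch each).

    Candidates with identical model coverage are collapsed to the one with the
    highest summed disruption score (lexicographically smallest position set on
    ties), which keeps the exact cover search small without losing optima.
    """
    disruption = disruption or {}
    best: dict[frozenset[str], tuple[float, tuple[ResidueKey, ...]]] = {}
    for patch in patches:
        positions = sorted(patch.residues)
        if mutations is not None:
            positions = [p for p in positions if p in mutations]
        if len(positions) > _PATCH_POSITION_CAP:
            keep = sorted(positions, key=lambda p: (-disruption.get(p, 0.0), p))
            positions = sorted(keep[:_PATCH_POSITION_CAP])
        for size in range(1, min(k, len(positions)) + 1):
            for combo in itertools.combinations(positions, size):
                covered = _coverage(frozenset(combo), epitopes, coverage_rule)
                if not covered:
                    continue
                score = sum(disruption.get(p, 0.0) for p in combo)
                prev = best.get(covered)
                if prev is None or score > prev[0] or (score == prev[0] and combo < prev[1]):
                    best[covered] = (score, combo)
    out = [
        (VariantDesign(mutations=_make_specs(combo, mutations), covered_models=covered), score)
        for covered, (score, combo) in best.items()
    ]
    out.sort(key=lambda vs: tuple(sorted(vs[0].positions)))
    return out


def design_variant_panel(
    epitopes: Mapping[str, frozenset[ResidueKey] | set],
    patches: Sequence[Patch],
    k: int = DEFAULT_MUTATIONS_PER_VARIANT,
    alternates: int = 2,
    disruption: Mapping[ResidueKey, float] | None = None,
    mutations: Mapping[ResidueKey, MutationSpec] | None = None,
    coverage_rule: Literal["any", "all"] = "any",
) -> list[Panel]:
    """Exact minimum panel of variants covering every docking model.

    Returns the optimal panel first, followed by up to ``alternates`` next-best
    distinct panels (ordered by size, then descending total disruption, then
    lexicographic variant order). Models no candidate variant can cover are
    reported on each panel rather than silently dropped.
    """
    candidates = enumerate_candidate_variants(
        epitopes, patches, k=k, disruption=disruption,
        mutations=mutations, coverage_rule=coverage_rule)
    all_models = frozenset(epitopes)
    coverable: frozenset[str] = frozenset()
    for v, _ in candidates:
        coverable |= v.covered_models
    uncoverable = all_models - coverable
    if not candidates:
        return [Panel(variants=(), objective=(0, 0.0), uncoverable_models=uncoverable)]

    solutions = _covers_up_to_size(candidates, coverable, alternates)
    panels = [
        Panel(variants=tuple(sorted(vs, key=lambda v: tuple(sorted(v.positions)))),
              objective=(len(vs), total), uncoverable_models=uncoverable)
        for vs, total in solutions
    ]
    return panels[: alternates + 1]


def _covers_up_to_size(candidates: Sequence[tuple[VariantDesign, float]],
                       universe: frozenset[str],
                       alternates: int) -> list[tuple[list[VariantDesign], float]]:
    """Covering panels in optimal order via iterative-deepening exact search."""
    if not universe:
        return [([], 0.0)]
    solutions: list[tuple[tuple, list[VariantDesign], float]] = []
    n = len(candidates)
    for size in range(1, n + 1):
        found: list[tuple[list[VariantDesign], float]] = []

        def extend(start: int, chosen: list[int], covered: frozenset[str]) -> None:
            if len(chosen) == size:
                if covered >= universe:
                    vs = [candidates[i][0] for i in chosen]
                    found.append((vs, sum(candidates[i][1] for i in chosen)))
                return
            remaining_slots = size - len(chosen)
            # bound: the best remaining candidates must be able to finish the cover
            for i in range(start, n - remaining_slots + 1):
                v, _ = candidates[i]
                rest = frozenset().union(
                    *(candidates[j][0].covered_models for j in range(i, n)))
                if not (covered | rest) >= universe:
                    break
                extend(i + 1, chosen + [i], covered | v.covered_models)

        extend(0, [], frozenset())
        if found:
            found.sort(key=lambda ft: (-ft[1], [tuple(sorted(v.positions)) for v in ft[0]]))
            for vs, total in found:
                solutions.append(((len(vs), -total), vs, total))
            if len(solutions) > alternates:
                break
    solutions.sort(key=lambda s: (s[0], [tuple(sorted(v.positions)) for v in s[1]]))
    return [(vs, total) for _, vs, total in solutions]


def check_coverage(panel: Panel, epitopes: Mapping[str, frozenset[ResidueKey] | set],
                   coverage_rule: Literal["any", "all"] = "any") -> bool:
    """Direct predicate check that the panel covers every coverable model."""
    covered: set[str] = set(panel.uncoverable_models)
    for v in panel.variants:
        covered |= _coverage(v.positions, epitopes, coverage_rule)
    return covered >= set(epitopes)


# ---------------------------------------------------------------------------
# external ddG tables

def read_ddg_table(path: str | Path) -> dict[tuple[ResidueKey, str, str], float]:
    """TSV with columns chain, number, icode, wt, sub, ddg."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "icode": str})
    table: dict[tuple[ResidueKey, str, str], float] = {}
    for row in df.itertuples(index=False):
        icode = "" if pd.isna(row.icode) or row.icode in ("", "-") else str(row.icode)
        key = ((str(row.chain), int(row.number), icode), str(row.wt), str(row.sub))
        table[key] = float(row.ddg)
    return table
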