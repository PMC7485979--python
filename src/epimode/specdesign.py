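"""Conservation-guided specificity analysis and greedy multi-target design.

Given a confirmed complex model, cross-species specificity is traced to
binder residues that contact target positions where homolog sequences
diverge. Affinity design scans substitutions at chosen binder positions
against one or more target complexes with a deterministic residue-level
contact potential (or an imported ddG table), then fixes the best first-site
substitution and re-scans the second site — the greedy two-stage scheme used
for double-mutant design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Mapping, Sequence

import numpy as np

from ._aa import STANDARD_AA, THREE_TO_ONE, aa_class
from .interface import ChainPartition, residue_contacts
from .paneldesign import MutationSpec
from .structio import ResidueKey, Structure

DEFAULT_SCAN_EXCLUDE = frozenset({"C", "P"})  # disulfide / backbone-geometry risks


# ---------------------------------------------------------------------------
# homolog alignments and conservation classes

@dataclass(frozen=True)
class HomologAlignment:
    labels: tuple[str, ...]
    sequences: tuple[str, ...]  # aligned, equal length, '-' gaps
    column_keys: Mapping[int, ResidueKey]  # alignment column -> target residue key

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        if len(self.labels) != len(self.sequences):
            raise ValueError("one label per sequence required")

    @property
    def n_species(self) -> int:
        return len(self.sequences)

    def column_of(self, position: ResidueKey) -> int:
        for col, key in self.column_keys.items():
            if key == position:
                return col
        raise KeyError(f"position {position} not mapped to an alignment column")

    @classmethod
    def from_fasta(cls, path: str | Path, reference_label: str,
                   reference_keys: Sequence[ResidueKey]) -> "HomologAlignment":
        """Load a pre-aligned FASTA; map reference non-gap columns to residue keys."""
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"{path}: no FASTA records")
        labels = tuple(r.id for r in records)
        sequences = tuple(str(r.seq).upper() for r in records)
        if reference_label not in labels:
            raise ValueError(f"reference {reference_label!r} not among {labels}")
        ref_seq = sequences[labels.index(reference_label)]
        non_gap_cols = [i for i, c in enumerate(ref_seq) if c != "-"]
        if len(non_gap_cols) != len(reference_keys):
            raise ValueError(
                f"reference has {len(non_gap_cols)} residues but "
                f"{len(reference_keys)} keys were supplied")
        column_keys = dict(zip(non_gap_cols, reference_keys))
        return cls(labels=labels, sequences=sequences, column_keys=column_keys)


ConsClass = Literal["shared_by_all", "shared_by_two", "unique"]


@dataclass(frozen=True)
class ConservationClass:
    position: ResidueKey
    cls: ConsClass


def classify_conservation(aln: HomologAlignment,
                          positions: Iterable[ResidueKey]) -> list[ConservationClass]:
    """Conservation class per position from the column amino-acid multiset.

    With n species: 1 distinct residue -> shared_by_all, n distinct -> unique,
    anything between -> shared_by_two (shared by a proper subset). Gaps count
    as distinct characters.
    """
    out = []
    for pos in sorted(set(positions)):
        col = aln.column_of(pos)
        chars = {seq[col] for seq in aln.sequences}
        if len(chars) == 1:
            cls: ConsClass = "shared_by_all"
        elif len(chars) == aln.n_species:
            cls = "unique"
        else:
            cls = "shared_by_two"
        out.append(ConservationClass(position=pos, cls=cls))
    return out


def specificity_candidates(model: Structure, part: ChainPartition,
                           classes: Sequence[ConservationClass],
                           cutoff: float = 5.0) -> list[tuple[ResidueKey, int]]:
    """Binder residues ranked by how many divergent target positions they contact.

    A binder residue touching many positions where the homologs differ is the
    prime candidate for switching or broadening specificity.
    """
    by_pos = {c.position: c.cls for c in classes}
    contacts = residue_contacts(model, part, cutoff)
    counts: dict[ResidueKey, int] = {}
    for b, t in contacts.pairs:
        counts.setdefault(b, 0)
        if by_pos.get(t, "shared_by_all") != "shared_by_all":
            counts[b] += 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# residue-level contact potential (deterministic scan surrogate)

# Pairwise class interaction energies (arbitrary units, negative = favourable).
_CLASS_POTENTIAL: dict[frozenset[str], float] = {
    frozenset({"positive", "negative"}): -1.0,
    frozenset({"positive"}): +1.0,
    frozenset({"negative"}): +1.0,
    frozenset({"hydrophobic"}): -0.5,
    frozenset({"hydrophobic", "aromatic"}): -0.4,
    frozenset({"aromatic"}): -0.4,
    frozenset({"aromatic", "positive"}): -0.2,  # cation-pi flavoured
    frozenset({"polar"}): -0.2,
    frozenset({"polar", "positive"}): -0.1,
    frozenset({"polar", "negative"}): -0.1,
}


def contact_potential(aa_binder: str, aa_target: str) -> float:
    key = frozenset({aa_class(aa_binder), aa_class(aa_target)})
    return _CLASS_POTENTIAL.get(key, 0.0)


def _default_scan_scorer(complex_structure: Structure, part: ChainPartition,
                         position: ResidueKey, wt: str, sub: str,
                         cutoff: float = 5.0) -> float:
    """Change in summed residue-level contact potential upon mutating one position.

    Negative = predicted affinity gain. Identity substitutions score 0 by
    construction.
    """
    contacts = residue_contacts(complex_structure, part, cutoff)
    total = 0.0
    for b, t in contacts.pairs:
        if b != position:
            continue
        t_aa = THREE_TO_ONE.get(complex_structure.residue(t).name)
        if t_aa is None:
            continue
        total += contact_potential(sub, t_aa) - contact_potential(wt, t_aa)
    return total


ScanScorer = Callable[[Structure, ChainPartition, ResidueKey, str, str], float]


def scan_mutations(targets: Mapping[str, tuple[Structure, ChainPartition]],
                   positions: Sequence[ResidueKey],
                   scorer: ScanScorer | None = None,
                   exclude: frozenset[str] | set[str] = DEFAULT_SCAN_EXCLUDE,
                   ddg_tables: Mapping[str, Mapping[tuple[ResidueKey, str, str], float]] | None = None,
                   ) -> dict[tuple[ResidueKey, str, str], float]:
    """Score every substitution at every position against every target complex.

    Returns a complete, deterministic matrix keyed by (position, substitution,
    target id); the wild-type residue and excluded amino acids (Cys/Pro by
    default) are omitted. ``ddg_tables`` (per-target imported ddG values) take
    precedence over the builtin scorer.
    """
    scorer = scorer or _default_scan_scorer
    matrix: dict[tuple[ResidueKey, str, str], float] = {}
    for target_id, (structure, part) in targets.items():
        for pos in positions:
            try:
                residue = structure.residue(pos)
            except KeyError:
                raise KeyError(
                    f"scan position {pos} absent from target complex {target_id!r}") from None
            wt = THREE_TO_ONE.get(residue.name, "X")
            for sub in STANDARD_AA:
                if sub == wt or sub in exclude:
                    continue
                if ddg_tables is not None and target_id in ddg_tables:
                    value = float(ddg_tables[target_id][(pos, wt, sub)])
                else:
                    value = float(scorer(structure, part, pos, wt, sub))
                matrix[(pos, sub, target_id)] = value
    return matrix


# ---------------------------------------------------------------------------
# design records and greedy double design

@dataclass(frozen=True)
class SegmentReplacement:
    start: ResidueKey
    removed: str  # verbatim removed sequence, 1-letter
    inserted: str

    def __str__(self) -> str:
        cid, num, icode = self.start
        return f"{cid}:{num}{icode} {self.removed}->{self.inserted}"


@dataclass(frozen=True)
class DesignRecord:
    mutations: tuple[MutationSpec, ...] = ()
    segment: SegmentReplacement | None = None
    predicted_scores: Mapping[str, float] = field(default_factory=dict)  # target -> score
    stage_scores: tuple[Mapping[str, float], ...] = ()


def record_loop_replacement(start: ResidueKey, removed: str, inserted: str,
                            predicted_scores: Mapping[str, float] | None = None) -> DesignRecord:
    """Sequence-level record of a segment swap (e.g. truncating a specificity loop)."""
    return DesignRecord(segment=SegmentReplacement(start, removed, inserted),
                        predicted_scores=dict(predicted_scores or {}))


Aggregate = Literal["worst_case", "sum"]


def _aggregate(values: Iterable[float], how: Aggregate) -> float:
    values = list(values)
    return max(values) if how == "worst_case" else sum(values)


def greedy_double_design(matrix: Mapping[tuple[ResidueKey, str, str], float],
                         pos1: ResidueKey, pos2: ResidueKey,
                         aggregate: Aggregate = "worst_case",
                         wildtypes: Mapping[ResidueKey, str] | None = None) -> DesignRecord:
    """Two-stage greedy double-mutant design over a scan matrix.

    Stage 1 picks the substitution at ``pos1`` minimizing the aggregate score
    across targets; stage 2 fixes it, adds the per-target stage-1 scores to
    each candidate at ``pos2`` (the matrix is per-site, so combination scores
    are additive) and picks likewise. Worst-case aggregation (max over
    targets) suits designs that must bind every target.
    """
    targets = sorted({t for (_, _, t) in matrix})
    if not targets:
        raise ValueError("empty scan matrix")

    def candidates(pos: ResidueKey) -> list[str]:
        subs = sorted({s for (p, s, _) in matrix if p == pos})
        if not subs:
            raise ValueError(f"no candidate substitutions at {pos}")
        return subs

    def per_target(pos: ResidueKey, sub: str) -> dict[str, float]:
        return {t: matrix[(pos, sub, t)] for t in targets}

    stage1 = min(candidates(pos1),
                 key=lambda s: (_aggregate(per_target(pos1, s).values(), aggregate), s))
    s1_scores = per_target(pos1, stage1)

    def combined(sub: str) -> dict[str, float]:
        s2 = per_target(pos2, sub)
        return {t: s1_scores[t] + s2[t] for t in targets}

    stage2 = min(candidates(pos2),
                 key=lambda s: (_aggregate(combined(s).values(), aggregate), s))
    final_scores = combined(stage2)

    wildtypes = wildtypes or {}
    mut1 = MutationSpec(pos1, wt=wildtypes.get(pos1, "X"), sub=stage1)
    mut2 = MutationSpec(pos2, wt=wildtypes.get(pos2, "X"), sub=stage2)
    return DesignRecord(
        mutations=(mut1, mut2),
        predicted_scores=final_scores,
        stage_scores=(s1_scores, final_scores),
    )


def export_scan_matrix(matrix: Mapping[tuple[ResidueKey, str, str], float],
                       path: str | Path) -> Path:
    """TSV export: chain, number, icode, sub, target, score."""
    import pandas as pd

    rows = [
        {"chain": pos[0], "number": pos[1], "icode": pos[2],
         "sub": sub, "target": target, "score": value}
        for (pos, sub, target), value in sorted(matrix.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)
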