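"""Deterministic synthetic complexes, decoy ensembles and simulated assays.

Every pipeline stage is testable offline against fixtures with known ground
truth: toy two-chain complexes whose contact set is planted exactly, rigid-
body decoys of graded quality with oracle-computed metrics, C2 homodimer
targets where the binder engages one protomer, and simulated dissociation-
constant tables with multiplicative (log-normal) noise, mirroring how
calorimetry fold-changes behave.

Fixture geometry is idealized (compact pseudo-residues on a line, not real
stereochemistry); everything in scope consumes coordinates and residue
identities only, so this is sufficient — and it makes exact planted contact
sets constructible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .capriqc import QualityMetrics, assess
from .filterrank import AssayEntry, AssayTable
from .interface import ChainPartition, SymmetryMap, residue_contacts
from .paneldesign import MutationSpec, Panel
from .structio import Atom, Residue, ResidueKey, Structure

# Atom offsets (A) around a residue centre; max norm ~1.17 so residues whose
# centres are 4 A apart are in 5 A heavy-atom contact and centres >= 8 A
# apart never are.
_ATOM_OFFSETS = {
    "N": (-0.60, 0.40, 0.00),
    "CA": (0.00, 0.00, 0.00),
    "C": (0.60, 0.40, 0.00),
    "O": (0.60, 1.00, 0.00),
    "CB": (0.00, -0.80, 0.40),
}
_SPACING = 8.0       # centre-to-centre spacing within a chain
_CONTACT_GAP = 4.0   # centre gap for planted contacts (heavy atoms well under 5 A)
_FAR_GAP = 30.0      # binder residues without planted contacts sit this far away
_JITTER = 0.03       # deterministic seeded jitter, small enough to keep margins


@dataclass(frozen=True)
class ToySpec:
    binder_length: int = 6
    target_length: int = 12
    contacts: tuple[tuple[int, int], ...] = ((2, 5), (3, 6), (4, 7))  # (binder, target) numbers
    binder_chain: str = "R"
    target_chain: str = "T"
    spacing: float = _SPACING
    seed: int = 0

    def __post_init__(self) -> None:
        for b, t in self.contacts:
            if not (1 <= b <= self.binder_length and 1 <= t <= self.target_length):
                raise ValueError(f"planted contact ({b}, {t}) outside chain lengths")


@dataclass(frozen=True)
class DecoySchedule:
    """Rigid-body binder perturbations; must include the identity (the native)."""

    moves: tuple[tuple[float, tuple[float, float, float]], ...]  # (rotation deg about z, translation)
    seed: int = 0

    def __post_init__(self) -> None:
        if not any(rot == 0.0 and tuple(t) == (0.0, 0.0, 0.0) for rot, t in self.moves):
            raise ValueError("schedule must include the identity perturbation")


class UnrealizableContactsError(ValueError):
    """Planted contact list cannot be realized under the 5 A cutoff geometry."""


def _make_residue(chain_id: str, number: int, centre: np.ndarray,
                  rng: np.random.Generator | None, name: str = "ALA") -> Residue:
    atoms = []
    for atom_name, offset in _ATOM_OFFSETS.items():
        if name == "GLY" and atom_name == "CB":
            continue
        xyz = centre + np.asarray(offset)
        if rng is not None:
            xyz = xyz + rng.uniform(-_JITTER, _JITTER, size=3)
        element = atom_name[0]
        atoms.append(Atom(name=atom_name, element=element, xyz=xyz))
    return Residue(chain_id, number, "", name, atoms)


def make_toy_complex(spec: ToySpec = ToySpec(),
                     sequences: Mapping[str, str] | None = None) -> Structure:
    """Two-chain complex whose 5 A contact set equals the planted list exactly.

    Target residues lie on a line; binder residues with planted contacts sit
    4 A above their partner (centroid when one binder residue contacts
    several targets), all others 30 A away. ``sequences`` optionally assigns
    1-letter sequences per chain id (default poly-alanine).
    """
    rng = np.random.default_rng(spec.seed)
    targets_of: dict[int, list[int]] = {}
    for b, t in spec.contacts:
        targets_of.setdefault(b, []).append(t)

    def centre_of_target(t: int) -> np.ndarray:
        return np.array([t * spec.spacing, 0.0, 0.0])

    from ._aa import ONE_TO_THREE

    def residue_name(chain: str, number: int) -> str:
        if sequences and chain in sequences:
            return ONE_TO_THREE.get(sequences[chain][number - 1].upper(), "ALA")
        return "ALA"

    target_residues = [
        _make_residue(spec.target_chain, t, centre_of_target(t), rng,
                      residue_name(spec.target_chain, t))
        for t in range(1, spec.target_length + 1)
    ]
    used_centres: list[np.ndarray] = []
    binder_residues = []
    for b in range(1, spec.binder_length + 1):
        if b in targets_of:
            centre = np.mean([centre_of_target(t) for t in targets_of[b]], axis=0)
            centre = centre + np.array([0.0, _CONTACT_GAP, 0.0])
            # stack binder residues sharing a centre along z so atoms never coincide
            n_same = sum(1 for c in used_centres if np.allclose(c[:2], centre[:2]))
            centre = centre + np.array([0.0, 0.0, 1.5 * n_same])
            used_centres.append(centre)
        else:
            centre = np.array([b * spec.spacing, _FAR_GAP, 0.0])
        binder_residues.append(
            _make_residue(spec.binder_chain, b, centre, rng,
                          residue_name(spec.binder_chain, b)))

    s = Structure(id=f"toy-seed{spec.seed}", chains={
        spec.binder_chain: binder_residues,
        spec.target_chain: target_residues,
    })
    part = ChainPartition(frozenset({spec.binder_chain}), frozenset({spec.target_chain}))
    realized = {
        (b[1], t[1]) for b, t in residue_contacts(s, part, 5.0).pairs
    }
    if realized != set(spec.contacts):
        raise UnrealizableContactsError(
            f"planted {sorted(set(spec.contacts))} but geometry realizes {sorted(realized)}")
    return s


def toy_partition(spec: ToySpec = ToySpec()) -> ChainPartition:
    return ChainPartition(frozenset({spec.binder_chain}), frozenset({spec.target_chain}))


def _rotation_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0.0],
                     [np.sin(a), np.cos(a), 0.0],
                     [0.0, 0.0, 1.0]])


def perturb_binder(native: Structure, part: ChainPartition,
                   rot_deg: float, translation: Sequence[float]) -> Structure:
    """Rotate the binder about its centroid (z axis), then translate it."""
    binder_coords = np.concatenate(
        [r.coords() for r in native.residues(sorted(part.binder_chains))], axis=0)
    centroid = binder_coords.mean(axis=0)
    rot = _rotation_z(rot_deg)
    # x -> R (x - c) + c + t
    t = centroid - rot @ centroid + np.asarray(translation, dtype=float)
    return native.transform(rot, t, chain_ids=part.binder_chains)


def make_decoy_set(native: Structure, schedule: DecoySchedule,
                   part: ChainPartition) -> list[tuple[Structure, QualityMetrics]]:
    """Rigid-body decoys per schedule, with oracle-computed quality labels."""
    if len(residue_contacts(native, part, 5.0)) == 0:
        raise ValueError("native complex has no contacts; decoys would be meaningless")
    out = []
    for i, (rot_deg, translation) in enumerate(schedule.moves):
        decoy = perturb_binder(native, part, rot_deg, translation)
        decoy.id = f"decoy_{i:03d}"
        decoy.meta["perturbation"] = {"rot_deg": rot_deg, "translation": tuple(translation)}
        with warnings.catch_warnings():
            # fully dissociated decoys are expected here; their undefined
            # interface recovery is reported as NaN in the labels
            warnings.simplefilter("ignore", UserWarning)
            metrics = assess(decoy, native, part)
        out.append((decoy, metrics))
    return out


def make_homodimer_complex(protomer_length: int = 10,
                           epitope_numbers: tuple[int, ...] = (4, 5, 6),
                           seed: int = 0) -> tuple[Structure, SymmetryMap, ChainPartition]:
    """Binder + C2 homodimeric target; the binder contacts one protomer only.

    Protomer chains A and B are related by an exact two-fold rotation about z;
    the binder chain R engages the epitope positions on chain A.
    """
    rng = np.random.default_rng(seed)
    protomer_a = [
        _make_residue("A", i, np.array([i * _SPACING, 0.0, 0.0]), rng)
        for i in range(1, protomer_length + 1)
    ]
    # exact C2: rotate protomer A's centres by 180 deg about the z axis through
    # (cx, -10, 0); jitter is applied per-protomer so symmetry stays exact only
    # at centre level, which is all the contact logic sees. Use no jitter on B
    # mirror of A atom positions to keep the rotation exact at atom level.
    cx = (protomer_length + 1) * _SPACING / 2.0
    axis_point = np.array([cx, -10.0, 0.0])
    rot180 = _rotation_z(180.0)
    protomer_b = []
    for res in protomer_a:
        atoms = [Atom(a.name, a.element, rot180 @ (a.xyz - axis_point) + axis_point)
                 for a in res.atoms]
        protomer_b.append(Residue("B", res.number, "", res.name, atoms))
    binder = [
        _make_residue("R", j + 1,
                      np.array([n * _SPACING, _CONTACT_GAP, 0.0]), rng)
        for j, n in enumerate(epitope_numbers)
    ]
    s = Structure(id=f"homodimer-seed{seed}",
                  chains={"R": binder, "A": protomer_a, "B": protomer_b})
    sym = SymmetryMap(equivalences=(frozenset({"A", "B"}),))
    part = ChainPartition(frozenset({"R"}), frozenset({"A", "B"}))
    return s, sym, part


def simulate_assay_outcomes(native_epitope: frozenset[ResidueKey] | set,
                            panel: Panel,
                            wt_kd: float = 128.0,
                            effect: float = 3.0,
                            noise_sd: float = 0.0,
                            seed: int = 0,
                            sym: SymmetryMap | None = None) -> AssayTable:
    """Simulated Kd table for a variant panel against a planted epitope.

    Kd(variant) = wt_kd * effect^(mutated positions inside the epitope) *
    exp(N(0, noise_sd)) — multiplicative disruption per epitope hit with
    log-normal measurement noise. Single-mutant entries are generated for
    every panel position, mirroring the follow-up measurements that resolve
    which positions of a disruptive multi-mutant actually matter.
    """
    if effect <= 1.0:
        raise ValueError("effect must exceed 1 (fold-change per epitope hit)")
    rng = np.random.default_rng(seed)
    native = frozenset(native_epitope)

    def hits(positions: frozenset[ResidueKey]) -> int:
        n = 0
        for p in positions:
            orbit = sym.orbit(p) if sym is not None else {p}
            if orbit & native:
                n += 1
        return n

    entries = [AssayEntry("WT", (), wt_kd)]
    singles: dict[ResidueKey, MutationSpec] = {}
    for i, variant in enumerate(panel.variants, start=1):
        noise = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
        kd = wt_kd * effect ** hits(variant.positions) * noise
        entries.append(AssayEntry(f"Var{i}", tuple(sorted(variant.mutations)), kd))
        for m in variant.mutations:
            singles.setdefault(m.position, m)
    for pos in sorted(singles):
        m = singles[pos]
        noise = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
        kd = wt_kd * effect ** hits(frozenset({pos})) * noise
        entries.append(AssayEntry(f"single_{m}", (m,), kd))
    return AssayTable.from_entries(entries)
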