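"""PDB coordinate I/O, substructure selection and rigid-body superposition.

The hierarchical model is deliberately minimal: chains of residues of heavy
atoms, keyed by author numbering plus insertion code exactly as deposited.
Hydrogens are dropped on read and alternate locations are collapsed to the
highest-occupancy conformer, so every downstream distance computation sees a
single, unambiguous set of heavy-atom coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

#: (chain_id, author residue number, insertion code "" when absent)
ResidueKey = tuple[str, int, str]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class PDBFormatError(ValueError):
    """Raised when a coordinate file or record cannot be interpreted."""


class EmptyStructureError(ValueError):
    """Raised when a file or selection contains no usable heavy atoms."""


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), angstroms
    occupancy: float = 1.0
    altloc: str = ""
    serial: int = 0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name!r}: coordinates must be 3 finite numbers")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        """Heavy-atom coordinate array, shape (n_atoms, 3)."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def rep_coord(self) -> np.ndarray:
        """Side-chain representative point: CB, falling back to CA (Gly)."""
        a = self.atom("CB") or self.atom("CA")
        if a is None:
            return self.coords().mean(axis=0)
        return a.xyz


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[ResidueKey] = set()
        for cid, residues in self.chains.items():
            for r in residues:
                if r.chain_id != cid:
                    raise ValueError(f"residue {r.key} filed under chain {cid!r}")
                if r.key in seen:
                    raise ValueError(f"duplicate residue key {r.key}")
                seen.add(r.key)

    def residues(self, chain_ids: Iterable[str] | None = None) -> Iterator[Residue]:
        ids = list(self.chains) if chain_ids is None else list(chain_ids)
        for cid in ids:
            yield from self.chains[cid]

    def residue(self, key: ResidueKey) -> Residue:
        cid, number, icode = key
        for r in self.chains.get(cid, []):
            if r.number == number and r.icode == icode:
                return r
        raise KeyError(f"residue {key} not in structure {self.id!r}")

    def has_residue(self, key: ResidueKey) -> bool:
        try:
            self.residue(key)
            return True
        except KeyError:
            return False

    @property
    def chain_ids(self) -> set[str]:
        return set(self.chains)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def copy(self) -> "Structure":
        return Structure(
            id=self.id,
            chains={
                cid: [
                    Residue(r.chain_id, r.number, r.icode, r.name,
                            [Atom(a.name, a.element, a.xyz.copy(), a.occupancy, a.altloc, a.serial)
                             for a in r.atoms])
                    for r in residues
                ]
                for cid, residues in self.chains.items()
            },
            meta=dict(self.meta),
        )

    def transform(self, rotation: np.ndarray, translation: np.ndarray,
                  chain_ids: Iterable[str] | None = None) -> "Structure":
        """Return a copy with x -> R x + t applied to the selected chains."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        out = self.copy()
        targets = out.chain_ids if chain_ids is None else set(chain_ids)
        for r in out.residues():
            if r.chain_id in targets:
                for a in r.atoms:
                    a.xyz = rotation @ a.xyz + translation
        return out


@dataclass
class Superposition:
    rotation: np.ndarray  # (3, 3) proper rotation
    translation: np.ndarray  # (3,) angstroms
    rmsd: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# reading / writing

_HYDROGEN_ELEMENTS = {"H", "D"}


def read_pdb(path: str | Path, model_policy: Literal["first"] | int = "first",
             include_hetatm: bool = False) -> Structure:
    """Read a PDB file into a heavy-atom :class:`Structure`.

    Hydrogens are dropped; for altloc duplicates the highest-occupancy
    conformer wins (alphabetical altloc on ties); multi-model files keep the
    model chosen by ``model_policy`` ("first" or a 0-based index).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    index = 0 if model_policy == "first" else int(model_policy)
    if index >= len(st):
        raise IndexError(f"{path}: model index {index} out of range ({len(st)} models)")
    model = st[index]

    chains: dict[str, list[Residue]] = {}
    for chain in model:
        cid = chain.name
        residues = chains.setdefault(cid, [])
        for res in chain:
            is_het = res.het_flag == "H" and res.name != "MSE"
            if is_het and not include_hetatm:
                continue
            icode = res.seqid.icode.strip()
            # collapse altlocs: per atom name keep (max occupancy, min altloc)
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element.name.upper() in _HYDROGEN_ELEMENTS:
                    continue
                prev = best.get(atom.name)
                if prev is None or (atom.occ, _altloc_rank(atom.altloc)) > (
                        prev.occ, _altloc_rank(prev.altloc)):
                    best[atom.name] = atom
            if not best:
                continue
            atoms = [
                Atom(name=a.name, element=a.element.name.upper(),
                     xyz=np.array([a.pos.x, a.pos.y, a.pos.z]),
                     occupancy=min(max(a.occ, 0.0), 1.0),
                     altloc=(a.altloc or "").replace("\x00", "").strip(),
                     serial=a.serial)
                for a in best.values()
            ]
            atoms.sort(key=lambda a: a.serial)
            residues.append(Residue(cid, res.seqid.num, icode, res.name, atoms))
    chains = {cid: rs for cid, rs in chains.items() if rs}
    if not chains:
        raise EmptyStructureError(f"{path}: no heavy atoms retained")
    return Structure(id=path.stem, chains=chains, meta={"source": str(path)})


def _altloc_rank(altloc: str) -> float:
    """Sort helper: larger is better; '' beats 'A' beats 'B'."""
    altloc = (altloc or "").replace("\x00", "").strip()
    return 0.0 if not altloc else -ord(altloc)


def _prevalidate_pdb(path: Path) -> None:
    n_atoms = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                n_atoms += 1
                if len(line.rstrip("\n")) < 54:
                    raise PDBFormatError(f"{path}:{lineno}: truncated {rec} record")
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError:
                    raise PDBFormatError(
                        f"{path}:{lineno}: unparseable coordinates in {rec} record") from None
    if n_atoms == 0:
        raise EmptyStructureError(f"{path}: no ATOM records")


def write_pdb(s: Structure, path: str | Path) -> Path:
    """Write a structure as standard ATOM/TER records (3-decimal coordinates)."""
    if not s.chains or s.n_atoms() == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    path = Path(path)
    lines: list[str] = []
    serial = 0
    for cid, residues in s.chains.items():
        if len(cid) != 1:
            raise PDBFormatError(f"chain id {cid!r} does not fit the 1-character PDB field")
        for r in residues:
            if not (-999 <= r.number <= 9999):
                raise PDBFormatError(f"residue number {r.number} outside the PDB field range")
            if len(r.icode) > 1:
                raise PDBFormatError(f"insertion code {r.icode!r} longer than 1 character")
            for a in r.atoms:
                serial += 1
                if np.any(np.abs(a.xyz) >= 10000):
                    raise PDBFormatError(f"coordinate {a.xyz} outside the PDB field range")
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name}{a.altloc or ' '}{r.name:>3s} "
                    f"{cid}{r.number:4d}{r.icode or ' '}   "
                    f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                    f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
                )
        serial += 1
        last = residues[-1]
        lines.append(f"TER   {serial:5d}      {last.name:>3s} {cid}{last.number:4d}{last.icode or ' '}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# superposition

def kabsch_superpose(ref_coords: np.ndarray, mov_coords: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``mov`` onto ``ref`` (proper rotation).

    Returns the :class:`Superposition` whose ``apply`` maps moving coordinates
    onto the reference frame with the minimized RMSD.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    ref_mean, mov_mean = ref.mean(axis=0), mov.mean(axis=0)
    ref_c, mov_c = ref - ref_mean, mov - mov_mean
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2 or np.linalg.matrix_rank(mov_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set: rotation is not determined")
    rot, rssd = Rotation.align_vectors(ref_c, mov_c)
    rmsd = float(rssd) / np.sqrt(n)
    rotation = rot.as_matrix()
    translation = ref_mean - rotation @ mov_mean
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd)


@dataclass
class CaRmsdResult:
    rmsd: float
    n_paired: int
    n_unpaired: int
    superposition: Superposition

    def __float__(self) -> float:
        return self.rmsd


def ca_rmsd(a: Structure, b: Structure,
            pairing: Literal["by_author_number", "by_alignment"] = "by_author_number"
            ) -> CaRmsdResult:
    """Minimized Calpha RMSD between two structures after Kabsch superposition.

    Residues are paired either by identical author numbering (same chain id,
    number, insertion code) or by global sequence alignment of chain
    sequences — the latter is what cross-entry comparisons of the same protein
    in different depositions need. Unpaired residues are excluded but counted.
    """
    pairs = (_pair_by_author_number(a, b) if pairing == "by_author_number"
             else _pair_by_alignment(a, b))
    coords_a, coords_b = [], []
    for ra, rb in pairs:
        ca_a, ca_b = ra.atom("CA"), rb.atom("CA")
        if ca_a is None or ca_b is None:
            continue
        coords_a.append(ca_a.xyz)
        coords_b.append(ca_b.xyz)
    total_a = sum(1 for _ in a.residues())
    total_b = sum(1 for _ in b.residues())
    n_paired = len(coords_a)
    n_unpaired = (total_a - n_paired) + (total_b - n_paired)
    if n_paired < 3:
        raise ValueError(f"only {n_paired} Calpha pairs; need at least 3")
    sup = kabsch_superpose(np.array(coords_a), np.array(coords_b))
    return CaRmsdResult(rmsd=sup.rmsd, n_paired=n_paired,
                        n_unpaired=n_unpaired, superposition=sup)


def _pair_by_author_number(a: Structure, b: Structure) -> list[tuple[Residue, Residue]]:
    index_b = {r.key: r for r in b.residues()}
    return [(r, index_b[r.key]) for r in a.residues() if r.key in index_b]


def _chain_pairs(a: Structure, b: Structure) -> list[tuple[str, str]]:
    if a.chain_ids == b.chain_ids:
        return [(cid, cid) for cid in a.chains]
    return list(zip(a.chains, b.chains))


def _pair_by_alignment(a: Structure, b: Structure) -> list[tuple[Residue, Residue]]:
    from Bio import Align
    from ._aa import THREE_TO_ONE

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0

    pairs: list[tuple[Residue, Residue]] = []
    for cid_a, cid_b in _chain_pairs(a, b):
        res_a = a.chains[cid_a]
        res_b = b.chains[cid_b]
        seq_a = "".join(THREE_TO_ONE.get(r.name, "X") for r in res_a)
        seq_b = "".join(THREE_TO_ONE.get(r.name, "X") for r in res_b)
        aln = aligner.align(seq_a, seq_b)[0]
        for (sa, ea), (sb, eb) in zip(aln.aligned[0], aln.aligned[1]):
            for i, j in zip(range(sa, ea), range(sb, eb)):
                pairs.append((res_a[i], res_b[j]))
    return pairs
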