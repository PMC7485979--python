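"""Per-position binding calls, docking-model consistency filtering and ranking.

The experimental readout is a table of dissociation constants: wild-type
target plus designed variants. A position is called binding-disruptive when
its single-mutant Kd fold-change exceeds a threshold, neutral when binding is
unchanged. A docking model is consistent with the calls when it contacts
every disrupted position (on either protomer of a symmetric target) and no
neutral position. Survivors are then ranked by interface energy — either an
imported table (e.g. minimized full-atom force-field totals computed
elsewhere) or the builtin cross-interface surrogate scorer.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .interface import (ChainPartition, SymmetryMap, contacts_under_symmetry,
                        format_key, parse_key)
from .paneldesign import MutationSpec
from .structio import ResidueKey, Structure

#: Smallest Kd fold-change treated as binding-disruptive. Chosen just below the
#: smallest single-mutant change a calorimetry assay typically resolves as a
#: meaningful loss (~1.5-fold) and above replicate noise; configurable everywhere.
DEFAULT_DISRUPTION_THRESHOLD = 1.4


# ---------------------------------------------------------------------------
# assay tables

@dataclass(frozen=True)
class AssayEntry:
    variant_id: str
    mutations: tuple[MutationSpec, ...]
    kd_nm: float
    n_rep: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.kd_nm) or self.kd_nm <= 0:
            raise ValueError(f"{self.variant_id}: Kd must be positive, got {self.kd_nm}")


@dataclass
class AssayTable:
    entries: dict[str, AssayEntry]
    wt_kd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.wt_kd) or self.wt_kd <= 0:
            raise ValueError("wild-type Kd must be positive")

    @classmethod
    def from_entries(cls, entries: Iterable[AssayEntry]) -> "AssayTable":
        index = {e.variant_id: e for e in entries}
        wt = index.pop("WT", None)
        if wt is None:
            raise ValueError("assay table lacks the required WT row")
        return cls(entries=index, wt_kd=wt.kd_nm)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AssayTable":
        """CSV columns: variant, mutations (';'-joined, e.g. 'A.H310A'), kd_nm, n_rep."""
        import pandas as pd

        df = pd.read_csv(path, dtype={"variant": str, "mutations": str})
        entries = []
        for row in df.itertuples(index=False):
            raw = "" if pd.isna(row.mutations) else str(row.mutations)
            muts = tuple(parse_mutation(tok) for tok in raw.split(";") if tok)
            n_rep = int(getattr(row, "n_rep", 1) or 1)
            entries.append(AssayEntry(str(row.variant), muts, float(row.kd_nm), n_rep))
        return cls.from_entries(entries)

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        rows = [{"variant": "WT", "mutations": "", "kd_nm": self.wt_kd, "n_rep": 1}]
        for e in self.entries.values():
            rows.append({"variant": e.variant_id,
                         "mutations": ";".join(str(m) for m in e.mutations),
                         "kd_nm": e.kd_nm, "n_rep": e.n_rep})
        pd.DataFrame(rows).to_csv(path, index=False)
        return Path(path)


_MUT_RE = re.compile(r"^(?P<chain>\w+)\.(?P<wt>[A-Z])(?P<number>-?\d+)(?P<icode>[A-Za-z]?)(?P<sub>[A-Z])$")


def parse_mutation(token: str) -> MutationSpec:
    """Parse 'CHAIN.WT<number><icode?>SUB' tokens such as 'A.H310A'."""
    m = _MUT_RE.match(token.strip())
    if not m:
        raise ValueError(f"cannot parse mutation token {token!r}")
    return MutationSpec(position=(m["chain"], int(m["number"]), m["icode"]),
                        wt=m["wt"], sub=m["sub"])


# ---------------------------------------------------------------------------
# position calls

Status = Literal["disrupted", "neutral", "untested"]


@dataclass(frozen=True)
class PositionCall:
    position: ResidueKey
    status: Status
    fold_change: float  # Kd(variant) / Kd(wt); NaN when untested


def call_positions(assay: AssayTable,
                   threshold: float = DEFAULT_DISRUPTION_THRESHOLD,
                   neutral_slack: float = 1.0) -> list[PositionCall]:
    """Per-position binding involvement from single-mutant Kd fold-changes.

    disrupted: fold >= threshold; neutral: fold <= threshold / neutral_slack;
    in between (only possible with neutral_slack > 1): untested/ambiguous.
    Positions mutated only inside multi-mutant variants stay untested — a
    triple mutant losing binding does not say which of its positions matters.
    """
    if threshold <= 1.0:
        raise ValueError("threshold must exceed 1.0")
    calls: dict[ResidueKey, PositionCall] = {}
    multi_positions: set[ResidueKey] = set()
    for e in assay.entries.values():
        if len(e.mutations) != 1:
            multi_positions.update(m.position for m in e.mutations)
            continue
        pos = e.mutations[0].position
        fold = e.kd_nm / assay.wt_kd
        if fold >= threshold:
            status: Status = "disrupted"
        elif fold <= threshold / neutral_slack:
            status = "neutral"
        else:
            status = "untested"
        calls[pos] = PositionCall(position=pos, status=status, fold_change=fold)
    for pos in multi_positions - set(calls):
        calls[pos] = PositionCall(position=pos, status="untested", fold_change=float("nan"))
    return [calls[k] for k in sorted(calls)]


def variant_fold_changes(assay: AssayTable) -> dict[str, float]:
    return {vid: e.kd_nm / assay.wt_kd for vid, e in assay.entries.items()}


# ---------------------------------------------------------------------------
# consistency filtering

def filter_models(epitopes: Mapping[str, frozenset[ResidueKey] | set],
                  calls: Sequence[PositionCall],
                  sym: SymmetryMap | None = None,
                  strict_neutral: bool = True) -> list[str]:
    """Docking models consistent with the binding calls.

    A model passes iff it contacts every disrupted position (any symmetry-
    equivalent copy counts) and, when ``strict_neutral``, contacts no neutral
    position. Untested positions never constrain. An empty result is a valid
    outcome (all models refuted).
    """
    disrupted = [c.position for c in calls if c.status == "disrupted"]
    neutral = [c.position for c in calls if c.status == "neutral"]
    out = []
    for model_id in sorted(epitopes):
        epi = frozenset(epitopes[model_id])
        ok = all(contacts_under_symmetry(epi, p, sym) for p in disrupted)
        if ok and strict_neutral:
            ok = not any(contacts_under_symmetry(epi, p, sym) for p in neutral)
        if ok:
            out.append(model_id)
    return out


# ---------------------------------------------------------------------------
# interface energy surrogate

@dataclass(frozen=True)
class EnergyScore:
    model_id: str
    value: float
    source: Literal["builtin", "imported"]
    clash: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"{self.model_id}: energy must be finite")


# Lennard-Jones well parameters per element (sigma in A, epsilon in arbitrary
# energy units) and integer formal charges on charged side-chain termini.
_LJ_PARAMS = {"C": (3.40, 0.09), "N": (3.25, 0.17), "O": (2.96, 0.21),
              "S": (3.56, 0.25), "P": (3.74, 0.20)}
_LJ_DEFAULT = (3.40, 0.09)
_FORMAL_CHARGES = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
}
_PAIR_CUTOFF = 10.0
_CLASH_DISTANCE = 0.5


def pair_energy(r: float, sigma_i: float, eps_i: float, sigma_j: float, eps_j: float,
                q_i: float = 0.0, q_j: float = 0.0) -> float:
    """LJ (Lorentz-Berthelot mixing) + distance-dependent-dielectric Coulomb."""
    sigma = 0.5 * (sigma_i + sigma_j)
    eps = float(np.sqrt(eps_i * eps_j))
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6) + q_i * q_j / (4.0 * r * r)


def _atom_params(s: Structure, chain_ids: Iterable[str]):
    xyz, sigma, eps, charge = [], [], [], []
    for r in s.residues(sorted(chain_ids)):
        for a in r.atoms:
            sg, ep = _LJ_PARAMS.get(a.element.upper(), _LJ_DEFAULT)
            xyz.append(a.xyz)
            sigma.append(sg)
            eps.append(ep)
            charge.append(_FORMAL_CHARGES.get((r.name, a.name), 0.0))
    return (np.asarray(xyz), np.asarray(sigma), np.asarray(eps), np.asarray(charge))


def score_interface(model: Structure, part: ChainPartition,
                    scorer: Literal["builtin", "table"] = "builtin",
                    table: Mapping[str, float] | None = None,
                    pair_cutoff: float = _PAIR_CUTOFF) -> EnergyScore:
    """Cross-interface energy of a docked pose (lower = better).

    The builtin scorer sums a Lennard-Jones plus screened-Coulomb term over all
    cross-partition heavy-atom pairs within ``pair_cutoff``; it is a coarse
    stand-in for a minimized full-atom total energy, which can instead be
    supplied via ``table`` (model id -> energy).
    """
    if scorer == "table":
        if table is None or model.id not in table:
            raise KeyError(f"no imported energy for model {model.id!r}")
        return EnergyScore(model_id=model.id, value=float(table[model.id]), source="imported")
    part.validate(model)
    b_xyz, b_sig, b_eps, b_q = _atom_params(model, part.binder_chains)
    t_xyz, t_sig, t_eps, t_q = _atom_params(model, part.target_chains)
    tree = cKDTree(t_xyz)
    neighbours = tree.query_ball_point(b_xyz, r=pair_cutoff)
    total = 0.0
    clash = False
    for bi, hits in enumerate(neighbours):
        if not hits:
            continue
        hits = np.asarray(hits)
        r = np.linalg.norm(t_xyz[hits] - b_xyz[bi], axis=1)
        keep = r < pair_cutoff
        hits, r = hits[keep], r[keep]
        if r.size == 0:
            continue
        if np.any(r < _CLASH_DISTANCE):
            clash = True
            r = np.maximum(r, _CLASH_DISTANCE)
        sigma = 0.5 * (b_sig[bi] + t_sig[hits])
        eps = np.sqrt(b_eps[bi] * t_eps[hits])
        sr6 = (sigma / r) ** 6
        total += float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)
                              + b_q[bi] * t_q[hits] / (4.0 * r * r)))
    return EnergyScore(model_id=model.id, value=total, source="builtin", clash=clash)


def read_energy_table(path: str | Path) -> dict[str, float]:
    """TSV with columns model_id, energy."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"model_id": str})
    return {str(r.model_id): float(r.energy) for r in df.itertuples(index=False)}


# ---------------------------------------------------------------------------
# ranking

@dataclass(frozen=True)
class RankResult:
    order: tuple[str, ...]
    selected: str | None

    @property
    def no_consistent_model(self) -> bool:
        return self.selected is None


def rank_and_select(scores: Sequence[EnergyScore],
                    filtered: Iterable[str]) -> RankResult:
    """Ascending energy order over the filtered models; best is selected.

    Ties break lexicographically by model id so rankings are reproducible.
    """
    by_id = {s.model_id: s for s in scores}
    filtered = sorted(set(filtered))
    missing = [m for m in filtered if m not in by_id]
    if missing:
        raise KeyError(f"filtered models without scores: {missing}")
    order = tuple(sorted(filtered, key=lambda m: (by_id[m].value, m)))
    return RankResult(order=order, selected=order[0] if order else None)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks on ties); NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho is undefined", stacklevel=2)
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)
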