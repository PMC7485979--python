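"""Docking-model quality against a reference complex: f_nat, I-RMSD, recovery.

Conventions follow community assessment practice: native contacts at a 5 A
heavy-atom cutoff, interface residues at 10 A, and interface RMSD over
backbone atoms (N, CA, C, O) of the reference-defined interface residues
after optimal superposition on exactly those atoms. All cutoffs are exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .interface import ChainPartition, residue_contacts
from .structio import BACKBONE_ATOMS, ResidueKey, Structure, kabsch_superpose

DEFAULT_CONTACT_CUTOFF = 5.0
DEFAULT_IFACE_CUTOFF = 10.0


@dataclass(frozen=True)
class QualityMetrics:
    fnat: float
    irmsd: float
    interface_recovery: float

    def __post_init__(self) -> None:
        if not np.isnan(self.fnat) and not (0.0 <= self.fnat <= 1.0):
            raise ValueError(f"fnat {self.fnat} outside [0, 1]")
        if not np.isnan(self.interface_recovery) and not (0.0 <= self.interface_recovery <= 1.0):
            raise ValueError(f"interface_recovery {self.interface_recovery} outside [0, 1]")
        if self.irmsd < 0:
            raise ValueError("irmsd must be non-negative")


def fnat(model: Structure, reference: Structure, part: ChainPartition,
         cutoff: float = DEFAULT_CONTACT_CUTOFF) -> float:
    """Fraction of the reference's residue-residue contacts present in the model."""
    ref_pairs = residue_contacts(reference, part, cutoff).pairs
    if not ref_pairs:
        warnings.warn("reference has no contacts: fnat undefined", stacklevel=2)
        return float("nan")
    model_pairs = residue_contacts(model, part, cutoff).pairs
    return len(ref_pairs & model_pairs) / len(ref_pairs)


def _interface_residues(s: Structure, part: ChainPartition,
                        cutoff: float) -> frozenset[ResidueKey]:
    cs = residue_contacts(s, part, cutoff)
    return cs.binder_residues | cs.target_residues


def irmsd(model: Structure, reference: Structure, part: ChainPartition,
          iface_cutoff: float = DEFAULT_IFACE_CUTOFF) -> float:
    """Backbone RMSD over reference-defined interface residues, minimized.

    The residue set comes from the reference (any heavy atom within
    ``iface_cutoff`` across the partition), per assessment convention, so a
    model cannot shrink its own error by predicting a smaller interface.
    """
    iface = sorted(_interface_residues(reference, part, iface_cutoff))
    if len(iface) < 3:
        raise ValueError(f"only {len(iface)} interface residues; need at least 3")
    ref_coords, mod_coords = [], []
    for key in iface:
        ref_res = reference.residue(key)
        try:
            mod_res = model.residue(key)
        except KeyError:
            raise KeyError(f"interface residue {key} missing from model {model.id!r}") from None
        for name in BACKBONE_ATOMS:
            ra, ma = ref_res.atom(name), mod_res.atom(name)
            if ra is not None and ma is not None:
                ref_coords.append(ra.xyz)
                mod_coords.append(ma.xyz)
    sup = kabsch_superpose(np.asarray(ref_coords), np.asarray(mod_coords))
    return sup.rmsd


def interface_recovery(model: Structure, reference: Structure, part: ChainPartition,
                       cutoff: float = DEFAULT_CONTACT_CUTOFF) -> float:
    """Fraction of the model's predicted target-side interface that is correct."""
    predicted = residue_contacts(model, part, cutoff).target_residues
    if not predicted:
        warnings.warn("model predicts an empty interface: recovery undefined", stacklevel=2)
        return float("nan")
    native = residue_contacts(reference, part, cutoff).target_residues
    return len(predicted & native) / len(predicted)


def assess(model: Structure, reference: Structure, part: ChainPartition,
           contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
           iface_cutoff: float = DEFAULT_IFACE_CUTOFF) -> QualityMetrics:
    """All three quality metrics for one model against a reference complex."""
    return QualityMetrics(
        fnat=fnat(model, reference, part, contact_cutoff),
        irmsd=irmsd(model, reference, part, iface_cutoff),
        interface_recovery=interface_recovery(model, reference, part, contact_cutoff),
    )
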