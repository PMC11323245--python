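"""Geometric hydrogen-bond detection between migrating waters and protein.

A hydrogen bond is accepted when the donor-acceptor heavy-atom distance is
at most ``d_max`` (default 3.5 A, inclusive) and the angle at the hydrogen
vertex — between the acceptor heavy atom, the hydrogen, and the donor
heavy atom — lies in ``[angle_min, angle_max]`` (default [135, 180]
degrees, inclusive; a perfectly linear bond scores 180).

Donor/acceptor assignments follow Amber ff14SB atom naming.  Histidine
acceptors depend on the protonation-state residue name (HID/HIE/HIP); a
plain ``HIS`` is treated as the common epsilon tautomer HIE.

Partner protein atoms are classified as backbone or by side-chain
character (nonpolar / polar / positively or negatively charged residue).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sstats

__all__ = [
    "AtomRecord",
    "DonorAcceptorTable",
    "HBondCriteria",
    "HBond",
    "PartnerClass",
    "BACKBONE_ATOM_NAMES",
    "default_table",
    "detect_hbonds",
    "hbonds_at_minimal_sphere",
    "classify_partner",
    "correlate_radius_hbonds",
]

#: Atom names counted as backbone; everything else on a residue is side chain.
BACKBONE_ATOM_NAMES = frozenset(
    {"N", "CA", "C", "O", "OXT",
     "H", "H1", "H2", "H3", "HA", "HA2", "HA3"})

WATER_RESIDUES = frozenset({"WAT", "HOH", "TIP3", "SPC", "OPC"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom with residue identity and position (angstrom)."""

    atom_name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "position",
            np.asarray(self.position, dtype=float).reshape(3))

    @property
    def role(self) -> str:
        """``"backbone"`` or ``"sidechain"`` (by atom name)."""
        return "backbone" if self.atom_name in BACKBONE_ATOM_NAMES \
            else "sidechain"

    def key(self) -> tuple:
        return (self.chain_id, self.residue_id, self.atom_name)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance window for a hydrogen bond."""

    d_max: float = 3.5
    angle_min: float = 135.0
    angle_max: float = 180.0

    def __post_init__(self):
        if not self.d_max > 0:
            raise ValueError("d_max must be > 0")
        if not (0 <= self.angle_min <= self.angle_max <= 180):
            raise ValueError("require 0 <= angle_min <= angle_max <= 180")


@dataclass(frozen=True)
class HBond:
    """A detected hydrogen bond (vertex angle measured at the hydrogen)."""

    donor: AtomRecord
    hydrogen: AtomRecord
    acceptor: AtomRecord
    distance: float
    angle: float


@dataclass(frozen=True)
class ResidueTemplate:
    donors: Mapping[str, tuple[str, ...]]  # heavy atom -> bonded H names
    acceptors: frozenset[str]


def _t(donors: dict | None = None, acceptors: Sequence[str] = ()) -> ResidueTemplate:
    return ResidueTemplate(donors=dict(donors or {}),
                           acceptors=frozenset(acceptors))


_BB_DONOR = {"N": ("H", "H1", "H2", "H3")}
_BB_ACC = ("O", "OXT")


def _residue(donors: dict | None = None,
             acceptors: Sequence[str] = ()) -> ResidueTemplate:
    d = dict(_BB_DONOR)
    d.update(donors or {})
    return _t(d, tuple(_BB_ACC) + tuple(acceptors))


class DonorAcceptorTable:
    """Donor/acceptor atoms per residue template (ff14SB naming)."""

    def __init__(self, templates: Mapping[str, ResidueTemplate],
                 aliases: Mapping[str, str] | None = None):
        self._templates = dict(templates)
        self._aliases = dict(aliases or {})

    def get(self, residue_name: str) -> ResidueTemplate | None:
        name = self._aliases.get(residue_name, residue_name)
        return self._templates.get(name)

    def residues(self) -> list[str]:
        return sorted(self._templates)


def default_table() -> DonorAcceptorTable:
    templates = {
        "ALA": _residue(),
        "GLY": _residue(),
        "ILE": _residue(),
        "LEU": _residue(),
        "PRO": _t({}, _BB_ACC),  # no amide H
        "VAL": _residue(),
        "PHE": _residue(),
        "MET": _residue(),  # SD omitted: weak S acceptor not counted
        "TRP": _residue({"NE1": ("HE1",)}),
        "SER": _residue({"OG": ("HG",)}, ("OG",)),
        "THR": _residue({"OG1": ("HG1",)}, ("OG1",)),
        "CYS": _residue({"SG": ("HG",)}),
        "TYR": _residue({"OH": ("HH",)}, ("OH",)),
        "ASN": _residue({"ND2": ("HD21", "HD22")}, ("OD1",)),
        "GLN": _residue({"NE2": ("HE21", "HE22")}, ("OE1",)),
        "ASP": _residue({}, ("OD1", "OD2")),
        "GLU": _residue({}, ("OE1", "OE2")),
        "LYS": _residue({"NZ": ("HZ1", "HZ2", "HZ3")}),
        "ARG": _residue({"NE": ("HE",), "NH1": ("HH11", "HH12"),
                         "NH2": ("HH21", "HH22")}),
        "HID": _residue({"ND1": ("HD1",)}, ("NE2",)),
        "HIE": _residue({"NE2": ("HE2",)}, ("ND1",)),
        "HIP": _residue({"ND1": ("HD1",), "NE2": ("HE2",)}),
        "WAT": _t({"O": ("H1", "H2")}, ("O",)),
    }
    aliases = {"HIS": "HIE", "HOH": "WAT", "TIP3": "WAT", "OPC": "WAT",
               "ASH": "ASP", "GLH": "GLU", "LYN": "LYS", "CYX": "CYS",
               "CYM": "CYS"}
    return DonorAcceptorTable(templates, aliases)


def hbond_angle(donor_pos, hydrogen_pos, acceptor_pos) -> float:
    """Angle in degrees at the hydrogen, between acceptor and donor."""
    h = np.asarray(hydrogen_pos, dtype=float)
    v1 = np.asarray(donor_pos, dtype=float) - h
    v2 = np.asarray(acceptor_pos, dtype=float) - h
    cosang = float(np.dot(v1, v2) /
                   (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _passes(criteria: HBondCriteria, distance: float, angle: float) -> bool:
    return (distance <= criteria.d_max
            and criteria.angle_min <= angle <= criteria.angle_max)


def _split_water(water_atoms: Sequence[AtomRecord]):
    oxygens = [a for a in water_atoms if a.element.upper() == "O"]
    hydrogens = [a for a in water_atoms if a.element.upper() == "H"]
    if len(oxygens) != 1:
        raise ValueError("water must have exactly one oxygen")
    if len(hydrogens) < 2:
        raise ValueError("water must carry explicit hydrogens (two expected)")
    return oxygens[0], hydrogens


def detect_hbonds(water_atoms: Sequence[AtomRecord],
                  protein_atoms: Sequence[AtomRecord],
                  table: DonorAcceptorTable | None = None,
                  criteria: HBondCriteria | None = None) -> list[HBond]:
    """Find all water-protein hydrogen bonds in one frame.

    Both directions are counted: water as donor (via its two hydrogens
    toward protein acceptors) and water as acceptor (from protein donor
    groups).  Each (donor, hydrogen, acceptor) triple is reported once;
    the same heavy-atom pair reached through different hydrogens yields
    distinct bonds.

    Protein atoms from residues absent from the donor/acceptor table are
    skipped with a warning; heavy atoms that are neither donor nor
    acceptor in their template simply do not participate.
    """
    table = table or default_table()
    criteria = criteria or HBondCriteria()
    water_o, water_hs = _split_water(water_atoms)

    # index protein hydrogens by (chain, residue) for donor lookup
    by_residue: dict[tuple, dict[str, AtomRecord]] = {}
    unknown: set[str] = set()
    for atom in protein_atoms:
        if table.get(atom.residue_name) is None:
            unknown.add(atom.residue_name)
            continue
        by_residue.setdefault((atom.chain_id, atom.residue_id),
                              {})[atom.atom_name] = atom
    for name in sorted(unknown):
        warnings.warn(f"residue {name!r} not in donor/acceptor table; "
                      "its atoms are skipped", stacklevel=2)

    bonds: list[HBond] = []
    for atoms in by_residue.values():
        template = None
        for atom in atoms.values():
            template = table.get(atom.residue_name)
            break
        if template is None:  # pragma: no cover
            continue
        for name, atom in atoms.items():
            # water as donor -> protein acceptor
            if name in template.acceptors:
                d = float(np.linalg.norm(atom.position - water_o.position))
                if d <= criteria.d_max:
                    for wh in water_hs:
                        ang = hbond_angle(water_o.position, wh.position,
                                          atom.position)
                        if _passes(criteria, d, ang):
                            bonds.append(HBond(water_o, wh, atom, d, ang))
            # protein donor -> water as acceptor
            if name in template.donors:
                d = float(np.linalg.norm(atom.position - water_o.position))
                if d <= criteria.d_max:
                    for h_name in template.donors[name]:
                        h_atom = atoms.get(h_name)
                        if h_atom is None:
                            continue
                        ang = hbond_angle(atom.position, h_atom.position,
                                          water_o.position)
                        if _passes(criteria, d, ang):
                            bonds.append(HBond(atom, h_atom, water_o, d, ang))
    bonds.sort(key=lambda b: (b.donor.key(), b.hydrogen.key(),
                              b.acceptor.key()))
    return bonds


def hbonds_at_minimal_sphere(event, mes,
                             frame_atoms: Mapping[int, tuple],
                             table: DonorAcceptorTable | None = None,
                             criteria: HBondCriteria | None = None,
                             ) -> tuple[list[int], dict[int, list[HBond]]]:
    """Water-protein H-bonds at every minimal-event-sphere frame.

    ``frame_atoms`` maps frame id to ``(water_atoms, protein_atoms)`` for
    that frame.  Returns the per-frame bond counts (one per minimal frame,
    in frame order — the distribution, not a single summary) and the bond
    lists keyed by frame.
    """
    counts: list[int] = []
    per_frame: dict[int, list[HBond]] = {}
    for frame in mes.minimal_frames:
        frame = int(frame)
        if frame not in frame_atoms:
            raise ValueError(
                f"no atom coordinates for minimal frame {frame} "
                f"of event {mes.event_id}")
        water_atoms, protein_atoms = frame_atoms[frame]
        found = detect_hbonds(water_atoms, protein_atoms, table, criteria)
        per_frame[frame] = found
        counts.append(len(found))
    return counts, per_frame


class PartnerClass(str, Enum):
    """Classification of the protein atom H-bonded to a migrating water."""

    BACKBONE = "backbone"
    SIDECHAIN_NONPOLAR = "sidechain_nonpolar"
    SIDECHAIN_POLAR = "sidechain_polar"
    SIDECHAIN_POSITIVE = "sidechain_positive"
    SIDECHAIN_NEGATIVE = "sidechain_negative"


_NONPOLAR = {"ALA", "GLY", "ILE", "LEU", "MET", "PHE", "PRO", "TRP", "VAL"}
_POLAR = {"ASN", "CYS", "GLN", "SER", "THR", "TYR"}
_POSITIVE = {"ARG", "HIS", "LYS"}
_NEGATIVE = {"ASP", "GLU"}
_RESIDUE_ALIASES = {"HID": "HIS", "HIE": "HIS", "HIP": "HIS",
                    "ASH": "ASP", "GLH": "GLU", "LYN": "LYS",
                    "CYX": "CYS", "CYM": "CYS"}


def classify_partner(atom: AtomRecord) -> PartnerClass:
    """Classify a protein H-bond partner atom.

    Backbone atoms are ``backbone`` regardless of residue; side-chain
    atoms take their residue's character (nonpolar, polar, positively or
    negatively charged).  The four residue sets partition the 20 standard
    amino acids; Amber protonation-state names map to their parent.
    """
    res = _RESIDUE_ALIASES.get(atom.residue_name, atom.residue_name)
    if res not in (_NONPOLAR | _POLAR | _POSITIVE | _NEGATIVE):
        raise ValueError(f"nonstandard residue {atom.residue_name!r}: "
                         "expected one of the 20 standard amino acids")
    if atom.role == "backbone":
        return PartnerClass.BACKBONE
    if res in _NONPOLAR:
        return PartnerClass.SIDECHAIN_NONPOLAR
    if res in _POLAR:
        return PartnerClass.SIDECHAIN_POLAR
    if res in _POSITIVE:
        return PartnerClass.SIDECHAIN_POSITIVE
    return PartnerClass.SIDECHAIN_NEGATIVE


def correlate_radius_hbonds(pairs: Sequence[tuple[float, float]]
                            ) -> tuple[float, float]:
    """Spearman rank correlation between minimal radius and H-bond count.

    ``pairs`` holds one ``(minimal_radius, mean_bond_count)`` tuple per
    event.  Returns ``(rho, p_value)`` with the two-sided p-value from
    the asymptotic t approximation.  A negative rho means waters form
    more hydrogen bonds in tighter constrictions.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (radius, count) pairs")
    radii, counts = arr[:, 0], arr[:, 1]
    if np.all(radii == radii[0]) or np.all(counts == counts[0]):
        raise ValueError("correlation undefined for constant input")
    res = _sstats.spearmanr(radii, counts)
    return float(res.statistic), float(res.pvalue)
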