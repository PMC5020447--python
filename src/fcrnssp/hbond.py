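"""Distance-based hydrogen-bond contact detection and MM/MH tallies.

Putative hydrogen bonds are inferred purely from geometry: any pair of
polar atoms (N or O, including water oxygens) whose centres lie within
a donor-acceptor cutoff (3.6 A by default) counts as a contact, with
donor/acceptor roles deliberately ignored.  Pairs within one residue
and the covalent backbone O(i)-N(i+1) peptide pair are excluded.  Each
atom is classed as main-chain (M: backbone N, O, OXT of a standard
residue), polar side-chain (S), or water (H, for hetero), giving pair
categories MM, MH, MS, SS, SH; anything else (e.g. water-water,
non-water hetero) is 'other'.

For prediction analysis, residues observed as Coil or Sheet are binned
by outcome R_ij (observed i, predicted j; i, j in {C, E}) and their
main-chain contacts tallied: the MM vs MH split per outcome category
asks whether mispredicted coils sit in backbone-bonded environments
while correctly predicted ones are water-coordinated.

The angular criteria of full hydrogen-bond assignment programs are out
of scope; this is the distance-only criterion, so absolute counts are
not comparable with angular-filtered tools.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "HBondContact",
    "ContactTally",
    "read_pdb",
    "find_contacts",
    "tally_by_outcome",
    "DEFAULT_CUTOFF",
    "WATER_RESNAMES",
    "MAINCHAIN_ATOMS",
]

DEFAULT_CUTOFF = 3.6
WATER_RESNAMES = {"HOH", "WAT", "DOD"}
MAINCHAIN_ATOMS = {"N", "O", "OXT"}
_POLAR_ELEMENTS = {"N", "O"}

OUTCOME_CATEGORIES = ("R_CC", "R_CE", "R_EC", "R_EE")


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure, with enough identity for contact typing."""

    chain: str
    res_seq: int
    res_name: str
    name: str
    element: str
    pos: tuple[float, float, float]
    hetero: bool

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_RESNAMES

    @property
    def is_polar(self) -> bool:
        return self.element in _POLAR_ELEMENTS

    @property
    def role(self) -> str | None:
        """'M' (main chain), 'S' (polar side chain), 'H' (water), or None."""
        if not self.is_polar:
            return None
        if self.is_water:
            return "H"
        if self.hetero:
            return None  # non-water hetero polar atom: uncategorized
        return "M" if self.name in MAINCHAIN_ATOMS else "S"

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain, self.res_seq)


@dataclass(frozen=True)
class HBondContact:
    """An unordered polar-atom pair within the distance cutoff."""

    a: AtomRecord
    b: AtomRecord
    distance: float
    category: str  # MM | MH | MS | SS | SH | other


def read_pdb(path: str | Path) -> list[AtomRecord]:
    """Read ATOM/HETATM records of a PDB file into AtomRecord entries.

    Alternate locations are resolved to the highest-occupancy conformer
    per (residue, atom name); ties keep the first occurring.
    """
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: cannot parse PDB file: {exc}") from None
    if len(structure) == 0:
        raise ValueError(f"{path}: structure has no models")
    model = structure[0]

    records: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            # altloc resolution: best occupancy per atom name, first on ties
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                records.append(
                    AtomRecord(
                        chain=chain.name,
                        res_seq=res.seqid.num,
                        res_name=res.name.strip(),
                        name=atom.name.strip(),
                        element=atom.element.name.upper(),
                        pos=(atom.pos.x, atom.pos.y, atom.pos.z),
                        hetero=res.het_flag == "H",
                    )
                )
    return records


def _pair_category(a: AtomRecord, b: AtomRecord) -> str:
    roles = {a.role, b.role}
    if None in roles:
        return "other"
    if roles == {"M"}:
        return "MM"
    if roles == {"M", "H"}:
        return "MH"
    if roles == {"M", "S"}:
        return "MS"
    if roles == {"S"}:
        return "SS"
    if roles == {"S", "H"}:
        return "SH"
    return "other"  # water-water and anything else


def find_contacts(
    atoms: Sequence[AtomRecord], cutoff: float = DEFAULT_CUTOFF
) -> list[HBondContact]:
    """All polar-atom pairs within ``cutoff`` angstroms.

    Same-residue pairs and the sequential-backbone O(i)-N(i+1) peptide
    pair are excluded.  Neighbour search uses a k-d tree; results are
    identical to the all-pairs scan.
    """
    if not atoms:
        raise ValueError("empty structure")
    polar = [a for a in atoms if a.is_polar]
    if len(polar) < 2:
        return []
    coords = np.array([a.pos for a in polar])
    tree = cKDTree(coords)
    contacts: list[HBondContact] = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        a, b = polar[i], polar[j]
        if a.residue_key == b.residue_key:
            continue
        if _is_peptide_neighbour_pair(a, b):
            continue
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        contacts.append(HBondContact(a, b, dist, _pair_category(a, b)))
    return contacts


def _is_peptide_neighbour_pair(a: AtomRecord, b: AtomRecord) -> bool:
    """True for the covalently constrained backbone O(i)..N(i+1) pair."""
    if a.chain != b.chain or a.hetero or b.hetero:
        return False
    for x, y in ((a, b), (b, a)):
        if x.name == "O" and y.name == "N" and y.res_seq == x.res_seq + 1:
            return True
    return False


@dataclass(frozen=True)
class CategoryTally:
    mm: int
    mh: int
    all_bonds: int
    n_residues: int

    @property
    def mm_mh(self) -> int:
        return self.mm + self.mh

    @property
    def frac_mm(self) -> float | None:
        return None if self.mm_mh == 0 else 100.0 * self.mm / self.mm_mh

    @property
    def frac_mh(self) -> float | None:
        return None if self.mm_mh == 0 else 100.0 * self.mh / self.mm_mh


@dataclass(frozen=True)
class ContactTally:
    """Per-outcome-category (R_CC, R_CE, R_EC, R_EE) contact counts."""

    categories: Mapping[str, CategoryTally]

    def __getitem__(self, key: str) -> CategoryTally:
        return self.categories[key]


def tally_by_outcome(
    contacts: Sequence[HBondContact],
    observed: str,
    predicted: str,
    residue_map: Mapping[tuple[str, int], int],
) -> ContactTally:
    """Cross-tabulate main-chain contacts by prediction outcome.

    ``residue_map`` maps (chain, residue number) to a position in the
    observed/predicted strings.  For every scored residue observed as C
    or E and predicted as C or E, each contact endpoint contributes:
    MM when the residue's main-chain atom partners another main-chain
    atom, MH when it partners a water oxygen.  ``all_bonds`` counts
    every contact touching any atom of the residue, and ``n_residues``
    the residues of the category with at least one contact of any kind.
    Counting is per residue endpoint, so a contact between two scored
    residues contributes to both.
    """
    if len(observed) != len(predicted):
        raise ValueError("observed and predicted strings differ in length")
    for key, pos in residue_map.items():
        if not 0 <= pos < len(observed):
            raise ValueError(
                f"residue {key} maps to position {pos}, outside the "
                f"strings of length {len(observed)}"
            )

    def outcome(key: tuple[str, int]) -> str | None:
        pos = residue_map.get(key)
        if pos is None:
            return None
        o, p = observed[pos], predicted[pos]
        if o in "CE" and p in "CE":
            return f"R_{o}{p}"
        return None

    mm = defaultdict(int)
    mh = defaultdict(int)
    all_bonds = defaultdict(int)
    touched: dict[str, set[tuple[str, int]]] = defaultdict(set)

    for contact in contacts:
        for atom, partner in ((contact.a, contact.b), (contact.b, contact.a)):
            cat = outcome(atom.residue_key)
            if cat is None:
                continue
            all_bonds[cat] += 1
            touched[cat].add(atom.residue_key)
            if atom.role == "M":
                if partner.role == "M":
                    mm[cat] += 1
                elif partner.role == "H":
                    mh[cat] += 1

    return ContactTally(
        {
            cat: CategoryTally(
                mm=mm[cat],
                mh=mh[cat],
                all_bonds=all_bonds[cat],
                n_residues=len(touched[cat]),
            )
            for cat in OUTCOME_CATEGORIES
        }
    )
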