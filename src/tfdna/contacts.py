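"""Polar-contact detection and apo/bound interface restructuring accounting.

Hydrogen bonds are inferred from heavy-atom donor/acceptor geometry alone
(distance cutoff, default 3.5 Å, no angular term) because the structures
this package targets are low-resolution crystal structures without modelled
hydrogens.  Donor/acceptor assignments come from fixed chemical dictionaries
for the 20 amino acids and the 4 deoxynucleotides; His/Asn/Gln amide and
imidazole atoms are treated as both donor and acceptor, reflecting their
crystallographic ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .bases import nucleotide_code
from .structure import Atom, Structure

DEFAULT_HBOND_CUTOFF = 3.5  # Å, heavy-atom donor-acceptor
DEFAULT_CONTACT_CUTOFF = 3.9  # Å, looser count including non-polar packing
STACKING_CENTROID_CUTOFF = 5.5  # Å, aromatic ring centroid separation

# --- protein chemistry ------------------------------------------------------

_AMBIGUOUS = {
    "HIS": ("ND1", "NE2"),
    "ASN": ("OD1", "ND2"),
    "GLN": ("OE1", "NE2"),
}

PROTEIN_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "ASN": ("ND2", "OD1"),
    "GLN": ("NE2", "OE1"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "TRP": ("NE1",),
    "CYS": ("SG",),
}

PROTEIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1", "ND2"),
    "GLN": ("OE1", "NE2"),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
    "MET": ("SD",),
}

AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

# --- DNA chemistry ----------------------------------------------------------

DNA_BASE_DONORS: dict[str, tuple[str, ...]] = {
    "A": ("N6",),
    "G": ("N1", "N2"),
    "C": ("N4",),
    "T": ("N3",),
}

DNA_BASE_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "A": ("N1", "N3", "N7"),
    "G": ("O6", "N3", "N7"),
    "C": ("O2", "N3"),
    "T": ("O2", "O4"),
}

DNA_BACKBONE_ACCEPTORS = ("OP1", "OP2", "OP3", "O5'", "O3'", "O4'")

BACKBONE_ATOM_NAMES = frozenset({"P", "OP1", "OP2", "OP3"})

AROMATIC_RINGS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}


def _is_protein(atom: Atom) -> bool:
    return atom.residue_name in AMINO_ACIDS


def _is_dna(atom: Atom) -> bool:
    return nucleotide_code(atom.residue_name) is not None


def is_backbone_dna_atom(atom_name: str) -> bool:
    """Sugar (primed) and phosphate atoms count as backbone."""
    name = atom_name.replace("′", "'")
    return "'" in name or name in BACKBONE_ATOM_NAMES


def atom_is_donor(atom: Atom) -> bool:
    if _is_protein(atom):
        if atom.atom_name == "N":  # backbone amide
            return atom.residue_name != "PRO"
        return atom.atom_name in PROTEIN_DONORS.get(atom.residue_name, ())
    code = nucleotide_code(atom.residue_name)
    if code is not None:
        return not is_backbone_dna_atom(atom.atom_name) and atom.atom_name in DNA_BASE_DONORS[code]
    return False


def atom_is_acceptor(atom: Atom) -> bool:
    if _is_protein(atom):
        if atom.atom_name in ("O", "OXT"):  # backbone carbonyl
            return True
        return atom.atom_name in PROTEIN_ACCEPTORS.get(atom.residue_name, ())
    code = nucleotide_code(atom.residue_name)
    if code is not None:
        if atom.atom_name in DNA_BACKBONE_ACCEPTORS:
            return True
        return atom.atom_name in DNA_BASE_ACCEPTORS[code]
    return False


# ---------------------------------------------------------------------------


AtomKey = tuple[str, int, str, str]  # chain, residue number, insertion code, atom name


def atom_key(atom: Atom) -> AtomKey:
    return (atom.chain_id, atom.residue_number, atom.insertion_code, atom.atom_name)


@dataclass
class HBond:
    donor: Atom
    acceptor: Atom
    distance: float
    category: str  # protein-DNA-base | protein-DNA-backbone | protein-protein | other

    @property
    def pair_id(self) -> tuple[AtomKey, AtomKey]:
        return tuple(sorted([atom_key(self.donor), atom_key(self.acceptor)]))  # type: ignore[return-value]


@dataclass
class StackingContact:
    protein_residue: tuple[str, int]
    dna_residue: tuple[str, int]
    centroid_distance: float
    flag: str = "stacking"


@dataclass
class InterfaceDiff:
    """Disrupted/formed/retained polar-contact accounting between two states.

    Each record is ``(pair_id, apo_distance, bound_distance)``; distances are
    reported in both states even when beyond the cutoff (None when an atom is
    absent from that state).
    """

    disrupted: list[tuple] = field(default_factory=list)
    formed: list[tuple] = field(default_factory=list)
    retained: list[tuple] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "disrupted": len(self.disrupted),
            "formed": len(self.formed),
            "retained": len(self.retained),
        }


@dataclass
class Selection:
    """A named set of chains, optionally restricted to a residue range."""

    chains: tuple[str, ...]
    residue_range: tuple[int, int] | None = None

    def atoms(self, structure: Structure) -> list[Atom]:
        out: list[Atom] = []
        for cid in self.chains:
            for res in structure.chain(cid).residues:
                if res.is_water:
                    continue
                if self.residue_range is not None:
                    lo, hi = self.residue_range
                    if not lo <= res.number <= hi:
                        continue
                out.extend(a for a in res.atoms if a.element != "H")
        return out


def _categorize(a: Atom, b: Atom) -> str:
    if _is_protein(a) and _is_protein(b):
        return "protein-protein"
    prot, other = (a, b) if _is_protein(a) else (b, a)
    if _is_protein(prot) and _is_dna(other):
        return (
            "protein-DNA-backbone"
            if is_backbone_dna_atom(other.atom_name)
            else "protein-DNA-base"
        )
    return "other"


def find_polar_contacts(
    structure: Structure,
    selection_1: Selection | list[Atom],
    selection_2: Selection | list[Atom],
    cutoff: float = DEFAULT_HBOND_CUTOFF,
) -> list[HBond]:
    """All donor/acceptor heavy-atom pairs across two disjoint selections
    within the cutoff."""
    atoms_1 = selection_1.atoms(structure) if isinstance(selection_1, Selection) else selection_1
    atoms_2 = selection_2.atoms(structure) if isinstance(selection_2, Selection) else selection_2
    if not atoms_1 or not atoms_2:
        raise ValueError("both selections must be non-empty")
    keys_1 = {atom_key(a) for a in atoms_1}
    overlap = keys_1 & {atom_key(a) for a in atoms_2}
    if overlap:
        raise ValueError(f"selections overlap on {len(overlap)} atoms, e.g. {sorted(overlap)[0]}")

    pos_2 = np.array([a.position for a in atoms_2])
    tree = cKDTree(pos_2)
    bonds: dict[tuple[AtomKey, AtomKey], HBond] = {}
    for a1 in atoms_1:
        if a1.is_water:
            continue
        d1, acc1 = atom_is_donor(a1), atom_is_acceptor(a1)
        if not (d1 or acc1):
            continue
        for j in tree.query_ball_point(a1.position, cutoff):
            a2 = atoms_2[j]
            if a2.is_water:
                continue
            dist = float(np.linalg.norm(a1.position - a2.position))
            if dist > cutoff:
                continue
            if d1 and atom_is_acceptor(a2):
                donor, acceptor = a1, a2
            elif acc1 and atom_is_donor(a2):
                donor, acceptor = a2, a1
            else:
                continue
            hb = HBond(donor, acceptor, dist, _categorize(a1, a2))
            bonds.setdefault(hb.pair_id, hb)
    return sorted(bonds.values(), key=lambda h: h.pair_id)


def find_nonpolar_contacts(
    structure: Structure,
    selection_1: Selection | list[Atom],
    selection_2: Selection | list[Atom],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[tuple[Atom, Atom, float]]:
    """All heavy-atom pairs (any chemistry) across two selections within the
    cutoff — the loose 'contacts' count that includes van der Waals packing.
    Never reported as hydrogen bonds."""
    atoms_1 = selection_1.atoms(structure) if isinstance(selection_1, Selection) else selection_1
    atoms_2 = selection_2.atoms(structure) if isinstance(selection_2, Selection) else selection_2
    pos_2 = np.array([a.position for a in atoms_2])
    tree = cKDTree(pos_2)
    out = []
    for a1 in atoms_1:
        if a1.is_water:
            continue
        for j in tree.query_ball_point(a1.position, cutoff):
            a2 = atoms_2[j]
            if a2.is_water:
                continue
            out.append((a1, a2, float(np.linalg.norm(a1.position - a2.position))))
    return out


def classify_dna_contacts(
    contacts: list, structure: Structure | None = None
) -> tuple[dict[str, int], dict[tuple[str, str, int], dict[str, int]]]:
    """Split protein-DNA contacts into base vs backbone totals and a
    per-protein-residue breakdown.

    Accepts HBond objects or ``(atom, atom, distance)`` tuples (the loose
    contact list).
    """
    totals = {"base": 0, "backbone": 0}
    per_residue: dict[tuple[str, str, int], dict[str, int]] = {}
    for c in contacts:
        pair = (c.donor, c.acceptor) if isinstance(c, HBond) else (c[0], c[1])
        prot = [a for a in pair if _is_protein(a)]
        dna = [a for a in pair if _is_dna(a)]
        if len(prot) != 1 or len(dna) != 1:
            raise ValueError(
                "classify_dna_contacts requires one protein and one DNA atom per contact"
            )
        kind = "backbone" if is_backbone_dna_atom(dna[0].atom_name) else "base"
        totals[kind] += 1
        key = (prot[0].chain_id, prot[0].residue_name, prot[0].residue_number)
        per_residue.setdefault(key, {"base": 0, "backbone": 0})[kind] += 1
    return totals, per_residue


def detect_stacking(
    structure: Structure,
    protein_selection: Selection,
    dna_selection: Selection,
    cutoff: float = STACKING_CENTROID_CUTOFF,
) -> list[StackingContact]:
    """Aromatic-ring / nucleobase centroid proximity, flagged 'stacking';
    excluded from all hydrogen-bond counts."""
    from .bases import RING_ATOMS

    def centroid(res, names):
        pts = [res.atom(n).position for n in names if res.has_atom(n)]
        if len(pts) < len(names) - 1:
            return None
        return np.mean(pts, axis=0)

    prot_rings = []
    for cid in protein_selection.chains:
        for res in structure.chain(cid).residues:
            names = AROMATIC_RINGS.get(res.name)
            if names:
                c = centroid(res, names)
                if c is not None:
                    prot_rings.append(((cid, res.number), c))
    out: list[StackingContact] = []
    for cid in dna_selection.chains:
        for res in structure.chain(cid).residues:
            code = nucleotide_code(res.name)
            if code is None:
                continue
            c = centroid(res, RING_ATOMS[code])
            if c is None:
                continue
            for pid, pc in prot_rings:
                d = float(np.linalg.norm(pc - c))
                if d <= cutoff:
                    out.append(StackingContact(pid, (cid, res.number), d))
    return out


# ---------------------------------------------------------------------------
# apo vs bound diff


def _pair_distance(structure: Structure, key_a: AtomKey, key_b: AtomKey) -> float | None:
    try:
        a = structure.atom(key_a[0], key_a[1], key_a[3], key_a[2])
        b = structure.atom(key_b[0], key_b[1], key_b[3], key_b[2])
    except KeyError:
        return None
    return float(np.linalg.norm(a.position - b.position))


def diff_interface(
    apo: Structure,
    bound: Structure,
    chain_map: dict[str, str],
    selection_1: Selection,
    selection_2: Selection,
    cutoff: float = DEFAULT_HBOND_CUTOFF,
) -> InterfaceDiff:
    """Disrupted / formed / retained polar contacts between two states.

    ``chain_map`` sends apo chain ids to bound chain ids; selections are
    expressed in bound naming.  Bonds are keyed by (residue, atom-name)
    pairs after mapping; a pair within the cutoff in apo only is disrupted,
    in bound only formed, in both retained.  Distances in both states are
    reported even beyond the cutoff.
    """
    bound_chain_ids = {c.chain_id for c in bound.chains}
    bad = [f"{a}->{b}" for a, b in chain_map.items() if b not in bound_chain_ids]
    missing = [c.chain_id for c in apo.chains if c.chain_id not in chain_map]
    if bad or missing:
        raise ValueError(
            f"unmappable chains: targets missing in bound {bad}; apo chains without mapping {missing}"
        )
    inverse = {b: a for a, b in chain_map.items()}

    def to_apo(sel: Selection) -> Selection:
        try:
            return Selection(
                chains=tuple(inverse[c] for c in sel.chains),
                residue_range=sel.residue_range,
            )
        except KeyError as exc:
            raise ValueError(f"selection chain {exc.args[0]!r} has no apo counterpart") from exc

    def mapped_key(key: AtomKey, mapping: dict[str, str]) -> AtomKey:
        return (mapping[key[0]], key[1], key[2], key[3])

    apo_bonds = {
        tuple(sorted([mapped_key(atom_key(h.donor), chain_map),
                      mapped_key(atom_key(h.acceptor), chain_map)])): h
        for h in find_polar_contacts(apo, to_apo(selection_1), to_apo(selection_2), cutoff)
    }
    bound_bonds = {
        h.pair_id: h
        for h in find_polar_contacts(bound, selection_1, selection_2, cutoff)
    }

    diff = InterfaceDiff()
    for pid, h in sorted(apo_bonds.items()):
        ka, kb = pid
        if pid in bound_bonds:
            diff.retained.append((pid, h.distance, bound_bonds[pid].distance))
        else:
            d_bound = _pair_distance(bound, ka, kb)
            diff.disrupted.append((pid, h.distance, d_bound))
    for pid, h in sorted(bound_bonds.items()):
        if pid not in apo_bonds:
            ka, kb = pid
            ka_apo = (inverse[ka[0]], ka[1], ka[2], ka[3]) if ka[0] in inverse else ka
            kb_apo = (inverse[kb[0]], kb[1], kb[2], kb[3]) if kb[0] in inverse else kb
            d_apo = _pair_distance(apo, ka_apo, kb_apo)
            diff.formed.append((pid, d_apo, h.distance))
    return diff


def center_to_center(
    structure: Structure,
    atom_ref_1: tuple[str, int, str],
    atom_ref_2: tuple[str, int, str],
) -> float:
    """Euclidean distance between two named atoms, e.g. the recognition-helix
    G44 amide nitrogens of the two monomers of a homodimer."""
    try:
        a = structure.atom(atom_ref_1[0], atom_ref_1[1], atom_ref_1[2])
    except KeyError:
        raise ValueError(f"atom not found: {atom_ref_1}") from None
    try:
        b = structure.atom(atom_ref_2[0], atom_ref_2[1], atom_ref_2[2])
    except KeyError:
        raise ValueError(f"atom not found: {atom_ref_2}") from None
    return float(np.linalg.norm(a.position - b.position))
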