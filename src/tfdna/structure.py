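"""Coordinate-file I/O and a light hierarchical structure model.

PDB parsing is delegated to gemmi; the model exposed to the rest of the
package is a plain chains -> residues -> atoms hierarchy carrying only what
the geometric analyses need (names, elements, coordinates in Å, occupancy,
B-factor).  Alternate locations are resolved at read time: the highest
occupancy conformer wins, ties broken by file order.  Waters are retained
but flagged so geometry operators can ignore them.

Writing uses fixed-width PDB ATOM/HETATM records; a written file re-read and
re-written is byte-identical over the ATOM block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .bases import PURINES, COMPLEMENT, is_nucleotide, nucleotide_code

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

# Watson-Crick detection thresholds (heavy atoms, Å)
C1_C1_RANGE = (8.9, 11.9)
GLYCOSIDIC_HBOND_MAX = 3.5


class FormatError(ValueError):
    """Malformed or unsupported coordinate file content."""


@dataclass
class Atom:
    """One heavy (or hydrogen) atom with PDB-style identity."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.atom_name}: position must be a finite 3-vector")
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        # normalize typographic primes to ASCII
        self.atom_name = self.atom_name.replace("′", "'")

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES


@dataclass
class Residue:
    chain_id: str
    number: int
    insertion_code: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        name = name.replace("′", "'")
        for a in self.atoms:
            if a.atom_name == name:
                return a
        raise KeyError(
            f"atom {name!r} not found in {self.chain_id}/{self.name}{self.number}"
        )

    def has_atom(self, name: str) -> bool:
        name = name.replace("′", "'")
        return any(a.atom_name == name for a in self.atoms)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def is_nucleotide(self) -> bool:
        return is_nucleotide(self.name)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Residue {self.chain_id}/{self.name}{self.number}{self.insertion_code.strip()}>"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int, insertion_code: str = "") -> Residue:
        for r in self.residues:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        raise KeyError(f"residue {number}{insertion_code} not in chain {self.chain_id}")

    @property
    def nucleotides(self) -> list[Residue]:
        return [r for r in self.residues if r.is_nucleotide]


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in structure {self.id!r}")

    def iter_atoms(self):
        for c in self.chains:
            for r in c.residues:
                yield from r.atoms

    def iter_residues(self):
        for c in self.chains:
            yield from c.residues

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def atom(self, chain_id: str, residue_number: int, atom_name: str,
             insertion_code: str = "") -> Atom:
        try:
            return self.chain(chain_id).residue(residue_number, insertion_code).atom(atom_name)
        except KeyError as exc:
            raise KeyError(
                f"atom {chain_id}/{residue_number}{insertion_code}/{atom_name} not found"
            ) from exc

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid-body copy: x -> R x + t for every atom."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        out = Structure(id=self.id)
        for c in self.chains:
            nc = Chain(chain_id=c.chain_id)
            for r in c.residues:
                nr = Residue(r.chain_id, r.number, r.insertion_code, r.name)
                for a in r.atoms:
                    nr.atoms.append(
                        Atom(a.chain_id, a.residue_number, a.insertion_code,
                             a.residue_name, a.atom_name, a.element,
                             R @ a.position + t, a.occupancy, a.b_factor, a.is_hetero)
                    )
                nc.residues.append(nr)
            out.chains.append(nc)
        return out


@dataclass
class BasePair:
    """One base pair (or unpaired overhang) of a duplex."""

    residue_I: Residue | None
    residue_II: Residue | None
    pair_type: str  # "watson-crick" | "noncanonical" | "overhang"

    @property
    def is_watson_crick(self) -> bool:
        return self.pair_type == "watson-crick"


# ---------------------------------------------------------------------------
# reading


def read_structure(path: str | Path, model_index: int = 0) -> Structure:
    """Read a PDB file into a Structure.

    Only the model selected by ``model_index`` (default: first) is loaded.
    Alternate locations are collapsed to the highest-occupancy conformer
    (ties: first in file).  Hydrogens and waters are kept.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models / no ATOM records")
    if not 0 <= model_index < len(st):
        raise IndexError(f"model_index {model_index} out of range (file has {len(st)})")
    model = st[model_index]

    out = Structure(id=st.name or path.stem)
    n_atoms = 0
    for gchain in model:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            res = Residue(
                chain_id=gchain.name,
                number=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                name=gres.name.strip(),
            )
            # altloc groups keyed by atom name, resolved by occupancy
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for ga in gres:
                if ga.name not in best:
                    best[ga.name] = ga
                    order.append(ga.name)
                elif ga.occ > best[ga.name].occ:
                    best[ga.name] = ga
            for name in order:
                ga = best[name]
                res.atoms.append(
                    Atom(
                        chain_id=gchain.name,
                        residue_number=res.number,
                        insertion_code=res.insertion_code,
                        residue_name=res.name,
                        atom_name=ga.name,
                        element=ga.element.name,
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        b_factor=ga.b_iso,
                        is_hetero=gres.het_flag == "H",
                    )
                )
                n_atoms += 1
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            out.chains.append(chain)
    if n_atoms == 0:
        raise FormatError(f"{path}: no ATOM records")
    return out


# ---------------------------------------------------------------------------
# writing


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as fixed-width PDB (ATOM/HETATM/TER/END)."""
    if structure.n_atoms == 0:
        raise ValueError("cannot write an empty structure")
    lines: list[str] = []
    serial = 0
    for chain in structure.chains:
        if len(chain.chain_id) != 1:
            raise FormatError(
                f"PDB chain ids are single characters; got {chain.chain_id!r}"
            )
        for res in chain.residues:
            for a in res.atoms:
                serial += 1
                if serial > 99999:
                    raise OverflowError("more than 99999 atoms: PDB serial overflow")
                record = "HETATM" if (a.is_hetero or a.is_water) else "ATOM  "
                x, y, z = a.position
                if max(abs(x), abs(y), abs(z)) >= 10000:
                    raise OverflowError("coordinate exceeds PDB fixed-width field")
                lines.append(
                    f"{record}{serial:5d} {_format_atom_name(a.atom_name, a.element)}"
                    f" {a.residue_name:>3s} {chain.chain_id}{a.residue_number:4d}"
                    f"{(a.insertion_code or ' '):1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
                    f"          {a.element:>2s}  "
                )
        serial += 1
        last = chain.residues[-1]
        lines.append(
            f"TER   {serial:5d}      {last.name:>3s} {chain.chain_id}{last.number:4d}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# duplex pairing


def _wc_candidate(res_a: Residue, res_b: Residue) -> float | None:
    """Glycosidic-face N1-N3 distance if (a, b) pass the Watson-Crick
    criteria, else None."""
    code_a = nucleotide_code(res_a.name)
    code_b = nucleotide_code(res_b.name)
    if code_a is None or code_b is None or COMPLEMENT[code_a] != code_b:
        return None
    try:
        c1a = res_a.atom("C1'").position
        c1b = res_b.atom("C1'").position
    except KeyError:
        return None
    d_c1 = float(np.linalg.norm(c1a - c1b))
    if not C1_C1_RANGE[0] <= d_c1 <= C1_C1_RANGE[1]:
        return None
    purine, pyrimidine = (res_a, res_b) if code_a in PURINES else (res_b, res_a)
    try:
        n1 = purine.atom("N1").position
        n3 = pyrimidine.atom("N3").position
    except KeyError:
        return None
    d_hb = float(np.linalg.norm(n1 - n3))
    if d_hb > GLYCOSIDIC_HBOND_MAX:
        return None
    return d_hb


def pair_duplex(structure: Structure, chain_a: str, chain_b: str) -> list[BasePair]:
    """Identify Watson-Crick base pairs between two chains of a duplex.

    Pairs are detected from complementarity, C1'-C1' distance in
    [8.9, 11.9] Å and the purine-N1/pyrimidine-N3 hydrogen-bond distance
    (≤ 3.5 Å).  The list is ordered 5'->3' along ``chain_a``; unpaired
    nucleotides on either chain are appended as overhang entries.
    """
    ca = structure.chain(chain_a)
    cb = structure.chain(chain_b)
    nts_a = ca.nucleotides
    nts_b = cb.nucleotides
    if not nts_a or not nts_b:
        empty = chain_a if not nts_a else chain_b
        raise ValueError(f"chain {empty!r} contains no nucleotides")

    used_b: set[tuple[str, int, str]] = set()
    pairs: list[BasePair] = []
    for res_a in nts_a:
        best: tuple[float, Residue] | None = None
        for res_b in nts_b:
            if res_b.key in used_b:
                continue
            d = _wc_candidate(res_a, res_b)
            if d is not None and (best is None or d < best[0]):
                best = (d, res_b)
        if best is not None:
            used_b.add(best[1].key)
            pairs.append(BasePair(res_a, best[1], "watson-crick"))
        else:
            pairs.append(BasePair(res_a, None, "overhang"))
    for res_b in nts_b:
        if res_b.key not in used_b:
            pairs.append(BasePair(None, res_b, "overhang"))
    return pairs


def watson_crick_pairs(pairs: list[BasePair]) -> list[BasePair]:
    """The Watson-Crick subset, in input order."""
    return [p for p in pairs if p.is_watson_crick]
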