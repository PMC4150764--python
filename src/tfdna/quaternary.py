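"""Quaternary-arrangement metrics, disulfide geometry/strain, and SASA.

Disulfide bridges are described by the five side-chain torsions
χ1 (N–CA–CB–SG), χ2 (CA–CB–SG–SG′), χ3 (CB–SG–SG′–CB′) and the primed
equivalents of residue B.  Handedness follows the sign of χ3 (negative:
left-handed); the spiral/hook/staple conformation class follows the common
sign-pattern taxonomy, and torsional strain energy uses a standard
cosine-series expression with configurable force constants.

Solvent-accessible surface area uses Shrake–Rupley quadrature with a
deterministic golden-spiral point set, a 1.4 Å water probe and a fixed van
der Waals radius table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._linalg import angle_between, dihedral
from .structure import Residue, Structure

# torsional strain force constants, kcal/mol: E = sum_k A_k (1 + cos(m_k chi))
DEFAULT_STRAIN_CONSTANTS = {
    "chi1": 2.0,       # 3-fold barrier on chi1 and chi1'
    "chi2": 1.0,       # 3-fold barrier on chi2 and chi2'
    "chi3_2fold": 3.5, # 2-fold term on the S-S torsion
    "chi3_3fold": 0.6, # 3-fold term on the S-S torsion
}

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

SS_BOND_MAX = 2.5  # Å


@dataclass
class DisulfideGeometry:
    chi1: float
    chi2: float
    chi3: float
    chi2_prime: float
    chi1_prime: float
    ss_distance: float
    handedness: str  # "LH" | "RH"
    conformation_class: str  # "spiral" | "hook" | "staple"
    strain_energy: float  # kcal/mol


@dataclass
class QuaternaryReport:
    dimer_centroids: tuple[np.ndarray, np.ndarray]
    pivot: np.ndarray
    inter_dimer_angle: float  # degrees at the DNA pivot
    binding_site_midpoints: tuple[np.ndarray, np.ndarray]


@dataclass
class SurfaceReport:
    per_atom_area: np.ndarray  # Å², aligned with atom list order
    total: float
    probe_radius: float
    n_points: int
    atoms: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# disulfide geometry


def strain_energy(
    chi1: float,
    chi2: float,
    chi3: float,
    chi2_prime: float,
    chi1_prime: float,
    constants: dict[str, float] | None = None,
) -> float:
    """Torsional disulfide strain energy (kcal/mol).

    E = A1[1+cos 3χ1] + A1[1+cos 3χ1′] + A2[1+cos 3χ2] + A2[1+cos 3χ2′]
        + A3[1+cos 2χ3] + A4[1+cos 3χ3]
    """
    c = {**DEFAULT_STRAIN_CONSTANTS, **(constants or {})}
    rad = math.radians
    return (
        c["chi1"] * (1 + math.cos(3 * rad(chi1)))
        + c["chi1"] * (1 + math.cos(3 * rad(chi1_prime)))
        + c["chi2"] * (1 + math.cos(3 * rad(chi2)))
        + c["chi2"] * (1 + math.cos(3 * rad(chi2_prime)))
        + c["chi3_2fold"] * (1 + math.cos(2 * rad(chi3)))
        + c["chi3_3fold"] * (1 + math.cos(3 * rad(chi3)))
    )


def classify_disulfide(chi2: float, chi2_prime: float, chi3: float) -> tuple[str, str]:
    """(handedness, class) from the torsion sign pattern.

    spiral: χ2 and χ2′ share the sign of χ3; staple: both oppose it;
    hook: mixed.
    """
    handedness = "LH" if chi3 < 0 else "RH"
    same = [(chi2 < 0) == (chi3 < 0), (chi2_prime < 0) == (chi3 < 0)]
    if all(same):
        cls = "spiral"
    elif not any(same):
        cls = "staple"
    else:
        cls = "hook"
    return handedness, cls


def disulfide_geometry(
    structure: Structure,
    cys_a: tuple[str, int],
    cys_b: tuple[str, int],
    constants: dict[str, float] | None = None,
) -> DisulfideGeometry:
    """Torsion geometry, handedness/class and strain energy of a disulfide."""

    def fetch(ref: tuple[str, int]) -> Residue:
        res = structure.chain(ref[0]).residue(ref[1])
        if res.name != "CYS":
            raise ValueError(f"{ref[0]}/{ref[1]} is {res.name}, not CYS")
        for name in ("N", "CA", "CB", "SG"):
            if not res.has_atom(name):
                raise ValueError(f"{ref[0]}/CYS{ref[1]} missing atom {name}")
        return res

    ra, rb = fetch(cys_a), fetch(cys_b)
    pa = {n: ra.atom(n).position for n in ("N", "CA", "CB", "SG")}
    pb = {n: rb.atom(n).position for n in ("N", "CA", "CB", "SG")}
    ss = float(np.linalg.norm(pa["SG"] - pb["SG"]))
    if ss > SS_BOND_MAX:
        raise ValueError(
            f"SG-SG distance {ss:.2f} Å exceeds {SS_BOND_MAX} Å: not a disulfide"
        )
    chi1 = dihedral(pa["N"], pa["CA"], pa["CB"], pa["SG"])
    chi2 = dihedral(pa["CA"], pa["CB"], pa["SG"], pb["SG"])
    chi3 = dihedral(pa["CB"], pa["SG"], pb["SG"], pb["CB"])
    chi2p = dihedral(pb["CA"], pb["CB"], pb["SG"], pa["SG"])
    chi1p = dihedral(pb["N"], pb["CA"], pb["CB"], pb["SG"])
    handedness, cls = classify_disulfide(chi2, chi2p, chi3)
    energy = strain_energy(chi1, chi2, chi3, chi2p, chi1p, constants)
    return DisulfideGeometry(
        chi1=chi1, chi2=chi2, chi3=chi3, chi2_prime=chi2p, chi1_prime=chi1p,
        ss_distance=ss, handedness=handedness, conformation_class=cls,
        strain_energy=energy,
    )


# ---------------------------------------------------------------------------
# dimer-of-dimers vs DNA angle


def dimer_dna_angle(
    structure: Structure,
    dimer_1_chains: tuple[str, ...],
    dimer_2_chains: tuple[str, ...],
    dna_chains: tuple[str, ...],
) -> QuaternaryReport:
    """Angle at the DNA centroid between rays to the two dimer Cα centroids.

    The pivot is the centroid of all DNA heavy atoms; each dimer centroid is
    the mean of its Cα positions (all heavy atoms if no Cα present).  The
    per-dimer binding-site midpoint reported alongside is the DNA heavy atom
    closest to each dimer centroid.
    """
    if set(dimer_1_chains) & set(dimer_2_chains):
        raise ValueError("dimer selections overlap")

    def centroid(chains: tuple[str, ...], atom_name: str | None) -> np.ndarray:
        pts = []
        for cid in chains:
            for res in structure.chain(cid).residues:
                if res.is_water:
                    continue
                for a in res.atoms:
                    if a.element == "H":
                        continue
                    if atom_name is None or a.atom_name == atom_name:
                        pts.append(a.position)
        if not pts:
            raise ValueError(f"no atoms found in chains {chains}")
        return np.mean(pts, axis=0)

    def protein_centroid(chains):
        try:
            return centroid(chains, "CA")
        except ValueError:
            return centroid(chains, None)

    c1 = protein_centroid(dimer_1_chains)
    c2 = protein_centroid(dimer_2_chains)
    pivot = centroid(dna_chains, None)

    angle = angle_between(c1 - pivot, c2 - pivot)

    dna_atoms = [
        a
        for cid in dna_chains
        for r in structure.chain(cid).residues
        for a in r.atoms
        if a.element != "H" and not a.is_water
    ]
    pos = np.array([a.position for a in dna_atoms])
    mid1 = pos[np.argmin(np.linalg.norm(pos - c1, axis=1))]
    mid2 = pos[np.argmin(np.linalg.norm(pos - c2, axis=1))]

    return QuaternaryReport(
        dimer_centroids=(c1, c2),
        pivot=pivot,
        inter_dimer_angle=float(angle),
        binding_site_midpoints=(mid1, mid2),
    )


# ---------------------------------------------------------------------------
# solvent-accessible surface area


def sasa(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: dict[str, float] | None = None,
    include_waters: bool = False,
) -> SurfaceReport:
    """Shrake–Rupley SASA with a deterministic golden-spiral point set.

    Per-atom area = (exposed points / total points) * 4π (r + probe)².
    """
    from ._linalg import fibonacci_sphere

    table = {**VDW_RADII, **(radii or {})}
    atoms = [
        a
        for a in structure.iter_atoms()
        if a.element != "H" and (include_waters or not a.is_water)
    ]
    if not atoms:
        raise ValueError("no atoms to compute SASA for")
    unknown = sorted({a.element for a in atoms} - set(table))
    if unknown:
        raise ValueError(f"no van der Waals radius configured for element(s) {unknown}")

    pos = np.array([a.position for a in atoms])
    rad = np.array([table[a.element] + probe for a in atoms])
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(pos)
    max_r = rad.max()

    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = pos[i] + rad[i] * sphere
        neighbors = [j for j in tree.query_ball_point(pos[i], rad[i] + max_r) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - pos[j]) ** 2, axis=1)
            exposed &= d2 > rad[j] ** 2
        areas[i] = exposed.sum() / n_points * 4.0 * np.pi * rad[i] ** 2
    return SurfaceReport(
        per_atom_area=areas,
        total=float(areas.sum()),
        probe_radius=probe,
        n_points=n_points,
        atoms=atoms,
    )
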