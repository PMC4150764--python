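"""Synthetic input generators: fiber-model B-DNA duplexes, paired apo/bound
toy complexes with a known contact ledger, random genomes with planted
motifs, and simulated ITC isotherms.

Every generator is a pure function of its spec (including the seed) so that
each downstream analysis has a ground truth to be tested against.  The
duplex builder places standard-geometry base templates on stacked base-pair
frames generated from prescribed step parameters, with the phosphate
backbone positioned by a fixed per-nucleotide template oriented by the base
frame — sufficient for frame, step-parameter and P-atom groove analyses,
not for refinement-grade stereochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import itc as _itc
from ._linalg import rot_x
from .bases import (
    BASE_TEMPLATES,
    COMPLEMENT,
    OP1_TEMPLATE,
    OP2_TEMPLATE,
    P_TEMPLATE,
    reverse_complement,
)
from .contacts import DEFAULT_HBOND_CUTOFF, InterfaceDiff
from .dna import step_transform
from .structure import Atom, Chain, Residue, Structure

# the 22-bp semi-palindromic consensus operator bound by CprB
CS_CONSENSUS = "ACATACGGGACGCCCCGTTTAT"

simulate_itc = _itc.simulate_itc  # the ITC input generator lives with its model

_FLIP = rot_x(180.0)


# ---------------------------------------------------------------------------
# B-DNA duplex builder


@dataclass
class DuplexSpec:
    """Recipe for a fiber-model B-form duplex (strand I sequence, 5'->3')."""

    sequence: str
    twist_per_step: float = 36.0  # degrees
    rise_per_step: float = 3.38  # Å
    roll_profile: tuple[float, ...] | None = None  # degrees per step
    tilt_profile: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 2:
            raise ValueError("duplex needs at least 2 base pairs")
        bad = sorted(set(self.sequence) - set("ACGT"))
        if bad:
            raise ValueError(f"invalid bases in sequence: {bad}")
        for prof in (self.roll_profile, self.tilt_profile):
            if prof is not None and len(prof) != len(self.sequence) - 1:
                raise ValueError(
                    f"profile length {len(prof)} != {len(self.sequence) - 1} steps"
                )


def _element_of(atom_name: str) -> str:
    return atom_name[0]


def build_ideal_bdna(spec: DuplexSpec) -> Structure:
    """Construct a two-chain B-form duplex from stacked base-pair frames.

    Chain A is strand I (residues 1..N, 5'->3'); chain B is the reverse
    complement (residues 1..N in its own 5'->3' order).  Every residue
    carries its base ring atoms, C1', and a 5'-phosphate group (P/OP1/OP2),
    so the duplex is fully analyzable by the frame, step-parameter and
    groove-width operators.
    """
    n = len(spec.sequence)
    n_steps = n - 1
    rolls = spec.roll_profile or (0.0,) * n_steps
    tilts = spec.tilt_profile or (0.0,) * n_steps

    # pair frames by composing the prescribed step transforms
    axes = [np.eye(3)]
    origins = [np.zeros(3)]
    for i in range(n_steps):
        R, t = step_transform(
            rise=spec.rise_per_step,
            roll=rolls[i],
            tilt=tilts[i],
            twist=spec.twist_per_step,
        )
        origins.append(origins[-1] + axes[-1] @ t)
        axes.append(axes[-1] @ R)

    def place(frame_axes, frame_origin, local: np.ndarray) -> np.ndarray:
        return frame_axes @ local + frame_origin

    chain_a = Chain(chain_id="A")
    strand_ii_residues: list[Residue] = []  # collected in level order (3'->5' of II)
    for level, base in enumerate(spec.sequence):
        comp = COMPLEMENT[base]
        ax, org = axes[level], origins[level]

        res_a = Residue(chain_id="A", number=level + 1, insertion_code="", name=f"D{base}")
        for name, local in BASE_TEMPLATES[base].items():
            res_a.atoms.append(
                Atom("A", level + 1, "", f"D{base}", name, _element_of(name),
                     place(ax, org, local))
            )
        for name, local in (("P", P_TEMPLATE), ("OP1", OP1_TEMPLATE), ("OP2", OP2_TEMPLATE)):
            res_a.atoms.append(
                Atom("A", level + 1, "", f"D{base}", name, _element_of(name),
                     place(ax, org, local))
            )
        chain_a.residues.append(res_a)

        ax_ii = ax @ _FLIP
        res_b = Residue(chain_id="B", number=n - level, insertion_code="", name=f"D{comp}")
        for name, local in BASE_TEMPLATES[comp].items():
            res_b.atoms.append(
                Atom("B", n - level, "", f"D{comp}", name, _element_of(name),
                     place(ax_ii, org, local))
            )
        for name, local in (("P", P_TEMPLATE), ("OP1", OP1_TEMPLATE), ("OP2", OP2_TEMPLATE)):
            res_b.atoms.append(
                Atom("B", n - level, "", f"D{comp}", name, _element_of(name),
                     place(ax_ii, org, local))
            )
        strand_ii_residues.append(res_b)

    chain_b = Chain(chain_id="B", residues=list(reversed(strand_ii_residues)))
    return Structure(id="bdna", chains=[chain_a, chain_b])


# ---------------------------------------------------------------------------
# apo/bound toy complexes


@dataclass
class ToyComplexSpec:
    """Prescribed hydrogen-bond ledger for an apo/bound structure pair."""

    n_bonds_retained: int = 5
    n_bonds_disrupted: int = 10
    n_bonds_formed: int = 9
    separation_distance: float = 7.0  # Å, broken pairs in the non-bonded state
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_bonds_retained", "n_bonds_disrupted", "n_bonds_formed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.separation_distance <= DEFAULT_HBOND_CUTOFF:
            raise ValueError(
                f"separation_distance {self.separation_distance} must exceed the "
                f"hydrogen-bond cutoff {DEFAULT_HBOND_CUTOFF} Å"
            )


def make_toy_complex(spec: ToyComplexSpec) -> tuple[Structure, Structure, InterfaceDiff]:
    """Build an apo/bound pair of two-chain structures realizing the ledger.

    Each prescribed bond is a LYS NZ (chain A) / SER OG (chain B) pair on a
    sparse grid (slots 25 Å apart, so no accidental cross-slot contacts);
    retained pairs sit within the cutoff in both states, disrupted pairs
    only in apo, formed pairs only in bound.  Returns the ground-truth
    InterfaceDiff keyed exactly as diff_interface reports it.
    """
    rng = np.random.default_rng(spec.seed)
    total = spec.n_bonds_retained + spec.n_bonds_disrupted + spec.n_bonds_formed
    kinds = (
        ["retained"] * spec.n_bonds_retained
        + ["disrupted"] * spec.n_bonds_disrupted
        + ["formed"] * spec.n_bonds_formed
    )

    def bonded_distance() -> float:
        return float(rng.uniform(2.6, 3.3))

    def broken_distance() -> float:
        return float(rng.uniform(spec.separation_distance, spec.separation_distance + 1.5))

    apo = Structure(id="toy-apo", chains=[Chain("A"), Chain("B")])
    bound = Structure(id="toy-bound", chains=[Chain("A"), Chain("B")])
    truth = InterfaceDiff()

    for slot, kind in enumerate(kinds):
        resnum = slot + 1
        anchor = np.array([25.0 * slot, 0.0, 0.0])
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        d_apo = bonded_distance() if kind in ("retained", "disrupted") else broken_distance()
        d_bound = bonded_distance() if kind in ("retained", "formed") else broken_distance()

        for st, d in ((apo, d_apo), (bound, d_bound)):
            res_a = Residue("A", resnum, "", "LYS")
            res_a.atoms.append(Atom("A", resnum, "", "LYS", "NZ", "N", anchor))
            res_b = Residue("B", resnum, "", "SER")
            res_b.atoms.append(Atom("B", resnum, "", "SER", "OG", "O", anchor + d * direction))
            st.chain("A").residues.append(res_a)
            st.chain("B").residues.append(res_b)

        pair_id = tuple(sorted([("A", resnum, "", "NZ"), ("B", resnum, "", "OG")]))
        record = (pair_id, d_apo, d_bound)
        getattr(truth, kind).append(record)

    if total == 0:
        # keep structures non-empty so they remain writable/readable
        for st in (apo, bound):
            res = Residue("A", 1, "", "GLY")
            res.atoms.append(Atom("A", 1, "", "GLY", "CA", "C", np.zeros(3)))
            st.chain("A").residues.append(res)
            res_b = Residue("B", 1, "", "GLY")
            res_b.atoms.append(Atom("B", 1, "", "GLY", "CA", "C", np.array([50.0, 0, 0])))
            st.chain("B").residues.append(res_b)
    return apo, bound, truth


# ---------------------------------------------------------------------------
# genomes with planted motifs


@dataclass
class GenomeSpec:
    """Random genome with degenerate motif copies planted at fixed positions."""

    length: int = 10000
    gc_fraction: float = 0.5
    # (motif, 1-based position on plus strand, strand '+'|'-', n_mismatches)
    plants: tuple[tuple[str, int, str, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("genome length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction outside [0, 1]")
        intervals = []
        for motif, pos, strand, n_mm in self.plants:
            if strand not in "+-":
                raise ValueError(f"strand must be '+' or '-', got {strand!r}")
            if n_mm < 0 or n_mm > len(motif):
                raise ValueError("mismatch count outside [0, motif length]")
            if pos < 1 or pos + len(motif) - 1 > self.length:
                raise ValueError(f"plant at {pos} does not fit in genome of {self.length} bp")
            intervals.append((pos, pos + len(motif) - 1))
        intervals.sort()
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 <= e1:
                raise ValueError(f"planted motifs overlap: [{s1},{e1}] and [{s2},{e2}]")


def generate_genome(spec: GenomeSpec) -> str:
    """Deterministic random genome with the requested plants.

    Mismatch positions and substitute bases are chosen by the seeded
    generator; minus-strand plants are inserted as the reverse complement of
    the (mutated) motif.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    alphabet = np.array(list("ACGT"))
    genome = rng.choice(alphabet, size=spec.length, p=probs)

    for motif, pos, strand, n_mm in spec.plants:
        motif = motif.upper()
        seq = list(motif)
        if n_mm > 0:
            sites = rng.choice(len(seq), size=n_mm, replace=False)
            for s in sites:
                choices = [b for b in "ACGT" if b != seq[s]]
                seq[s] = choices[rng.integers(len(choices))]
        planted = "".join(seq)
        if strand == "-":
            planted = reverse_complement(planted)
        genome[pos - 1 : pos - 1 + len(planted)] = list(planted)
    return "".join(genome)


def write_fasta(records: dict[str, str], path) -> None:
    """Write sequences as FASTA (wrapped at 70 columns) via Biopython."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()],
        str(path),
        "fasta",
    )
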