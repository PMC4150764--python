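"""Standard-geometry nucleobase templates and nucleotide chemistry tables.

The base-atom coordinates are the standard reference frame for nucleic-acid
bases (x into the major groove, y toward the strand-I backbone, z along the
helix advance; origin near the pair center).  A Watson–Crick partner is
generated by flipping the complementary template 180° about x.  The template
phosphorus position was calibrated once so that the groove-width convention
used here (minimal cross-strand P–P distance minus 5.8 Å) reproduces the
canonical ideal-B-form values of 11.7 Å (major) and 5.9 Å (minor); it also
reproduces a physically correct ~5.6 Å P(i)→C1′(i−1) backbone linkage.
"""

from __future__ import annotations

import numpy as np

# Base ring + exocyclic + C1' coordinates (Å) in the standard reference frame.
BASE_TEMPLATES: dict[str, dict[str, np.ndarray]] = {
    "A": {
        "C1'": np.array([-2.479, 5.346, 0.000]),
        "N9": np.array([-1.291, 4.498, 0.000]),
        "C8": np.array([0.024, 4.897, 0.000]),
        "N7": np.array([0.877, 3.902, 0.000]),
        "C5": np.array([0.071, 2.771, 0.000]),
        "C6": np.array([0.369, 1.398, 0.000]),
        "N6": np.array([1.611, 0.909, 0.000]),
        "N1": np.array([-0.668, 0.532, 0.000]),
        "C2": np.array([-1.912, 1.023, 0.000]),
        "N3": np.array([-2.320, 2.290, 0.000]),
        "C4": np.array([-1.267, 3.124, 0.000]),
    },
    "G": {
        "C1'": np.array([-2.477, 5.399, 0.000]),
        "N9": np.array([-1.289, 4.551, 0.000]),
        "C8": np.array([0.023, 4.962, 0.000]),
        "N7": np.array([0.870, 3.969, 0.000]),
        "C5": np.array([0.071, 2.833, 0.000]),
        "C6": np.array([0.424, 1.460, 0.000]),
        "O6": np.array([1.554, 0.955, 0.000]),
        "N1": np.array([-0.700, 0.641, 0.000]),
        "C2": np.array([-1.999, 1.087, 0.000]),
        "N2": np.array([-2.949, 0.139, -0.001]),
        "N3": np.array([-2.342, 2.364, 0.001]),
        "C4": np.array([-1.265, 3.177, 0.000]),
    },
    "C": {
        "C1'": np.array([-2.477, 5.402, 0.000]),
        "N1": np.array([-1.285, 4.542, 0.000]),
        "C2": np.array([-1.472, 3.158, 0.000]),
        "O2": np.array([-2.628, 2.709, 0.001]),
        "N3": np.array([-0.391, 2.344, 0.000]),
        "C4": np.array([0.837, 2.868, 0.000]),
        "N4": np.array([1.875, 2.027, 0.001]),
        "C5": np.array([1.056, 4.275, 0.000]),
        "C6": np.array([-0.023, 5.068, 0.000]),
    },
    "T": {
        "C1'": np.array([-2.481, 5.354, 0.000]),
        "N1": np.array([-1.284, 4.500, 0.000]),
        "C2": np.array([-1.462, 3.135, 0.000]),
        "O2": np.array([-2.562, 2.608, 0.000]),
        "N3": np.array([-0.298, 2.407, 0.000]),
        "C4": np.array([0.994, 2.897, 0.000]),
        "O4": np.array([1.944, 2.119, 0.000]),
        "C5": np.array([1.106, 4.338, 0.000]),
        "C7": np.array([2.466, 4.961, 0.001]),
        "C6": np.array([-0.024, 5.057, 0.000]),
    },
}

# Heavy-atom ring sets used for least-squares base-frame fitting.
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "T"})

COMPLEMENT: dict[str, str] = {"A": "T", "T": "A", "G": "C", "C": "G"}

# Phosphorus (and phosphate oxygens) in the base reference frame.  The P of
# residue i bridges residue i-1 -> i along 5'->3'.  Azimuth/height calibrated
# against the canonical B-form groove P-P distances (17.5 / 11.7 Å); radius
# 8.91 Å from the classic B-DNA fiber model.
_P_RADIUS = 8.91
_P_AZIMUTH_DEG = 106.186
_P_Z = -0.060
P_TEMPLATE = np.array(
    [
        _P_RADIUS * np.cos(np.deg2rad(_P_AZIMUTH_DEG)),
        _P_RADIUS * np.sin(np.deg2rad(_P_AZIMUTH_DEG)),
        _P_Z,
    ]
)
# Free phosphate oxygens flanking P, pointing outward from the helix.
OP1_TEMPLATE = P_TEMPLATE + np.array([0.45, 1.30, 0.60])
OP2_TEMPLATE = P_TEMPLATE + np.array([0.45, 1.30, -0.80])

# Canonical cross-strand partner-level offsets of the groove P-P minima for
# this fiber geometry: level i (strand I P) vs level i-k (strand II P).
MINOR_GROOVE_OFFSETS: tuple[int, ...] = (1, 2, 3, 4)
MAJOR_GROOVE_OFFSETS: tuple[int, ...] = (5, 6, 7)
# Two phosphate-group radii subtracted from raw P-P distances.
PHOSPHATE_RADIUS_CORRECTION = 5.8

_RESNAME_TO_CODE = {
    "DA": "A", "DT": "T", "DG": "G", "DC": "C",
    "A": "A", "T": "T", "G": "G", "C": "C",
    "ADE": "A", "THY": "T", "GUA": "G", "CYT": "C",
}


def nucleotide_code(residue_name: str) -> str | None:
    """One-letter base code for a residue name, or None if not a (deoxy)nucleotide."""
    return _RESNAME_TO_CODE.get(residue_name.strip().upper())


def is_nucleotide(residue_name: str) -> bool:
    return nucleotide_code(residue_name) is not None


def reverse_complement(seq: str) -> str:
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"not a DNA base: {exc.args[0]!r}") from exc
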