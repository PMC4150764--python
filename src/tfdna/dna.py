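"""Base-pair reference frames, step parameters, global bend and groove widths.

The frame convention is the standard reference frame for nucleic-acid bases
(x into the major groove, y toward strand I, z along helix advance), with
step parameters extracted through the mid-step-triad construction used by
the 3DNA family of tools: the two pair frames are symmetrically rotated onto
a common mid-frame z, twist is the in-plane x-axis rotation, and the
roll/tilt decomposition follows the hinge-axis phase angle.  Translational
parameters (shift, slide, rise) are the origin displacement expressed in the
mid-step triad.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import (
    angle_between,
    orthonormal_midframe,
    rot_x,
    rot_y,
    rot_z,
    rotation_about_axis,
)
from .bases import (
    BASE_TEMPLATES,
    MAJOR_GROOVE_OFFSETS,
    MINOR_GROOVE_OFFSETS,
    PHOSPHATE_RADIUS_CORRECTION,
    RING_ATOMS,
    nucleotide_code,
)
from .structure import BasePair, Residue, Structure, watson_crick_pairs
from ._linalg import kabsch

FLIP = rot_x(180.0)  # maps a strand-II base template into the shared pair frame


@dataclass
class Frame:
    """Orthonormal right-handed triad with an origin (Å)."""

    origin: np.ndarray
    axes: np.ndarray  # columns are x, y, z
    fit_rmsd: float = 0.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        self.axes = np.asarray(self.axes, float)
        err = np.abs(self.axes.T @ self.axes - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"frame axes not orthonormal (max deviation {err:.2e})")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("frame axes are left-handed")

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]


@dataclass
class BasePairStep:
    """The six rigid-body parameters between consecutive base-pair frames."""

    index: int  # 1-based, 5'->3' on strand I
    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist)


@dataclass
class GrooveMeasurement:
    """Major/minor groove widths at one base-pair level (None: not measurable)."""

    level: int  # 1-based pair index
    major_width: float | None
    minor_width: float | None
    definition_tag: str = "P-P minus 5.8 A, windowed cross-strand minimum"


PARAM_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")


# ---------------------------------------------------------------------------
# frames


def base_frame(residue: Residue) -> Frame:
    """Least-squares standard-reference frame of one nucleotide base.

    The standard-geometry ring of the base type is superposed onto the
    observed ring atoms; the resulting rotation/translation is the frame,
    and the fit RMSD is reported on it.
    """
    code = nucleotide_code(residue.name)
    if code is None:
        raise ValueError(f"{residue!r} is not a nucleotide")
    ring = RING_ATOMS[code]
    missing = [n for n in ring if not residue.has_atom(n)]
    if missing:
        raise ValueError(
            f"{residue.chain_id}/{residue.name}{residue.number}: "
            f"missing ring atoms {', '.join(missing)}"
        )
    template = np.array([BASE_TEMPLATES[code][n] for n in ring])
    observed = np.array([residue.atom(n).position for n in ring])
    R, t, rmsd = kabsch(template, observed)
    return Frame(origin=t, axes=R, fit_rmsd=rmsd)


def pair_frame(pair: BasePair) -> Frame:
    """Mean frame of a Watson-Crick pair (strand-II frame flipped about x)."""
    if not pair.is_watson_crick:
        raise ValueError("pair frame requires a Watson-Crick pair")
    f1 = base_frame(pair.residue_I)
    f2 = base_frame(pair.residue_II)
    r2 = f2.axes @ FLIP  # complementary strand flipped into the pair frame
    mid = orthonormal_midframe(f1.axes, r2)
    return Frame(
        origin=(f1.origin + f2.origin) / 2.0,
        axes=mid,
        fit_rmsd=max(f1.fit_rmsd, f2.fit_rmsd),
    )


# ---------------------------------------------------------------------------
# step parameters


def step_from_frames(frame1: Frame, frame2: Frame, index: int = 1) -> BasePairStep:
    """Mid-step-triad step parameters between two pair frames."""
    r1, r2 = frame1.axes, frame2.axes
    z1, z2 = r1[:, 2], r2[:, 2]
    gamma = angle_between(z1, z2)  # RollTilt magnitude
    hinge = np.cross(z1, z2)
    if np.linalg.norm(hinge) < 1e-12:
        r1p, r2p = r1, r2
        hinge = None
    else:
        r1p = rotation_about_axis(hinge, +gamma / 2.0) @ r1
        r2p = rotation_about_axis(hinge, -gamma / 2.0) @ r2
    zm = r1p[:, 2]
    x1, x2 = r1p[:, 0], r2p[:, 0]
    twist = float(
        np.degrees(np.arctan2(np.dot(np.cross(x1, x2), zm), np.dot(x1, x2)))
    )
    xm = x1 + x2
    ym = r1p[:, 1] + r2p[:, 1]
    if np.linalg.norm(xm) < 1e-9:  # twist of 180 degrees: undefined bisector
        raise ValueError("degenerate step: twist of 180 degrees")
    xm /= np.linalg.norm(xm)
    ym /= np.linalg.norm(ym)
    rm = np.column_stack([xm, ym, zm])
    if hinge is None:
        roll = tilt = 0.0
    else:
        h = hinge / np.linalg.norm(hinge)
        phi = float(
            np.degrees(np.arctan2(np.dot(np.cross(ym, h), zm), np.dot(ym, h)))
        )
        roll = gamma * np.cos(np.deg2rad(phi))
        tilt = gamma * np.sin(np.deg2rad(phi))
    disp = rm.T @ (frame2.origin - frame1.origin)
    return BasePairStep(
        index=index,
        shift=float(disp[0]),
        slide=float(disp[1]),
        rise=float(disp[2]),
        tilt=float(tilt),
        roll=float(roll),
        twist=twist,
    )


def step_transform(
    shift: float = 0.0,
    slide: float = 0.0,
    rise: float = 3.38,
    tilt: float = 0.0,
    roll: float = 0.0,
    twist: float = 36.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`step_from_frames`.

    Returns ``(R, t)`` in frame-1 local coordinates: the next pair frame is
    ``axes2 = axes1 @ R`` and ``origin2 = origin1 + axes1 @ t``.
    """
    gamma = float(np.hypot(roll, tilt))
    # sign of phi chosen to invert the extraction's hinge-phase convention
    phi = float(np.degrees(np.arctan2(-tilt, roll)))
    R = rot_z(twist / 2.0 - phi) @ rot_y(gamma) @ rot_z(twist / 2.0 + phi)
    rm_local = rot_z(twist / 2.0 - phi) @ rot_y(gamma / 2.0) @ rot_z(phi)
    t = rm_local @ np.array([shift, slide, rise])
    return R, t


def step_parameters(pairs: list[BasePair], structure: Structure | None = None) -> list[BasePairStep]:
    """Step parameters between all consecutive Watson-Crick pairs.

    Unpaired overhang entries are skipped; the index on each step is the
    1-based position of its 5' pair within the Watson-Crick subset.
    """
    wc = watson_crick_pairs(pairs)
    if len(wc) < 2:
        raise ValueError("need at least two Watson-Crick pairs for step parameters")
    frames = [pair_frame(p) for p in wc]
    return [
        step_from_frames(frames[i], frames[i + 1], index=i + 1)
        for i in range(len(frames) - 1)
    ]


def average_params(steps: list[BasePairStep]) -> dict[str, tuple[float, float]]:
    """Mean and sample standard deviation (n-1) of each step parameter."""
    if not steps:
        raise ValueError("no steps to average")
    out: dict[str, tuple[float, float]] = {}
    for name in PARAM_NAMES:
        vals = np.array([getattr(s, name) for s in steps], dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[name] = (float(vals.mean()), sd)
    return out


# ---------------------------------------------------------------------------
# global bend


def global_bend(
    pairs: list[BasePair],
    structure: Structure | None = None,
    method: str = "ends",
) -> float:
    """Overall axis deflection of the duplex, in degrees.

    ``ends`` (default): the angle between the mean base-pair normal of the
    first three pairs and that of the last three — an end-to-end statement
    of how much the helix entry and exit directions differ.  ``cumulative``:
    the sum of per-step bending magnitudes sqrt(roll² + tilt²), an upper
    bound that does not allow bends to cancel.
    """
    wc = watson_crick_pairs(pairs)
    if len(wc) < 4:
        raise ValueError("need at least four Watson-Crick pairs for a bend estimate")
    if method == "cumulative":
        steps = step_parameters(pairs)
        return float(sum(np.hypot(s.roll, s.tilt) for s in steps))
    if method != "ends":
        raise ValueError(f"unknown bend method {method!r}")
    frames = [pair_frame(p) for p in wc]
    head = np.mean([f.z for f in frames[:3]], axis=0)
    tail = np.mean([f.z for f in frames[-3:]], axis=0)
    ang = angle_between(head, tail)
    return float(min(ang, 360.0 - ang) % 180.0)


# ---------------------------------------------------------------------------
# groove widths


def groove_widths(pairs: list[BasePair], structure: Structure | None = None) -> list[GrooveMeasurement]:
    """Major and minor groove widths per base-pair level.

    Width at level i is the minimal cross-strand P-P distance between the
    strand-I phosphate at level i and strand-II phosphates at the canonical
    partner offsets (minor: levels i-1…i-4; major: i-5…i-7), minus 5.8 Å for
    the two phosphate-group radii.  Levels whose partner window has no
    phosphates are flagged not-measurable (None).
    """
    wc = watson_crick_pairs(pairs)
    if len(wc) < 7:
        raise ValueError("groove widths need at least 7 consecutive pairs")

    def p_pos(residue: Residue) -> np.ndarray | None:
        return residue.atom("P").position if residue.has_atom("P") else None

    p_i = [p_pos(p.residue_I) for p in wc]
    p_ii = [p_pos(p.residue_II) for p in wc]
    if all(p is None for p in p_i + p_ii):
        raise ValueError("no phosphorus atoms in the duplex")

    def window_min(level: int, offsets: tuple[int, ...]) -> float | None:
        # interior levels only: the full canonical window must be available,
        # otherwise a truncated window would bias the minimum upward
        ref = p_i[level]
        if ref is None:
            return None
        dists = []
        for k in offsets:
            j = level - k
            if not 0 <= j < len(wc) or p_ii[j] is None:
                return None
            dists.append(float(np.linalg.norm(ref - p_ii[j])))
        return min(dists) - PHOSPHATE_RADIUS_CORRECTION

    out: list[GrooveMeasurement] = []
    for level in range(len(wc)):
        major = window_min(level, MAJOR_GROOVE_OFFSETS)
        minor = window_min(level, MINOR_GROOVE_OFFSETS)
        out.append(GrooveMeasurement(level=level + 1, major_width=major, minor_width=minor))
    return out


def mean_groove_widths(measurements: list[GrooveMeasurement]) -> dict[str, float]:
    """Mean of the measurable interior levels for each groove."""
    majors = [m.major_width for m in measurements if m.major_width is not None]
    minors = [m.minor_width for m in measurements if m.minor_width is not None]
    out: dict[str, float] = {}
    if majors:
        out["major"] = float(np.mean(majors))
    if minors:
        out["minor"] = float(np.mean(minors))
    return out
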