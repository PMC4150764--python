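"""Consensus-sequence scanning of genomes on both strands.

The scan is an ungapped similarity lookup: a fixed-length consensus (IUPAC
degeneracy codes allowed) is slid over every window of the genome, scoring
one point per position whose base is compatible with the consensus code.
Minus-strand matches are found by scanning the reverse-complemented
consensus against the plus strand, so all coordinates are reported 1-based
inclusive on the plus strand regardless of hit strand; the hit subsequence
is reported as read 5'->3' on its own strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT_IUPAC = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


@dataclass
class MotifHit:
    """One consensus match: 1-based inclusive plus-strand coordinates."""

    start: int
    end: int
    strand: str  # "+" | "-"
    score: int
    subsequence: str  # as read 5'->3' on the hit strand
    record_id: str = ""


@dataclass
class ConservationAnnotation:
    sequences: tuple[str, ...]
    annotation: str  # over {'*', ':', ' '}


def _validate(seq: str, role: str) -> str:
    seq = seq.upper()
    bad = [i + 1 for i, ch in enumerate(seq) if ch not in IUPAC]
    if bad:
        raise ValueError(f"{role} has non-IUPAC characters at positions {bad[:10]}")
    return seq


def revcomp_iupac(seq: str) -> str:
    return "".join(_COMPLEMENT_IUPAC[c] for c in reversed(seq.upper()))


def score_window(consensus: str, window: str) -> int:
    """Count of window positions compatible with the consensus IUPAC code."""
    consensus = _validate(consensus, "consensus")
    window = _validate(window, "window")
    if len(consensus) != len(window):
        raise ValueError(
            f"length mismatch: consensus {len(consensus)} vs window {len(window)}"
        )
    return sum(1 for c, w in zip(consensus, window) if w in IUPAC[c])


def scan(
    genome: str,
    consensus: str,
    min_score: int,
    both_strands: bool = True,
    record_id: str = "",
) -> list[MotifHit]:
    """All windows scoring at least ``min_score``, sorted by descending score
    then ascending position (plus strand before minus at ties).  Overlapping
    hits are retained."""
    genome = _validate(genome, "genome")
    consensus = _validate(consensus, "consensus")
    L, m = len(genome), len(consensus)
    if L < m:
        raise ValueError(f"genome length {L} shorter than consensus {m}")

    searches = [("+", consensus)]
    if both_strands:
        searches.append(("-", revcomp_iupac(consensus)))

    hits: list[MotifHit] = []
    sets = {s: IUPAC[s] for s in IUPAC}
    for strand, pattern in searches:
        pat_sets = [sets[c] for c in pattern]
        for start in range(L - m + 1):
            window = genome[start : start + m]
            score = sum(1 for ps, w in zip(pat_sets, window) if w in ps)
            if score >= min_score:
                sub = window if strand == "+" else revcomp_iupac(window)
                hits.append(
                    MotifHit(
                        start=start + 1,
                        end=start + m,
                        strand=strand,
                        score=score,
                        subsequence=sub,
                        record_id=record_id,
                    )
                )
    hits.sort(key=lambda h: (-h.score, h.start, h.strand))
    return hits


def scan_fasta(
    path: str | Path,
    consensus: str,
    min_score: int,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan every record of a (multi-)FASTA file."""
    from Bio import SeqIO

    hits: list[MotifHit] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        hits.extend(
            scan(str(rec.seq), consensus, min_score, both_strands, record_id=rec.id)
        )
    hits.sort(key=lambda h: (-h.score, h.record_id, h.start, h.strand))
    return hits


def annotate_conservation(sequences: list[str]) -> ConservationAnnotation:
    """Per-column conservation marks: '*' all identical, ':' at least two
    identical (but not all), ' ' otherwise."""
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    seqs = [s.upper() for s in sequences]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"ragged sequence lengths: {sorted(lengths)}")
    marks = []
    for col in zip(*seqs):
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        top = max(counts.values())
        if top == len(col):
            marks.append("*")
        elif top >= 2:
            marks.append(":")
        else:
            marks.append(" ")
    return ConservationAnnotation(sequences=tuple(seqs), annotation="".join(marks))
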