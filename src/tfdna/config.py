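"""Declarative pipeline configuration.

A single JSON document drives the full-report pipeline; every default is
echoed into the report for provenance.  Unknown keys are rejected so that a
typo in a cutoff name cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .contacts import DEFAULT_CONTACT_CUTOFF, DEFAULT_HBOND_CUTOFF, STACKING_CENTROID_CUTOFF
from .quaternary import DEFAULT_N_POINTS, DEFAULT_PROBE, DEFAULT_STRAIN_CONSTANTS, VDW_RADII


@dataclass
class PipelineConfig:
    # chain assignments (bound-structure naming)
    protein_dimers: tuple[tuple[str, ...], ...] = (("A", "B"), ("C", "D"))
    dna_chains: tuple[str, ...] = ("E", "F")
    chain_map: dict[str, str] = field(default_factory=lambda: {"A": "A", "B": "B"})
    # recognition-helix center-to-center atoms, (chain, residue, atom)
    center_atoms: tuple[tuple[str, int, str], tuple[str, int, str]] = (
        ("A", 44, "N"),
        ("B", 44, "N"),
    )
    # disulfide pairs, ((chain, residue), (chain, residue))
    disulfide_pairs: tuple[tuple[tuple[str, int], tuple[str, int]], ...] = (
        (("A", 159), ("B", 159)),
    )
    # interface selection for the apo/bound diff (residue range of the
    # dimerization helices), applied per chain of the mapped dimer
    interface_residue_range: tuple[int, int] | None = None
    # cutoffs, Å
    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    stacking_cutoff: float = STACKING_CENTROID_CUTOFF
    # SASA
    sasa_probe: float = DEFAULT_PROBE
    sasa_points: int = DEFAULT_N_POINTS
    sasa_radii: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    # disulfide strain constants, kcal/mol
    strain_constants: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRAIN_CONSTANTS)
    )
    # ITC defaults
    itc_cell_volume_ul: float = 200.0
    itc_cell_concentration_uM: float = 10.0
    itc_syringe_concentration_uM: float = 120.0
    itc_temperature_K: float = 298.15
    # misc
    output_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hbond_cutoff <= 0 or self.contact_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.sasa_points < 16:
            raise ValueError("sasa_points must be at least 16")
        all_protein = [c for d in self.protein_dimers for c in d]
        if len(set(all_protein)) != len(all_protein):
            raise ValueError("protein dimer chain assignments overlap")
        if set(all_protein) & set(self.dna_chains):
            raise ValueError("DNA chains overlap protein chains")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        data = dict(data)
        if "protein_dimers" in data:
            data["protein_dimers"] = tuple(tuple(d) for d in data["protein_dimers"])
        if "dna_chains" in data:
            data["dna_chains"] = tuple(data["dna_chains"])
        if "center_atoms" in data:
            data["center_atoms"] = tuple(tuple(a) for a in data["center_atoms"])
        if "disulfide_pairs" in data:
            data["disulfide_pairs"] = tuple(
                tuple(tuple(r) for r in pair) for pair in data["disulfide_pairs"]
            )
        if data.get("interface_residue_range") is not None:
            data["interface_residue_range"] = tuple(data["interface_residue_range"])
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
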