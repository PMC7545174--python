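"""Structural containers: labelled coordinates and the domain annotation map.

:class:`FrameCoordinates` is the package's in-memory snapshot format — flat
numpy arrays of positions, masses, element symbols and residue numbers, one
frame per object. :class:`DomainMap` describes the domain architecture of a
protein (here fibrillin-1): ordered residue ranges with a type, the six-
cysteine ordinal map of each calcium-binding EGF (cbEGF) domain, and the
calcium-coordinating residue sets. Disulfide bonds in cbEGF domains follow
the conserved C1–C3 (bond 1), C2–C4 (bond 2), C5–C6 (bond 3) pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError

__all__ = [
    "FrameCoordinates",
    "DomainEntry",
    "DomainMap",
    "CYSTEINE_BOND_OF_ORDINAL",
    "load_domain_map",
    "default_domain_map",
]

#: Conserved cbEGF disulfide pairing: cysteine ordinal -> bond number.
CYSTEINE_BOND_OF_ORDINAL = {1: 1, 2: 2, 3: 1, 4: 2, 5: 3, 6: 3}

DOMAIN_TYPES = ("EGF", "cbEGF", "TB", "hybrid", "other")


@dataclass(frozen=True)
class FrameCoordinates:
    """One structural snapshot: positions with per-atom annotation."""

    positions: np.ndarray  # (n_atoms, 3), Å
    masses: np.ndarray  # amu
    elements: np.ndarray  # element symbols, upper-case
    residue_numbers: np.ndarray  # 1-based author numbering
    atom_names: np.ndarray | None = None
    time: float = 0.0  # ns

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValidationError("positions must have shape (n_atoms, 3)")
        n = pos.shape[0]
        masses = np.asarray(self.masses, dtype=float)
        elements = np.asarray(self.elements, dtype=object)
        resnum = np.asarray(self.residue_numbers, dtype=int)
        if masses.shape != (n,) or elements.shape != (n,) or resnum.shape != (n,):
            raise ValidationError("per-atom arrays must all have length n_atoms")
        if np.any(masses < 0):
            raise ValidationError("masses must be non-negative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "masses", masses)
        object.__setattr__(
            self, "elements", np.array([str(e).upper() for e in elements], dtype=object)
        )
        object.__setattr__(self, "residue_numbers", resnum)
        if self.atom_names is not None:
            names = np.asarray(self.atom_names, dtype=object)
            if names.shape != (n,):
                raise ValidationError("atom_names must have length n_atoms")
            object.__setattr__(self, "atom_names", names)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def select_residues(self, start: int, end: int) -> np.ndarray:
        """Indices of atoms with residue number in [start, end] (inclusive)."""
        return np.flatnonzero(
            (self.residue_numbers >= start) & (self.residue_numbers <= end)
        )

    def select_element(self, symbol: str) -> np.ndarray:
        return np.flatnonzero(self.elements == symbol.upper())


@dataclass(frozen=True)
class DomainEntry:
    """One domain of the protein: an inclusive 1-based residue range."""

    name: str
    domain_type: str
    start: int
    end: int
    #: cysteine ordinal (1..6) -> residue number, for cbEGF domains
    cysteines: dict = field(default_factory=dict)
    #: residue number -> wild-type one-letter code of calcium-binding residues
    calcium_binding: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.domain_type not in DOMAIN_TYPES:
            raise ValidationError(
                f"unknown domain type {self.domain_type!r}; expected one of {DOMAIN_TYPES}"
            )
        if not (1 <= self.start <= self.end):
            raise ValidationError(f"bad residue range {self.start}..{self.end}")
        if self.cysteines:
            if self.domain_type == "cbEGF" and set(self.cysteines) != set(range(1, 7)):
                raise ValidationError(
                    f"cbEGF domain {self.name} must map exactly six cysteine ordinals"
                )
            for ordinal, pos in self.cysteines.items():
                if not (self.start <= pos <= self.end):
                    raise ValidationError(
                        f"cysteine C{ordinal}={pos} outside {self.name} range"
                    )
        for pos in self.calcium_binding:
            if not (self.start <= pos <= self.end):
                raise ValidationError(
                    f"calcium-binding residue {pos} outside {self.name} range"
                )

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def bond_of_position(self, position: int) -> int | None:
        """Disulfide bond (1, 2 or 3) the cysteine at *position* belongs to."""
        for ordinal, pos in self.cysteines.items():
            if pos == position:
                return CYSTEINE_BOND_OF_ORDINAL[ordinal]
        return None


@dataclass(frozen=True)
class DomainMap:
    """Ordered, non-overlapping domain annotation of one protein chain."""

    domains: tuple
    protein_length: int
    ligand_residues: tuple = ()
    name: str = "domain_map"

    def __post_init__(self) -> None:
        domains = tuple(self.domains)
        prev_end = 0
        for d in domains:
            if d.start <= prev_end:
                raise ValidationError(
                    f"domain {d.name} overlaps or is out of order (start {d.start})"
                )
            prev_end = d.end
        if domains and domains[-1].end > self.protein_length:
            raise ValidationError("domains extend beyond protein length")
        object.__setattr__(self, "domains", domains)

    def domain_of(self, position: int) -> DomainEntry | None:
        """Domain containing *position*, or None for inter-domain positions."""
        if not (1 <= position <= self.protein_length):
            raise ValidationError(
                f"position {position} outside protein (length {self.protein_length})"
            )
        for d in self.domains:
            if d.contains(position):
                return d
        return None

    def by_name(self, name: str) -> DomainEntry:
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(name)

    def cysteine_positions(self) -> dict:
        """position -> (domain name, ordinal, bond) over all cbEGF domains."""
        out = {}
        for d in self.domains:
            for ordinal, pos in d.cysteines.items():
                out[pos] = (d.name, ordinal, CYSTEINE_BOND_OF_ORDINAL[ordinal])
        return out

    def calcium_binding_positions(self) -> dict:
        """position -> (domain name, wild-type residue code)."""
        out = {}
        for d in self.domains:
            for pos, aa in d.calcium_binding.items():
                out[pos] = (d.name, aa)
        return out

    def residues_by_type(self) -> dict:
        """domain type -> number of residues, with 'other' absorbing gaps."""
        counts: dict = {t: 0 for t in DOMAIN_TYPES}
        covered = 0
        for d in self.domains:
            n = d.end - d.start + 1
            counts[d.domain_type] += n
            covered += n
        counts["other"] += self.protein_length - covered
        return {t: c for t, c in counts.items() if c > 0}


def load_domain_map(path: str | Path) -> DomainMap:
    """Load a :class:`DomainMap` from its YAML sidecar format."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _map_from_dict(raw, name=Path(path).stem)


def _map_from_dict(raw: dict, name: str = "domain_map") -> DomainMap:
    domains = []
    for entry in raw.get("domains", []):
        domains.append(
            DomainEntry(
                name=str(entry["name"]),
                domain_type=str(entry["type"]),
                start=int(entry["start"]),
                end=int(entry["end"]),
                cysteines={int(k): int(v) for k, v in (entry.get("cysteines") or {}).items()},
                calcium_binding={
                    int(k): str(v) for k, v in (entry.get("calcium_binding") or {}).items()
                },
            )
        )
    return DomainMap(
        domains=tuple(domains),
        protein_length=int(raw["protein_length"]),
        ligand_residues=tuple(raw.get("ligand_residues", ())),
        name=str(raw.get("name", name)),
    )


def default_domain_map() -> DomainMap:
    """The packaged fibrillin-1 map (cbEGF12/cbEGF13 annotated in detail).

    Cysteine ordinals in cbEGF12 and cbEGF13 are anchored to reported
    mutation→bond assignments; positions the literature extract does not pin
    down are representative completions, hence the 'synthetic' label in the
    data file name. Calcium-binding sets for other domains are user-supplied.
    """
    ref = resources.files("fibmech.data").joinpath("fbn1_domain_map_synthetic.yaml")
    with ref.open() as fh:
        raw = yaml.safe_load(fh)
    return _map_from_dict(raw, name="fbn1_synthetic")
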