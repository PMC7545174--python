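"""Shared data containers for work, free-energy and force profiles.

A :class:`WorkEnsemble` holds the cumulative work accumulated along a pulled
coordinate for each replicate of a nonequilibrium pulling experiment, all on
one uniform extension grid. Free energy (:class:`PMFProfile`) and force
(:class:`ForceProfile`) profiles are functions of the same grid; the strain
axis is extension divided by a reference length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE
from .errors import ValidationError

__all__ = ["WorkProfile", "WorkEnsemble", "PMFProfile", "ForceProfile"]

#: Default strain reference length, Å. The calcium-bound wild-type
#: cbEGF12-cbEGF13 pair spans ~60 Å at equilibrium, so 50% strain ≈ +30 Å.
DEFAULT_STRAIN_REFERENCE = 60.0


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValidationError("extension grid must be 1-D with >= 2 points")
    if not np.all(np.diff(grid) > 0):
        raise ValidationError("extension grid must be strictly increasing")
    return grid


@dataclass(frozen=True)
class WorkProfile:
    """Cumulative work along the pulled coordinate for one replicate.

    Parameters
    ----------
    extension : array, Å
        Strictly increasing grid starting at the unstrained length offset 0.
    work : array, kcal/mol
        Cumulative external work; ``work[0]`` must be exactly 0.
    replicate : int
        Replicate identifier within its ensemble.
    """

    extension: np.ndarray
    work: np.ndarray
    replicate: int = 0

    def __post_init__(self) -> None:
        grid = _check_grid(self.extension)
        work = np.asarray(self.work, dtype=float)
        if work.shape != grid.shape:
            raise ValidationError("work and extension must have equal length")
        if work[0] != 0.0:
            raise ValidationError(f"work must start at 0, got {work[0]!r}")
        if not np.all(np.isfinite(work)):
            raise ValidationError("work profile contains non-finite values")
        object.__setattr__(self, "extension", grid)
        object.__setattr__(self, "work", work)


@dataclass(frozen=True)
class WorkEnsemble:
    """A set of replicate work profiles on one shared extension grid."""

    extension: np.ndarray
    works: np.ndarray  # shape (n_replicates, n_grid)
    temperature: float = DEFAULT_TEMPERATURE
    strain_reference: float = DEFAULT_STRAIN_REFERENCE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = _check_grid(self.extension)
        works = np.atleast_2d(np.asarray(self.works, dtype=float))
        if works.shape[1] != grid.size:
            raise ValidationError("works must have one column per grid point")
        if works.shape[0] < 1:
            raise ValidationError("ensemble needs at least one replicate")
        if np.any(works[:, 0] != 0.0):
            raise ValidationError("every work profile must start at 0")
        if not np.all(np.isfinite(works)):
            raise ValidationError("ensemble contains non-finite work values")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.strain_reference <= 0:
            raise ValidationError("strain reference length must be positive")
        object.__setattr__(self, "extension", grid)
        object.__setattr__(self, "works", works)

    @classmethod
    def from_profiles(
        cls,
        profiles: Sequence[WorkProfile],
        temperature: float = DEFAULT_TEMPERATURE,
        strain_reference: float = DEFAULT_STRAIN_REFERENCE,
        metadata: dict | None = None,
    ) -> "WorkEnsemble":
        if not profiles:
            raise ValidationError("need at least one work profile")
        grid = profiles[0].extension
        for p in profiles[1:]:
            if not np.array_equal(p.extension, grid):
                raise ValidationError("all profiles must share one grid")
        return cls(
            extension=grid,
            works=np.vstack([p.work for p in profiles]),
            temperature=temperature,
            strain_reference=strain_reference,
            metadata=metadata or {},
        )

    @property
    def n_replicates(self) -> int:
        return self.works.shape[0]

    @property
    def strain(self) -> np.ndarray:
        """Fractional strain axis in percent: 100 · extension / L_ref."""
        return 100.0 * self.extension / self.strain_reference

    def mean_work(self) -> np.ndarray:
        return self.works.mean(axis=0)

    def profiles(self) -> list[WorkProfile]:
        return [
            WorkProfile(self.extension, w, replicate=i)
            for i, w in enumerate(self.works)
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.works.T,
            columns=[f"work_{i}" for i in range(self.n_replicates)],
        )
        df.insert(0, "extension_A", self.extension)
        return df


@dataclass(frozen=True)
class PMFProfile:
    """Potential of mean force ΔG(z) along the pulled coordinate.

    ΔG is in kcal/mol with ΔG(0) = 0; ``strain_reference`` converts the
    extension axis to percent strain.
    """

    extension: np.ndarray
    delta_g: np.ndarray
    strain_reference: float = DEFAULT_STRAIN_REFERENCE
    temperature: float = DEFAULT_TEMPERATURE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = _check_grid(self.extension)
        dg = np.asarray(self.delta_g, dtype=float)
        if dg.shape != grid.shape:
            raise ValidationError("delta_g and extension must align")
        if not np.all(np.isfinite(dg)):
            raise ValidationError("PMF contains non-finite values")
        if abs(dg[0]) > 1e-9:
            raise ValidationError("PMF must vanish at zero extension")
        object.__setattr__(self, "extension", grid)
        object.__setattr__(self, "delta_g", dg)

    @property
    def strain(self) -> np.ndarray:
        return 100.0 * self.extension / self.strain_reference

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "extension_A": self.extension,
                "strain_pct": self.strain,
                "delta_g_kcal_mol": self.delta_g,
            }
        )


@dataclass(frozen=True)
class ForceProfile:
    """Force (pN) along the pulled coordinate, derived from a PMF."""

    extension: np.ndarray
    force: np.ndarray
    strain_reference: float = DEFAULT_STRAIN_REFERENCE
    smoothing_window: float = 0.0  # Å
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = _check_grid(self.extension)
        f = np.asarray(self.force, dtype=float)
        if f.shape != grid.shape:
            raise ValidationError("force and extension must align")
        object.__setattr__(self, "extension", grid)
        object.__setattr__(self, "force", f)

    @property
    def strain(self) -> np.ndarray:
        return 100.0 * self.extension / self.strain_reference

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "extension_A": self.extension,
                "strain_pct": self.strain,
                "force_pN": self.force,
            }
        )
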