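"""Calcium-binding observables: contacts, solvent exposure, weighted averages.

Contact counting uses a strict distance cutoff (< 4.0 Å by default) between
the calcium ion and a partner-atom selection; coordination chemistry makes
oxygen atoms the default partners.

Solvent-accessible surface area (SASA) is computed with the Shrake–Rupley
construction: test points on the expanded sphere of radius r_atom + probe
are classified buried if they fall inside any neighbour's expanded sphere,
and the exposed fraction scales the analytic sphere area. The test points
come from a deterministic golden-angle (Fibonacci) lattice so results are
reproducible without randomness. The isolated calcium ion (r = 1.5 Å, probe
1.4 Å) has area 4π·2.9² = 105.7 Å², the 100% normalisation reference.

Nonequilibrium trajectories sample configurations with Boltzmann-corrected
importance given by their accumulated work; per the Jarzynski identity an
observable X is averaged as

    X̄ = Σᵢ wᵢ Xᵢ,    wᵢ = exp(−Wᵢ/kT) / Σⱼ exp(−Wⱼ/kT),

with Wᵢ the work of trajectory i at the matched strain. Weights are formed
per strain point by default (each point uses that point's works); a single
global weight per replicate, from the endpoint works, is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import softmax

from .constants import (
    CALCIUM_REFERENCE_SASA,
    CONTACT_CUTOFF,
    VDW_RADII,
    WATER_PROBE_RADIUS,
    kt,
)
from .errors import ConfigurationError, ValidationError
from .structure import FrameCoordinates
from .synthetic import _fibonacci_sphere

__all__ = [
    "count_contacts",
    "compute_sasa",
    "normalize_sasa",
    "jarzynski_weighted_average",
    "WeightedObservable",
    "bin_by_strain",
    "ContactSeries",
    "SASASeries",
    "contact_series",
    "sasa_series",
]


def count_contacts(
    frame: FrameCoordinates,
    ligand_index: int,
    partner_indices=None,
    cutoff: float = CONTACT_CUTOFF,
    partner_element: str | None = "O",
) -> int:
    """Number of partner atoms strictly closer than *cutoff* to the ligand.

    Partners default to all oxygen atoms other than the ligand; pass
    explicit ``partner_indices`` or ``partner_element=None`` (all atoms) to
    override.
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    if not (0 <= ligand_index < frame.n_atoms):
        raise ValidationError(f"ligand index {ligand_index} out of range")
    if partner_indices is None:
        if partner_element is None:
            partner_indices = np.arange(frame.n_atoms)
        else:
            partner_indices = frame.select_element(partner_element)
        partner_indices = partner_indices[partner_indices != ligand_index]
    else:
        partner_indices = np.asarray(partner_indices, dtype=int)
        if partner_indices.size == 0:
            raise ValidationError("empty partner selection")
    deltas = frame.positions[partner_indices] - frame.positions[ligand_index]
    distances = np.linalg.norm(deltas, axis=1)
    return int(np.count_nonzero(distances < cutoff))


def compute_sasa(
    frame: FrameCoordinates,
    target_index: int,
    probe: float = WATER_PROBE_RADIUS,
    n_points: int = 960,
    radii: dict | None = None,
) -> float:
    """Shrake–Rupley accessible surface area of one atom, Å².

    A deterministic Fibonacci lattice of ``n_points`` test points is placed
    on the target's expanded sphere (radius r_target + probe); points inside
    any other atom's expanded sphere are buried. The returned area is the
    exposed point fraction times 4π(r_target + probe)².
    """
    if n_points < 100:
        raise ValidationError("n_points must be at least 100 for usable quadrature")
    if probe < 0:
        raise ValidationError("probe radius must be non-negative")
    if not (0 <= target_index < frame.n_atoms):
        raise ValidationError(f"target index {target_index} out of range")

    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})

    def radius_of(element: str) -> float:
        try:
            return table[element]
        except KeyError:
            raise ConfigurationError(
                f"no van der Waals radius for element {element!r}; "
                "supply one via the radii override"
            ) from None

    centre = frame.positions[target_index]
    r_target = radius_of(frame.elements[target_index]) + probe
    points = centre + r_target * _fibonacci_sphere(n_points)

    exposed = np.ones(n_points, dtype=bool)
    for j in range(frame.n_atoms):
        if j == target_index:
            continue
        r_j = radius_of(frame.elements[j]) + probe
        d2 = np.einsum("ij,ij->i", points - frame.positions[j], points - frame.positions[j])
        exposed &= d2 >= r_j * r_j
        if not exposed.any():
            return 0.0
    fraction = exposed.mean()
    return float(fraction * 4.0 * np.pi * r_target**2)


def normalize_sasa(absolute: float, reference: float = CALCIUM_REFERENCE_SASA) -> float:
    """Absolute SASA as percent of the isolated-ion reference area.

    Clipped at 100% (with a warning) if quadrature overshoots the reference.
    """
    if absolute < 0:
        raise ValidationError("SASA must be non-negative")
    pct = 100.0 * absolute / reference
    if pct > 100.0:
        warnings.warn(
            f"normalised SASA {pct:.2f}% exceeds 100%; clipping (quadrature overshoot)",
            stacklevel=2,
        )
        pct = 100.0
    return pct


@dataclass(frozen=True)
class WeightedObservable:
    """Work-weighted ensemble average of an observable along strain."""

    strain: np.ndarray  # %
    mean: np.ndarray  # weighted average per strain point
    weights: np.ndarray  # (n_replicates, n_strain)
    temperature: float
    per_point: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"strain_pct": self.strain, "weighted_mean": self.mean})


def jarzynski_weighted_average(
    observables,
    works,
    temperature: float,
    strain=None,
    per_point: bool = True,
) -> WeightedObservable:
    """Boltzmann work-weighted average of per-replicate observable series.

    Parameters
    ----------
    observables, works : arrays of shape (n_replicates, n_strain)
        Observable readings and cumulative works at matched strain points.
    temperature : float, K
    strain : array, %, optional
        Strain axis (defaults to point indices).
    per_point : bool
        Form the weights from each strain point's works (default). With
        ``False`` a single weight per replicate is computed from the final
        column and applied everywhere.

    Weights are computed with a stable shifted exponential so arbitrarily
    large works cannot overflow; they sum to 1 at every strain point and
    the average always lies within the range of the replicate values.
    """
    obs = np.atleast_2d(np.asarray(observables, dtype=float))
    wrk = np.atleast_2d(np.asarray(works, dtype=float))
    if obs.shape != wrk.shape:
        raise ValidationError(
            f"observables {obs.shape} and works {wrk.shape} must have equal shapes"
        )
    thermal = kt(temperature)
    if per_point:
        weights = softmax(-wrk / thermal, axis=0)
    else:
        w_end = softmax(-wrk[:, -1] / thermal)
        weights = np.repeat(w_end[:, None], wrk.shape[1], axis=1)
    mean = np.sum(weights * obs, axis=0)
    axis = (
        np.asarray(strain, dtype=float)
        if strain is not None
        else np.arange(obs.shape[1], dtype=float)
    )
    if axis.shape != (obs.shape[1],):
        raise ValidationError("strain axis must match the observable columns")
    return WeightedObservable(
        strain=axis,
        mean=mean,
        weights=weights,
        temperature=temperature,
        per_point=per_point,
    )


def bin_by_strain(strain, values, edges) -> pd.DataFrame:
    """Mean of *values* in half-open strain bins [lo, hi); empty bins are NaN."""
    strain = np.asarray(strain, dtype=float)
    values = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if strain.shape != values.shape:
        raise ValidationError("strain and values must align")
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin edges must be strictly increasing")
    labels = pd.IntervalIndex.from_breaks(edges, closed="left")
    binned = pd.cut(strain, bins=labels)
    grouped = pd.Series(values).groupby(binned, observed=False).mean()
    out = pd.DataFrame(
        {
            "lo": edges[:-1],
            "hi": edges[1:],
            "mean": grouped.to_numpy(),
            "n": pd.Series(values).groupby(binned, observed=False).count().to_numpy(),
        }
    )
    if out["n"].sum() == 0:
        warnings.warn("no data points fall inside the requested bins", stacklevel=2)
    return out


@dataclass(frozen=True)
class ContactSeries:
    """Contact counts along a strain grid."""

    strain: np.ndarray  # %
    counts: np.ndarray  # int per frame
    cutoff: float
    partner_element: str | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"strain_pct": self.strain, "contacts": self.counts})


@dataclass(frozen=True)
class SASASeries:
    """Absolute and normalised ligand SASA along a strain grid."""

    strain: np.ndarray  # %
    absolute: np.ndarray  # Å²
    normalized: np.ndarray  # % of the isolated-ion reference
    probe: float
    n_points: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain_pct": self.strain,
                "sasa_A2": self.absolute,
                "sasa_pct": self.normalized,
            }
        )


def contact_series(
    frames,
    ligand_index: int,
    strain,
    cutoff: float = CONTACT_CUTOFF,
    partner_element: str | None = "O",
) -> ContactSeries:
    """Contact counts for a sequence of frames along a strain axis (%)."""
    strain = np.asarray(strain, dtype=float)
    counts = np.array(
        [
            count_contacts(
                f, ligand_index, cutoff=cutoff, partner_element=partner_element
            )
            for f in frames
        ]
    )
    return ContactSeries(
        strain=strain, counts=counts, cutoff=cutoff, partner_element=partner_element
    )


def sasa_series(
    frames,
    ligand_index: int,
    strain,
    probe: float = WATER_PROBE_RADIUS,
    n_points: int = 960,
    radii: dict | None = None,
) -> SASASeries:
    """Ligand SASA (absolute and % of reference) along a strain axis."""
    strain = np.asarray(strain, dtype=float)
    absolute = np.array(
        [
            compute_sasa(f, ligand_index, probe=probe, n_points=n_points, radii=radii)
            for f in frames
        ]
    )
    normalized = np.array([normalize_sasa(a) for a in absolute])
    return SASASeries(
        strain=strain,
        absolute=absolute,
        normalized=normalized,
        probe=probe,
        n_points=n_points,
    )
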