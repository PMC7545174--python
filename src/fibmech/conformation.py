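"""Equilibrium conformational metrics: length, straightness, stiffness.

The two-domain length is defined as twice the Euclidean distance between the
mass-weighted centres of mass of the two domains. Straightness is the
negative dot product of the unit vectors from the combined centre of mass to
each domain's centre of mass: +1 for a perfectly straight (antiparallel)
arrangement, 0 at right angles.

The apparent stiffness modulus converts equilibrium length fluctuations to
an effective force scale:

    K = kT · L / ⟨(L₀ − L)²⟩

with L₀ the instantaneous and L the mean length; larger fluctuations mean a
softer molecule. The ensemble average uses the population (1/n) variance by
default since ⟨·⟩ denotes an ensemble average; ``ddof=1`` is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import PN_PER_KCAL_PER_MOL_ANG, kt
from .errors import DegenerateGeometryError, ValidationError
from .structure import DomainMap, FrameCoordinates

__all__ = [
    "center_of_mass",
    "domain_length",
    "straightness",
    "LengthSeries",
    "StiffnessEstimate",
    "apparent_stiffness",
    "compare_means",
    "compare_variances",
]


def center_of_mass(frame: FrameCoordinates, indices: np.ndarray) -> np.ndarray:
    if len(indices) == 0:
        raise ValidationError("empty atom selection")
    masses = frame.masses[indices]
    if masses.sum() <= 0:
        raise ValidationError("selection has zero total mass")
    return np.average(frame.positions[indices], axis=0, weights=masses)


def _domain_com(frame: FrameCoordinates, dmap: DomainMap, name: str) -> np.ndarray:
    d = dmap.by_name(name)
    idx = frame.select_residues(d.start, d.end)
    if len(idx) == 0:
        raise ValidationError(f"no atoms found for domain {name}")
    return center_of_mass(frame, idx)


def domain_length(
    frame: FrameCoordinates,
    dmap: DomainMap,
    domain_a: str,
    domain_b: str,
) -> float:
    """Two-domain length: 2 × |COM(a) − COM(b)|, Å (mass-weighted COMs)."""
    com_a = _domain_com(frame, dmap, domain_a)
    com_b = _domain_com(frame, dmap, domain_b)
    return 2.0 * float(np.linalg.norm(com_a - com_b))


def straightness(
    frame: FrameCoordinates,
    dmap: DomainMap,
    domain_a: str,
    domain_b: str,
) -> float:
    """−û·v̂ with û, v̂ from the combined COM to each domain COM, in [−1, 1].

    The combined centre of mass is taken over the contiguous residue span
    covering both domains, so linker atoms between them contribute. (If the
    frame contains no atoms beyond the two domains, the combined COM lies on
    the segment joining the domain COMs and the metric is identically +1.)
    """
    a = dmap.by_name(domain_a)
    b = dmap.by_name(domain_b)
    idx_a = frame.select_residues(a.start, a.end)
    idx_b = frame.select_residues(b.start, b.end)
    com_a = center_of_mass(frame, idx_a)
    com_b = center_of_mass(frame, idx_b)
    span = frame.select_residues(min(a.start, b.start), max(a.end, b.end))
    combined = center_of_mass(frame, span)
    u = com_a - combined
    v = com_b - combined
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateGeometryError(
            "a domain centre of mass coincides with the combined centre of mass"
        )
    value = -float(np.dot(u / nu, v / nv))
    return float(np.clip(value, -1.0, 1.0))


@dataclass(frozen=True)
class LengthSeries:
    """Per-frame instantaneous lengths with summary moments."""

    lengths: np.ndarray  # Å
    temperature: float  # K

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        if lengths.ndim != 1 or lengths.size < 2:
            raise ValidationError("length series needs at least two frames")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        object.__setattr__(self, "lengths", lengths)

    @classmethod
    def from_frames(
        cls,
        frames,
        dmap: DomainMap,
        domain_a: str,
        domain_b: str,
        temperature: float,
    ) -> "LengthSeries":
        return cls(
            lengths=np.array(
                [domain_length(f, dmap, domain_a, domain_b) for f in frames]
            ),
            temperature=temperature,
        )

    @property
    def mean(self) -> float:
        return float(self.lengths.mean())

    def variance(self, ddof: int = 0) -> float:
        return float(self.lengths.var(ddof=ddof))


@dataclass(frozen=True)
class StiffnessEstimate:
    """Apparent stiffness modulus with the inputs that produced it."""

    stiffness_pn: float
    stiffness_kcal_mol_ang: float
    mean_length: float  # Å
    variance: float  # Å²
    temperature: float  # K
    ddof: int


def apparent_stiffness(series: LengthSeries, ddof: int = 0) -> StiffnessEstimate:
    """K = kT·L/⟨(L₀ − L)²⟩ from an equilibrium length series, in pN.

    ``ddof=0`` (population variance) is the default ensemble-average
    convention; ``ddof=1`` gives the unbiased sample alternative.
    """
    variance = series.variance(ddof=ddof)
    if variance <= 0:
        raise ValidationError(
            "length variance is zero: apparent stiffness is infinite "
            "(degenerate, perfectly rigid series)"
        )
    k_kcal = kt(series.temperature) * series.mean / variance
    return StiffnessEstimate(
        stiffness_pn=k_kcal * PN_PER_KCAL_PER_MOL_ANG,
        stiffness_kcal_mol_ang=k_kcal,
        mean_length=series.mean,
        variance=variance,
        temperature=series.temperature,
        ddof=ddof,
    )


def compare_means(sample_a, sample_b, pooled: bool = False):
    """Two-tailed two-sample t-test on means; Welch by default.

    Welch (unequal variances) is the default because variance equality is
    exactly what the accompanying F-test interrogates; set ``pooled=True``
    for the classical equal-variance test.

    Returns (t statistic, p-value).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least two observations")
    t, p = stats.ttest_ind(a, b, equal_var=pooled)
    return float(t), float(p)


def compare_variances(sample_a, sample_b):
    """Two-sided two-sample F-test on variances.

    F is the larger sample variance over the smaller (so F ≥ 1) with the
    corresponding (n−1, n−1) degrees of freedom; the two-sided p doubles the
    upper tail and is capped at 1. Symmetric in the sample order.

    Returns (F statistic, p-value).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least two observations")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a <= 0 or var_b <= 0:
        raise ValidationError("zero variance in a sample; F-test undefined")
    if var_a >= var_b:
        f, dfn, dfd = var_a / var_b, a.size - 1, b.size - 1
    else:
        f, dfn, dfd = var_b / var_a, b.size - 1, a.size - 1
    p = min(1.0, 2.0 * float(stats.f.sf(f, dfn, dfd)))
    return float(f), p
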