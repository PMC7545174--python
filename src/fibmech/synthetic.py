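"""Synthetic data generation: steered-Langevin pulling, toy structures, cohorts.

This module stands in for the molecular-dynamics engine and the mutation
database. It produces every input the analysis stages consume:

* nonequilibrium work ensembles from overdamped (Brownian) Langevin dynamics
  of a single pulled coordinate in an analytically tractable potential, with
  a moving harmonic steering spring — the desk-scale analogue of
  constant-velocity steered MD;
* toy bead structures of a two-domain protein with a bound calcium-like
  ligand whose binding-pocket geometry opens under strain;
* equilibrium length series with Boltzmann statistics of known variance;
* synthetic mutation cohorts with prescribed class proportions that
  re-classify exactly to their generating class.

All generators are bit-reproducible under fixed seeds. Replicate ``i`` of an
ensemble draws from ``numpy`` SeedSequence ``(master_seed, i)``, so replicate
streams are independent of the ensemble size.

Work convention: the cumulative external work is accumulated with the
left-endpoint rule, ``dW = k_s (z - x) v dt`` with the spring centre ``z``
taken at the start of each step. Analytic comparisons in the tests use the
same convention. Because the dynamics are overdamped, pulling at speed ``v``
over distance ``d`` dissipates ``≈ γ v d`` even in the stiff-spring limit;
quasi-static behaviour therefore means choosing ``γ v d ≪ kT``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, kt
from .errors import ConfigurationError, ValidationError
from .profiles import DEFAULT_STRAIN_REFERENCE, WorkEnsemble, WorkProfile, PMFProfile
from .structure import DomainEntry, DomainMap, FrameCoordinates

__all__ = [
    "PotentialSpec",
    "SteeringProtocol",
    "LangevinConfig",
    "ToyStructure",
    "SyntheticCohortSpec",
    "simulate_steered_trajectory",
    "generate_work_ensemble",
    "analytic_pmf",
    "build_toy_structure",
    "generate_toy_conformations",
    "simulate_length_series",
    "equilibrium_length_ensemble",
    "generate_mutation_cohort",
    "COHORT_CLASSES",
    "largest_remainder_counts",
]

# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class PotentialSpec:
    """Analytic 1-D background potential sampled by the pulled coordinate.

    kinds
    -----
    ``flat``
        U = 0 everywhere.
    ``harmonic``
        U = ½ κ (x − x₀)², κ = ``stiffness`` (kcal/mol/Å²).
    ``double_well``
        Quartic with minima at x₀ and x₀ + ``well_separation`` and barrier
        ``barrier_height`` (kcal/mol) at the midpoint:
        U = 16 b u² (u − s)² / s⁴ with u = x − x₀.
    """

    kind: str
    stiffness: float = 1.0
    barrier_height: float = 0.0
    well_separation: float = 1.0
    reference_position: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "harmonic", "double_well"):
            raise ValidationError(f"unknown potential kind {self.kind!r}")
        if self.kind == "harmonic" and self.stiffness <= 0:
            raise ValidationError("harmonic stiffness must be positive")
        if self.kind == "double_well":
            if self.barrier_height < 0:
                raise ValidationError("barrier height must be non-negative")
            if self.well_separation <= 0:
                raise ValidationError("well separation must be positive")

    def energy(self, x):
        """Potential energy at absolute position(s) *x*, kcal/mol."""
        u = np.asarray(x, dtype=float) - self.reference_position
        if self.kind == "flat":
            return np.zeros_like(u)
        if self.kind == "harmonic":
            return 0.5 * self.stiffness * u**2
        s, b = self.well_separation, self.barrier_height
        return 16.0 * b * u**2 * (u - s) ** 2 / s**4

    def force(self, x):
        """−dU/dx at absolute position(s) *x*, kcal/mol/Å."""
        u = np.asarray(x, dtype=float) - self.reference_position
        if self.kind == "flat":
            return np.zeros_like(u)
        if self.kind == "harmonic":
            return -self.stiffness * u
        s, b = self.well_separation, self.barrier_height
        return -(16.0 * b / s**4) * (4.0 * u**3 - 6.0 * s * u**2 + 2.0 * s**2 * u)

    def curvature_bound(self, span: float = 0.0) -> float:
        """Upper bound on |U''| over [x₀, x₀ + span] for stability checks."""
        if self.kind == "flat":
            return 0.0
        if self.kind == "harmonic":
            return self.stiffness
        s, b = self.well_separation, self.barrier_height

        def curv(u):
            return abs((16.0 * b / s**4) * (12.0 * u**2 - 12.0 * s * u + 2.0 * s**2))

        # |U''| is a convex parabola in u: extrema at interval endpoints.
        return max(curv(0.0), curv(max(span, s)))


@dataclass(frozen=True)
class SteeringProtocol:
    """Constant-velocity steering protocol of the moving harmonic spring.

    Defaults follow the standard pulling setup: spring constant 7.4
    kcal/mol/Å², pull speed 0.1 Å/ns, 30 Å stretch, 100 kcal/mol/Å²
    terminal restraint. The terminal restraint is recorded for provenance
    only: the 1-D reduced model pulls the relative end-to-end coordinate, so
    the anchored terminus is implicit.
    """

    spring_constant: float = 7.4
    pull_speed: float = 0.1
    total_distance: float = 30.0
    terminal_restraint: float = 100.0
    output_interval: float = 10.0  # ns between recorded grid points

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValidationError("spring constant must be positive")
        if self.pull_speed <= 0:
            raise ValidationError("pull speed must be positive")
        if self.total_distance <= 0:
            raise ValidationError("total distance must be positive")
        if self.output_interval <= 0:
            raise ValidationError("output interval must be positive")
        n = self.total_distance / (self.pull_speed * self.output_interval)
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValidationError(
                "total_distance must be an integer multiple of "
                "pull_speed * output_interval"
            )

    @property
    def grid_spacing(self) -> float:
        """Extension grid spacing, Å (= pull_speed × output_interval)."""
        return self.pull_speed * self.output_interval

    @property
    def n_outputs(self) -> int:
        return round(self.total_distance / self.grid_spacing)

    @property
    def extension_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.total_distance, self.n_outputs + 1)


@dataclass(frozen=True)
class LangevinConfig:
    """Overdamped Langevin integration parameters.

    ``friction`` γ is the damping coefficient in kcal·ns/(mol·Å²), so the
    diffusion constant is kT/γ. Euler–Maruyama integration of a harmonic
    force of stiffness k is stable for dt < 2γ/k; this package enforces the
    conservative documented bound dt ≤ 0.2 γ / k_eff (checked against the
    combined spring-plus-potential stiffness when a simulation is launched,
    since the potential is not known at construction time).
    """

    temperature: float = DEFAULT_TEMPERATURE
    friction: float = 1.0
    timestep: float = 0.001  # ns
    seed: int = 0
    n_replicates: int = 100

    #: stability safety factor in dt ≤ factor · γ / k_eff
    STABILITY_FACTOR = 0.2

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValidationError("temperature must be non-negative")
        if self.friction <= 0:
            raise ValidationError("friction must be positive")
        if self.timestep <= 0:
            raise ValidationError("timestep must be positive")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")

    def check_stability(self, effective_stiffness: float) -> None:
        bound = self.STABILITY_FACTOR * self.friction / max(effective_stiffness, 1e-300)
        if self.timestep > bound:
            raise ConfigurationError(
                f"timestep {self.timestep} ns exceeds stability bound "
                f"{bound:.3g} ns (= {self.STABILITY_FACTOR} γ/k_eff with "
                f"k_eff = {effective_stiffness:.3g} kcal/mol/Å²)"
            )


# ---------------------------------------------------------------------------
# steered-Langevin simulation


def _replicate_rng(master_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((master_seed, index)))


def _simulate_many(
    potential: PotentialSpec,
    steer: SteeringProtocol,
    cfg: LangevinConfig,
    n_traj: int,
):
    """Integrate *n_traj* replicates simultaneously.

    Returns (extension grid, positions (n_out+1, n), works (n_out+1, n)).
    Each replicate consumes its own RNG stream, so results are independent
    of how many replicates run together.
    """
    dt = cfg.timestep
    gamma = cfg.friction
    k_s = steer.spring_constant
    v = steer.pull_speed
    ref = potential.reference_position

    k_eff = k_s + potential.curvature_bound(span=steer.total_distance)
    cfg.check_stability(k_eff)

    steps_per_out = steer.output_interval / dt
    if abs(steps_per_out - round(steps_per_out)) > 1e-9:
        raise ValidationError("output_interval must be an integer multiple of timestep")
    steps_per_out = round(steps_per_out)
    n_out = steer.n_outputs
    total_steps = n_out * steps_per_out

    temperature = cfg.temperature
    thermal = kt(temperature) if temperature > 0 else 0.0
    amp = math.sqrt(2.0 * thermal * dt / gamma)

    rngs = [_replicate_rng(cfg.seed, i) for i in range(n_traj)]

    # initial state: equilibrium of the combined trap+potential around the
    # local minimum (exact for harmonic backgrounds, local-curvature
    # approximation otherwise); deterministic at T = 0.
    if thermal > 0:
        local_curv = k_s + max(_local_curvature(potential), 0.0)
        sigma0 = math.sqrt(thermal / local_curv)
        x = np.array([ref + sigma0 * rng.standard_normal() for rng in rngs])
    else:
        x = np.full(n_traj, ref, dtype=float)

    work = np.zeros(n_traj)
    positions = np.empty((n_out + 1, n_traj))
    works = np.empty((n_out + 1, n_traj))
    positions[0] = x
    works[0] = 0.0

    chunk = max(1, min(total_steps, 2_000_000 // max(n_traj, 1)))
    centre = ref  # spring centre, advances at speed v
    step = 0
    out = 1
    while step < total_steps:
        m = min(chunk, total_steps - step)
        if amp > 0:
            noise = np.stack([rng.standard_normal(m) for rng in rngs], axis=1)
        else:
            noise = None
        for j in range(m):
            displacement = centre - x
            work += k_s * displacement * v * dt  # left-endpoint rule
            drift = (potential.force(x) + k_s * displacement) * (dt / gamma)
            if noise is not None:
                x = x + drift + amp * noise[j]
            else:
                x = x + drift
            centre += v * dt
            step += 1
            if step % steps_per_out == 0:
                positions[out] = x
                works[out] = work
                out += 1
    return steer.extension_grid, positions, works


def _local_curvature(potential: PotentialSpec) -> float:
    if potential.kind == "harmonic":
        return potential.stiffness
    if potential.kind == "double_well":
        s, b = potential.well_separation, potential.barrier_height
        return 32.0 * b / s**2  # curvature in either well
    return 0.0


def simulate_steered_trajectory(
    potential: PotentialSpec,
    steer: SteeringProtocol,
    cfg: LangevinConfig,
):
    """Run one steered-Langevin trajectory.

    Returns
    -------
    positions : ndarray
        Pulled-coordinate positions sampled on the steering grid
        (including the initial point), Å.
    work : WorkProfile
        Cumulative external work on the same grid, starting at exactly 0.
    """
    grid, positions, works = _simulate_many(potential, steer, cfg, n_traj=1)
    return positions[:, 0], WorkProfile(grid, works[:, 0], replicate=0)


def generate_work_ensemble(
    potential: PotentialSpec,
    steer: SteeringProtocol,
    cfg: LangevinConfig,
    strain_reference: float = DEFAULT_STRAIN_REFERENCE,
) -> WorkEnsemble:
    """Generate ``cfg.n_replicates`` independent work profiles on one grid."""
    if cfg.temperature <= 0:
        raise ValidationError("ensemble generation requires positive temperature")
    grid, _, works = _simulate_many(potential, steer, cfg, n_traj=cfg.n_replicates)
    return WorkEnsemble(
        extension=grid,
        works=works.T,
        temperature=cfg.temperature,
        strain_reference=strain_reference,
        metadata={
            "potential": potential.kind,
            "spring_constant": steer.spring_constant,
            "pull_speed": steer.pull_speed,
            "total_distance": steer.total_distance,
            "output_interval": steer.output_interval,
            "friction": cfg.friction,
            "timestep": cfg.timestep,
            "seed": cfg.seed,
            "n_replicates": cfg.n_replicates,
        },
    )


def analytic_pmf(
    potential: PotentialSpec,
    steer: SteeringProtocol,
    grid: Iterable[float] | None = None,
    strain_reference: float = DEFAULT_STRAIN_REFERENCE,
) -> PMFProfile:
    """Exact stiff-spring reference profile: U(x₀ + z) − U(x₀), ΔG(0) = 0.

    Serves as the ground-truth oracle for the work-based estimator; in the
    stiff-spring regime the reconstructed PMF approaches the background
    potential evaluated along the pulled coordinate.
    """
    if grid is None:
        grid = steer.extension_grid
    grid = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid, float)
    ref = potential.reference_position
    dg = potential.energy(ref + grid) - potential.energy(ref)
    return PMFProfile(
        extension=grid,
        delta_g=dg,
        strain_reference=strain_reference,
        metadata={"source": "analytic", "potential": potential.kind},
    )


def harmonic_benchmark(
    seed: int = 1,
    n_replicates: int = 100,
    pull_speed: float = 0.1,
):
    """Desk-scale quasi-static pulling benchmark with known ground truth.

    A harmonic background (κ = 1 kcal/mol/Å²) pulled 5 Å by a stiff spring
    (k_s = 100 kcal/mol/Å², a spring constant the stiff-spring literature
    validates) at 0.1 Å/ns with unit friction dissipates ≈ γvd = 0.5
    kcal/mol ≈ 0.84 kT — near-quasi-static, so the Jarzynski estimate
    should recover ½κz² closely. Returns (potential, steering, config).
    """
    potential = PotentialSpec(kind="harmonic", stiffness=1.0)
    steer = SteeringProtocol(
        spring_constant=100.0,
        pull_speed=pull_speed,
        total_distance=5.0,
        output_interval=0.1 / pull_speed,  # 0.1 Å grid spacing at any speed
    )
    cfg = LangevinConfig(
        temperature=DEFAULT_TEMPERATURE,
        friction=1.0,
        timestep=0.001,
        seed=seed,
        n_replicates=n_replicates,
    )
    return potential, steer, cfg


# ---------------------------------------------------------------------------
# toy two-domain structures


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit vectors (golden-angle lattice)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass(frozen=True)
class ToyStructure:
    """Two-domain bead model with a bound calcium-like ligand.

    The ligand sits at the origin surrounded by "oxygen" beads of the
    binding pocket placed on a sphere of ``contact_radius``. A per-bead
    strain gain controls how each bead's radial distance grows with the
    strain parameter (β-hairpin beads move, N-terminal-loop beads stay by
    default), and the second domain's centre of mass separates linearly with
    strain — the minimal geometry that reproduces strain-dependent contact
    loss and solvent exposure.
    """

    positions: np.ndarray
    masses: np.ndarray
    elements: np.ndarray
    residue_numbers: np.ndarray
    domain_map: DomainMap
    ligand_index: int
    pocket_indices: np.ndarray
    strain_gains: np.ndarray  # per pocket bead
    domain_b_indices: np.ndarray
    base_separation: float
    strain_parameter: float = 0.0

    def at_strain(self, strain: float) -> FrameCoordinates:
        """Frame with pocket radii and domain separation scaled by strain."""
        if strain < 0:
            raise ValidationError("strain must be non-negative")
        pos = self.positions.copy()
        ligand = self.positions[self.ligand_index]
        for idx, gain in zip(self.pocket_indices, self.strain_gains):
            rel = self.positions[idx] - ligand
            pos[idx] = ligand + rel * (1.0 + gain * strain)
        shift = np.array([0.0, 0.0, self.base_separation * strain])
        pos[self.domain_b_indices] += shift
        return FrameCoordinates(
            positions=pos,
            masses=self.masses,
            elements=self.elements,
            residue_numbers=self.residue_numbers,
            time=float(strain),
        )

    def com_separation(self, strain: float = 0.0) -> float:
        frame = self.at_strain(strain)
        a = self.domain_map.domains[0]
        b = self.domain_map.domains[1]
        ia = frame.select_residues(a.start, a.end)
        ib = frame.select_residues(b.start, b.end)
        com_a = np.average(frame.positions[ia], axis=0, weights=frame.masses[ia])
        com_b = np.average(frame.positions[ib], axis=0, weights=frame.masses[ib])
        return float(np.linalg.norm(com_a - com_b))


_MASS = {"O": 16.0, "C": 12.0, "N": 14.0, "CA": 40.08}

#: Residue number assigned to the ligand bead in toy structures.
TOY_LIGAND_RESIDUE = 999


def build_toy_structure(
    n_contacts: int = 8,
    n_hairpin: int = 4,
    contact_radius: float = 2.4,
    radius_spread: float = 0.3,
    hairpin_gain: float = 1.0,
    loop_gain: float = 0.0,
    n_core: int = 6,
    core_radius: float = 6.0,
    base_separation: float = 30.0,
) -> ToyStructure:
    """Construct the default toy cbEGF-like bead pair.

    ``n_contacts`` oxygen beads sit around the ligand at radii staggered by
    ``radius_spread`` about ``contact_radius`` (all < 4 Å initially, so
    beads release one by one as strain grows); the first ``n_hairpin`` of
    them are β-hairpin beads whose radii scale as (1 + hairpin_gain ·
    strain). Two carbon-bead domains provide centres of mass
    ``base_separation`` apart at zero strain (domain length = 2 ×
    separation = 60 Å by default, the calcium-bound equilibrium scale).
    """
    if not (0 <= n_hairpin <= n_contacts):
        raise ValidationError("n_hairpin must lie in [0, n_contacts]")
    if contact_radius <= 0 or core_radius <= 0 or base_separation <= 0:
        raise ValidationError("radii and separation must be positive")
    if not (0 <= radius_spread < 1):
        raise ValidationError("radius_spread must lie in [0, 1)")

    pocket_dirs = _fibonacci_sphere(n_contacts)
    if n_contacts > 1:
        radii = contact_radius * (
            1.0 + radius_spread * np.linspace(-0.5, 0.5, n_contacts)
        )
    else:
        radii = np.full(n_contacts, contact_radius)
    pocket = pocket_dirs * radii[:, None]
    core_a = _fibonacci_sphere(n_core) * core_radius
    core_b = _fibonacci_sphere(n_core) * core_radius + np.array(
        [0.0, 0.0, base_separation]
    )
    ligand = np.zeros((1, 3))

    positions = np.vstack([pocket, core_a, core_b, ligand])
    elements = np.array(
        ["O"] * n_contacts + ["C"] * n_core + ["C"] * n_core + ["CA"], dtype=object
    )
    masses = np.array([_MASS[e] for e in elements])
    # one residue per bead: pocket+core_a are domain A, core_b is domain B
    n_a = n_contacts + n_core
    residue_numbers = np.concatenate(
        [
            np.arange(1, n_a + 1),
            np.arange(n_a + 1, n_a + n_core + 1),
            [TOY_LIGAND_RESIDUE],
        ]
    )
    domain_map = DomainMap(
        domains=(
            DomainEntry("domA", "cbEGF", 1, n_a),
            DomainEntry("domB", "cbEGF", n_a + 1, n_a + n_core),
        ),
        protein_length=TOY_LIGAND_RESIDUE,
        ligand_residues=(TOY_LIGAND_RESIDUE,),
        name="toy_pair",
    )
    gains = np.array(
        [hairpin_gain] * n_hairpin + [loop_gain] * (n_contacts - n_hairpin)
    )
    return ToyStructure(
        positions=positions,
        masses=masses,
        elements=elements,
        residue_numbers=residue_numbers,
        domain_map=domain_map,
        ligand_index=len(positions) - 1,
        pocket_indices=np.arange(n_contacts),
        strain_gains=gains,
        domain_b_indices=np.arange(n_a, n_a + n_core),
        base_separation=base_separation,
    )


def generate_toy_conformations(
    base: ToyStructure,
    strain_grid: Sequence[float],
    noise: float = 0.0,
    seed: int = 0,
) -> list[FrameCoordinates]:
    """Frames of *base* along a strain grid, optionally with positional noise.

    The grid must be non-decreasing and start at 0; negative strains are
    rejected. With zero noise, contact counts are non-increasing and ligand
    solvent exposure non-decreasing along the grid by construction. Gaussian
    noise of the given amplitude (Å) is added to every non-ligand bead.
    """
    grid = np.asarray(strain_grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("strain grid must be non-empty")
    if np.any(grid < 0):
        raise ValidationError("strain must be non-negative")
    if grid[0] != 0.0:
        raise ValidationError("strain grid must start at 0")
    if np.any(np.diff(grid) < 0):
        raise ValidationError("strain grid must be non-decreasing")
    if noise < 0:
        raise ValidationError("noise amplitude must be non-negative")

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0)))
    frames = []
    for s in grid:
        frame = base.at_strain(float(s))
        if noise > 0:
            jitter = rng.standard_normal(frame.positions.shape) * noise
            jitter[base.ligand_index] = 0.0
            frame = FrameCoordinates(
                positions=frame.positions + jitter,
                masses=frame.masses,
                elements=frame.elements,
                residue_numbers=frame.residue_numbers,
                time=frame.time,
            )
        frames.append(frame)
    return frames


# ---------------------------------------------------------------------------
# equilibrium length fluctuations


def simulate_length_series(
    mean_length: float,
    stiffness: float,
    cfg: LangevinConfig,
    n_frames: int = 2000,
    burn_in_fraction: float = 0.5,
    replicate: int = 0,
) -> np.ndarray:
    """Ornstein–Uhlenbeck length series with stationary variance kT/κ_eff.

    Emulates equilibrium sampling of the instantaneous two-domain length:
    relaxation toward ``mean_length`` at rate κ_eff/γ plus thermal noise.
    The first ``burn_in_fraction`` of frames is discarded, mirroring the
    discard-first-half convention of equilibrium trajectory analysis.
    """
    if mean_length <= 0 or stiffness <= 0:
        raise ValidationError("mean length and stiffness must be positive")
    if not (0 <= burn_in_fraction < 1):
        raise ValidationError("burn_in_fraction must be in [0, 1)")
    if n_frames < 2:
        raise ValidationError("need at least two frames")
    cfg.check_stability(stiffness)
    thermal = kt(cfg.temperature) if cfg.temperature > 0 else 0.0
    dt, gamma = cfg.timestep, cfg.friction
    amp = math.sqrt(2.0 * thermal * dt / gamma)
    rng = _replicate_rng(cfg.seed, replicate)

    total = int(n_frames / (1.0 - burn_in_fraction)) + 1
    noise = rng.standard_normal(total)
    # deviation recursion d_i = (1 - κΔt/γ) d_{i-1} + amp ξ_i as a linear filter
    from scipy.signal import lfilter

    decay = 1.0 - stiffness * dt / gamma
    deviations = lfilter([amp], [1.0, -decay], noise)
    series = mean_length + deviations
    return series[total - n_frames :]


def equilibrium_length_ensemble(
    mean_length: float,
    stiffness: float,
    cfg: LangevinConfig,
    n_frames: int = 2000,
    burn_in_fraction: float = 0.5,
) -> list[np.ndarray]:
    """Independent equilibrium length replicates (``cfg.n_replicates`` of them)."""
    return [
        simulate_length_series(
            mean_length, stiffness, cfg, n_frames, burn_in_fraction, replicate=i
        )
        for i in range(cfg.n_replicates)
    ]


# ---------------------------------------------------------------------------
# synthetic mutation cohorts

COHORT_CLASSES = (
    "calcium_binding",
    "cysteine_bond1",
    "cysteine_bond2",
    "cysteine_bond3",
    "other",
)

_NON_CYS_AA = "ADEFGHIKLMNPQRSTVWY"
_CYS_SUBSTITUTIONS = "RYSGWF"


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Prescription for a synthetic mutation-record table.

    ``counts`` gives the number of records per disease label;
    ``proportions`` gives, per label, the class mix over
    :data:`COHORT_CLASSES` (each mix must sum to 1). Labels without an
    explicit mix default to all-``other`` records, which is the natural
    choice for excluded/unknown disease labels.
    """

    counts: dict
    proportions: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n in self.counts.items():
            if n < 0:
                raise ValidationError(f"negative count for label {label!r}")
        for label, mix in self.proportions.items():
            unknown = set(mix) - set(COHORT_CLASSES)
            if unknown:
                raise ValidationError(f"unknown classes {unknown} for {label!r}")
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"class proportions for {label!r} sum to {total}, not 1"
                )


def largest_remainder_counts(n: int, proportions: dict) -> dict:
    """Apportion *n* into integer class counts by largest remainder.

    Floors ``p·n`` per class, then hands out the remaining units in order of
    decreasing fractional remainder (ties broken by class order), so the
    counts always sum exactly to *n*.
    """
    quotas = {c: proportions.get(c, 0.0) * n for c in COHORT_CLASSES}
    counts = {c: int(math.floor(q)) for c, q in quotas.items()}
    leftover = n - sum(counts.values())
    remainders = sorted(
        COHORT_CLASSES,
        key=lambda c: (-(quotas[c] - counts[c]), COHORT_CLASSES.index(c)),
    )
    for c in remainders[:leftover]:
        counts[c] += 1
    return counts


def generate_mutation_cohort(
    spec: SyntheticCohortSpec,
    domain_map: DomainMap,
) -> pd.DataFrame:
    """Synthetic mutation-record table with exact class counts per label.

    Every generated record re-classifies to its generating class under
    the residue classifier applied with the same *domain_map* (round-trip
    identity): calcium-binding records sit on annotated calcium ligands,
    cysteine records on the annotated cysteine of the requested bond, and
    ``other`` records on positions outside both sets with a non-cysteine
    wild-type residue.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    ca_positions = sorted(domain_map.calcium_binding_positions().items())
    cys_by_bond: dict = {1: [], 2: [], 3: []}
    for pos, (_, _, bond) in sorted(domain_map.cysteine_positions().items()):
        cys_by_bond[bond].append(pos)
    special = {p for p, _ in ca_positions} | {
        p for positions in cys_by_bond.values() for p in positions
    }
    plain_positions = np.array(
        [p for p in range(1, domain_map.protein_length + 1) if p not in special]
    )

    rows = []
    rec = 0
    for label in spec.counts:
        n = spec.counts[label]
        mix = spec.proportions.get(label, {"other": 1.0})
        counts = largest_remainder_counts(n, mix)
        for cls in COHORT_CLASSES:
            for _ in range(counts[cls]):
                rec += 1
                if cls == "calcium_binding":
                    if not ca_positions:
                        raise ValidationError(
                            "domain map has no calcium-binding residues"
                        )
                    pos, (_, wt) = ca_positions[rng.integers(len(ca_positions))]
                    mut = _random_substitution(rng, wt)
                elif cls.startswith("cysteine_bond"):
                    bond = int(cls[-1])
                    if not cys_by_bond[bond]:
                        raise ValidationError(
                            f"domain map has no cysteines for bond {bond}"
                        )
                    pos = cys_by_bond[bond][rng.integers(len(cys_by_bond[bond]))]
                    wt = "C"
                    mut = _CYS_SUBSTITUTIONS[rng.integers(len(_CYS_SUBSTITUTIONS))]
                else:
                    pos = int(plain_positions[rng.integers(len(plain_positions))])
                    wt = _NON_CYS_AA[rng.integers(len(_NON_CYS_AA))]
                    mut = _random_substitution(rng, wt)
                rows.append(
                    {
                        "id": f"rec{rec:05d}",
                        "position": int(pos),
                        "wt_aa": wt,
                        "mut_aa": mut,
                        "disease": label,
                    }
                )
    df = pd.DataFrame(rows, columns=["id", "position", "wt_aa", "mut_aa", "disease"])
    return df


def _random_substitution(rng: np.random.Generator, wt: str) -> str:
    choices = [a for a in _NON_CYS_AA if a != wt]
    return choices[rng.integers(len(choices))]
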