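"""File formats, run configuration and the end-to-end pipeline.

Tables travel as TSV with ``#key=value`` metadata header lines ('.' decimal
separator, tab delimiter). Writers always record a ``units`` entry; readers
refuse unit-less files unless told to assume them. Structures travel as
standard PDB via biotite. Every pipeline output carries provenance metadata
(config hash, master seed, package version), and identical config + seed
reproduce numerically identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

try:  # package version for provenance stamps
    from importlib.metadata import version as _pkg_version

    _VERSION = _pkg_version("fibmech")
except Exception:  # pragma: no cover - editable/dev installs without metadata
    _VERSION = "unknown"

from . import binding, conformation, mutations, pmf as pmf_mod, synthetic
from .errors import ValidationError
from .profiles import ForceProfile, PMFProfile, WorkEnsemble
from .structure import FrameCoordinates

logger = logging.getLogger("fibmech")

__all__ = [
    "write_table",
    "read_table",
    "write_work_ensemble",
    "read_work_ensemble",
    "write_profile",
    "read_pmf_profile",
    "read_pdb",
    "write_pdb",
    "RunConfig",
    "run_pipeline",
]

_ELEMENT_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "CA": 40.078,
    "NA": 22.990,
    "MG": 24.305,
}


# ---------------------------------------------------------------------------
# TSV with metadata header


def write_table(df: pd.DataFrame, path, metadata: dict) -> None:
    """Write a TSV with ``#key=value`` metadata lines; ``units`` is required."""
    if "units" not in metadata:
        raise ValidationError("table metadata must declare 'units'")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key in sorted(metadata):
            fh.write(f"#{key}={metadata[key]}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path, assume_units: bool = False):
    """Read a metadata-headed TSV. Returns (DataFrame, metadata dict)."""
    metadata: dict = {}
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].rstrip("\n").partition("=")
                metadata[key] = value
            else:
                body.append(line)
    if "units" not in metadata and not assume_units:
        raise ValidationError(
            f"{path}: no units declared in metadata; pass assume_units=True to accept"
        )
    df = pd.read_csv(_io.StringIO("".join(body)), sep="\t")
    return df, metadata


def write_work_ensemble(ensemble: WorkEnsemble, path, extra_metadata=None) -> None:
    metadata = {
        "units": "extension_A:angstrom work:kcal/mol",
        "temperature_K": ensemble.temperature,
        "strain_reference_A": ensemble.strain_reference,
        "n_replicates": ensemble.n_replicates,
        **{f"protocol_{k}": v for k, v in ensemble.metadata.items()},
        **(extra_metadata or {}),
    }
    write_table(ensemble.to_frame(), path, metadata)


def read_work_ensemble(path, assume_units: bool = False) -> WorkEnsemble:
    df, metadata = read_table(path, assume_units=assume_units)
    work_cols = [c for c in df.columns if c.startswith("work_")]
    if "extension_A" not in df.columns or not work_cols:
        raise ValidationError(f"{path}: not a work-ensemble table")
    return WorkEnsemble(
        extension=df["extension_A"].to_numpy(),
        works=df[work_cols].to_numpy().T,
        temperature=float(metadata.get("temperature_K", 300.0)),
        strain_reference=float(metadata.get("strain_reference_A", 60.0)),
        metadata={
            k.removeprefix("protocol_"): _maybe_number(v)
            for k, v in metadata.items()
            if k.startswith("protocol_")
        },
    )


def _maybe_number(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except (TypeError, ValueError):
            continue
    return value


def write_profile(profile, path, extra_metadata=None) -> None:
    """Write a PMF or force profile as metadata-headed TSV."""
    if isinstance(profile, PMFProfile):
        units = "extension_A:angstrom strain_pct:percent delta_g_kcal_mol:kcal/mol"
    elif isinstance(profile, ForceProfile):
        units = "extension_A:angstrom strain_pct:percent force_pN:piconewton"
    else:
        raise ValidationError(f"unsupported profile type {type(profile).__name__}")
    metadata = {
        "units": units,
        "strain_reference_A": profile.strain_reference,
        **(extra_metadata or {}),
    }
    write_table(profile.to_frame(), path, metadata)


def read_pmf_profile(path, assume_units: bool = False) -> PMFProfile:
    df, metadata = read_table(path, assume_units=assume_units)
    return PMFProfile(
        extension=df["extension_A"].to_numpy(),
        delta_g=df["delta_g_kcal_mol"].to_numpy(),
        strain_reference=float(metadata.get("strain_reference_A", 60.0)),
    )


# ---------------------------------------------------------------------------
# PDB


def read_pdb(path) -> list[FrameCoordinates]:
    """Read a (possibly multi-model) PDB file into one frame per model.

    Residue numbering is preserved as written. Missing element columns are
    inferred from atom names with a warning.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    frames = []
    elements = np.array([e.upper() for e in stack.element], dtype=object)
    blank = elements == ""
    if blank.any():
        logger.warning(
            "%s: %d atoms lack an element column; inferring from atom names",
            path,
            int(blank.sum()),
        )
        inferred = [
            "".join(c for c in name if c.isalpha())[:1].upper()
            for name in stack.atom_name[blank]
        ]
        elements[blank] = inferred
    masses = np.array([_ELEMENT_MASS.get(e, 12.0) for e in elements])
    for model_idx in range(stack.stack_depth()):
        arr = stack[model_idx]
        frames.append(
            FrameCoordinates(
                positions=np.asarray(arr.coord, dtype=float),
                masses=masses,
                elements=elements,
                residue_numbers=np.asarray(arr.res_id, dtype=int),
                atom_names=np.asarray(arr.atom_name, dtype=object),
                time=float(model_idx),
            )
        )
    return frames


def write_pdb(frames, path) -> None:
    """Write one or more frames as a standard (multi-model) PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if isinstance(frames, FrameCoordinates):
        frames = [frames]
    n = frames[0].n_atoms
    template = struc.AtomArray(n)
    template.coord = frames[0].positions.astype(np.float32)
    template.res_id = frames[0].residue_numbers
    template.chain_id = np.full(n, "A", dtype="U4")
    template.element = np.array(
        [e[:2].upper() for e in frames[0].elements], dtype="U2"
    )
    hetero = template.element == "CA"
    template.hetero = hetero
    template.res_name = np.where(hetero, "CA", "TOY").astype("U5")
    if frames[0].atom_names is not None:
        template.atom_name = np.asarray(frames[0].atom_names, dtype="U6")
    else:
        template.atom_name = np.array(
            [f"{e}{i + 1}" for i, e in enumerate(template.element)], dtype="U6"
        )
    arrays = []
    for frame in frames:
        arr = template.copy()
        arr.coord = frame.positions.astype(np.float32)
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Parameters for an end-to-end synthetic pipeline run.

    Defaults mirror the standard pulling protocol: 300 K, spring constant
    7.4 kcal/mol/Å², pull speed 0.1 Å/ns, 100 replicates, 10 ns smoothing
    window, 4.0 Å contact cutoff, 1.4 Å probe.
    """

    outdir: str = "fibmech_run"
    seed: int = 0
    stages: tuple = ("simulate", "pmf", "metrics", "observables", "mutstats")
    # steering / dynamics
    temperature: float = 300.0
    spring_constant: float = 7.4
    pull_speed: float = 0.1
    total_distance: float = 30.0
    terminal_restraint: float = 100.0
    output_interval: float = 10.0
    friction: float = 1.0
    timestep: float = 0.01
    n_replicates: int = 100
    potential_kind: str = "harmonic"
    potential_stiffness: float = 0.05
    barrier_height: float = 5.0
    well_separation: float = 10.0
    strain_reference: float = 60.0
    window_ns: float = 10.0
    # metrics
    mean_length: float = 60.0
    length_stiffness: float = 1.0
    n_length_replicates: int = 10
    frames_per_replicate: int = 2000
    burn_in_fraction: float = 0.5
    # observables
    contact_cutoff: float = 4.0
    probe_radius: float = 1.4
    sasa_points: int = 960
    n_contacts: int = 8
    n_hairpin: int = 8
    per_point_weights: bool = True
    # mutation stats
    records_csv: str | None = None
    ensemble_path: str | None = None  # reuse a stored ensemble for stage 'pmf'
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        return out

    def config_hash(self) -> str:
        """Hash over the scientific parameters (paths and logging excluded)."""
        payload = {
            k: v
            for k, v in self.to_dict().items()
            if k not in ("outdir", "log_level")
        }
        return hashlib.sha1(
            yaml.safe_dump(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    def potential(self) -> synthetic.PotentialSpec:
        return synthetic.PotentialSpec(
            kind=self.potential_kind,
            stiffness=self.potential_stiffness,
            barrier_height=self.barrier_height,
            well_separation=self.well_separation,
        )

    def steering(self) -> synthetic.SteeringProtocol:
        return synthetic.SteeringProtocol(
            spring_constant=self.spring_constant,
            pull_speed=self.pull_speed,
            total_distance=self.total_distance,
            terminal_restraint=self.terminal_restraint,
            output_interval=self.output_interval,
        )

    def langevin(self) -> synthetic.LangevinConfig:
        return synthetic.LangevinConfig(
            temperature=self.temperature,
            friction=self.friction,
            timestep=self.timestep,
            seed=self.seed,
            n_replicates=self.n_replicates,
        )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages end to end; returns artefact paths.

    Stage order: simulate → pmf → metrics → observables → mutstats. Later
    stages reuse earlier in-memory results when available, or read stored
    inputs (``ensemble_path``, ``records_csv``) so stages can run in
    isolation.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": _VERSION,
    }
    artefacts: dict = {}
    ensemble = None

    if "simulate" in config.stages:
        logger.info("stage=simulate n_replicates=%d", config.n_replicates)
        ensemble = synthetic.generate_work_ensemble(
            config.potential(),
            config.steering(),
            config.langevin(),
            strain_reference=config.strain_reference,
        )
        path = outdir / "work_ensemble.tsv"
        write_work_ensemble(ensemble, path, extra_metadata=provenance)
        artefacts["work_ensemble"] = path

    if "pmf" in config.stages:
        if ensemble is None:
            source = config.ensemble_path or artefacts.get("work_ensemble")
            if source is None:
                raise ValidationError(
                    "stage 'pmf' needs stage 'simulate' or an ensemble_path"
                )
            ensemble = read_work_ensemble(source)
        logger.info("stage=pmf n=%d", ensemble.n_replicates)
        profile = pmf_mod.jarzynski_pmf(ensemble)
        force = pmf_mod.force_profile(profile, window_ns=config.window_ns)
        write_profile(profile, outdir / "pmf_profile.tsv", extra_metadata=provenance)
        write_profile(force, outdir / "force_profile.tsv", extra_metadata=provenance)
        artefacts["pmf_profile"] = outdir / "pmf_profile.tsv"
        artefacts["force_profile"] = outdir / "force_profile.tsv"

    if "metrics" in config.stages:
        logger.info("stage=metrics replicates=%d", config.n_length_replicates)
        cfg = synthetic.LangevinConfig(
            temperature=config.temperature,
            friction=config.friction,
            timestep=min(config.timestep, 0.1 * config.friction / config.length_stiffness),
            seed=config.seed + 1,
            n_replicates=config.n_length_replicates,
        )
        replicates = synthetic.equilibrium_length_ensemble(
            config.mean_length,
            config.length_stiffness,
            cfg,
            n_frames=config.frames_per_replicate,
            burn_in_fraction=config.burn_in_fraction,
        )
        series = conformation.LengthSeries(
            np.concatenate(replicates), temperature=config.temperature
        )
        estimate = conformation.apparent_stiffness(series)
        df = pd.DataFrame(
            {
                "replicate": np.arange(len(replicates)),
                "mean_length_A": [r.mean() for r in replicates],
                "variance_A2": [r.var() for r in replicates],
            }
        )
        path = outdir / "length_metrics.tsv"
        write_table(
            df,
            path,
            {
                "units": "mean_length_A:angstrom variance_A2:angstrom^2",
                "stiffness_pN": estimate.stiffness_pn,
                "mean_length_A": estimate.mean_length,
                **provenance,
            },
        )
        artefacts["length_metrics"] = path

    if "observables" in config.stages:
        logger.info("stage=observables")
        toy = synthetic.build_toy_structure(
            n_contacts=config.n_contacts, n_hairpin=config.n_hairpin
        )
        strain_grid = np.linspace(0.0, 0.5, 11)
        frames = generate_frames = synthetic.generate_toy_conformations(
            toy, strain_grid, noise=0.0, seed=config.seed
        )
        strain_pct = 100.0 * strain_grid
        contacts = binding.contact_series(
            frames, toy.ligand_index, strain_pct, cutoff=config.contact_cutoff
        )
        sasa = binding.sasa_series(
            frames,
            toy.ligand_index,
            strain_pct,
            probe=config.probe_radius,
            n_points=config.sasa_points,
        )
        df = contacts.to_frame().merge(sasa.to_frame(), on="strain_pct")
        if ensemble is not None:
            obs = np.repeat(
                contacts.counts[None, :].astype(float), ensemble.n_replicates, axis=0
            )
            works = np.vstack(
                [np.interp(strain_pct, ensemble.strain, w) for w in ensemble.works]
            )
            weighted = binding.jarzynski_weighted_average(
                obs,
                works,
                ensemble.temperature,
                strain=strain_pct,
                per_point=config.per_point_weights,
            )
            df["weighted_contacts"] = weighted.mean
        path = outdir / "binding_observables.tsv"
        write_table(
            df,
            path,
            {
                "units": "strain_pct:percent contacts:count sasa_A2:angstrom^2 sasa_pct:percent",
                "cutoff_A": config.contact_cutoff,
                "probe_A": config.probe_radius,
                **provenance,
            },
        )
        write_pdb(frames, outdir / "toy_conformations.pdb")
        artefacts["binding_observables"] = path
        artefacts["toy_conformations"] = outdir / "toy_conformations.pdb"

    if "mutstats" in config.stages:
        logger.info("stage=mutstats")
        from .structure import default_domain_map

        dmap = default_domain_map()
        if config.records_csv:
            records = pd.read_csv(config.records_csv)
        else:
            records = synthetic.generate_mutation_cohort(
                _default_cohort_spec(config.seed), dmap
            )
        partition = mutations.filter_records(records)
        frames_out = [
            mutations.summarize_cohort(partition.nmfs, dmap, "nMFS").to_frame(),
            mutations.summarize_cohort(partition.cmfs, dmap, "cMFS").to_frame(),
        ]
        df = pd.concat(frames_out, ignore_index=True)
        path = outdir / "mutation_summary.tsv"
        write_table(
            df,
            path,
            {
                "units": "percent:percent se_percent:percent count:records",
                "n_total": partition.n_total,
                "n_included": partition.n_included,
                "n_nmfs": len(partition.nmfs),
                "n_cmfs": len(partition.cmfs),
                "n_excluded": len(partition.excluded),
                **provenance,
            },
        )
        artefacts["mutation_summary"] = path

    logger.info("pipeline complete: %d artefacts in %s", len(artefacts), outdir)
    return artefacts


def _default_cohort_spec(seed: int) -> synthetic.SyntheticCohortSpec:
    """Synthetic registry replica with the published marginal counts."""
    return synthetic.SyntheticCohortSpec(
        counts={"neonatal MFS": 93, "Classical MFS": 1718, "unknown": 1420},
        proportions={
            "neonatal MFS": {
                "calcium_binding": 0.30,
                "cysteine_bond1": 0.20,
                "cysteine_bond2": 0.04,
                "cysteine_bond3": 0.13,
                "other": 0.33,
            },
            "Classical MFS": {
                "calcium_binding": 0.20,
                "cysteine_bond1": 0.13,
                "cysteine_bond2": 0.13,
                "cysteine_bond3": 0.13,
                "other": 0.41,
            },
        },
        seed=seed,
    )
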