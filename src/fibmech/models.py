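"""Model/Results interface over the analysis operations.

Each model is constructed from data and ``fit()`` returns a results object
carrying estimates, uncertainties and a ``summary()`` table — the idiom of
statistical modelling packages, layered over the functional API:

* :class:`JarzynskiPMF` — free-energy reconstruction from a work ensemble;
* :class:`StiffnessModel` — apparent stiffness from equilibrium lengths;
* :class:`MutationCohortModel` — cohort classification and comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pmf as _pmf
from .conformation import (
    LengthSeries,
    StiffnessEstimate,
    apparent_stiffness,
    compare_means,
    compare_variances,
)
from .errors import ValidationError
from .mutations import (
    CohortSummary,
    ComparisonResult,
    FilterResult,
    compare_cohorts,
    filter_records,
    summarize_cohort,
    uniform_random_baseline,
)
from .profiles import ForceProfile, PMFProfile, WorkEnsemble
from .structure import DomainMap

__all__ = [
    "JarzynskiPMF",
    "JarzynskiPMFResults",
    "StiffnessModel",
    "StiffnessResults",
    "MutationCohortModel",
    "MutationCohortResults",
]


class JarzynskiPMF:
    """Free-energy model of a nonequilibrium pulling experiment.

    Parameters
    ----------
    ensemble : WorkEnsemble
        Replicate work profiles on a common extension grid.
    """

    def __init__(self, ensemble: WorkEnsemble):
        self.ensemble = ensemble

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        temperature: float = 300.0,
        strain_reference: float = 60.0,
    ) -> "JarzynskiPMF":
        """Build from a table with an ``extension_A`` column plus one work
        column per replicate (the ensemble TSV layout)."""
        if "extension_A" not in df.columns:
            raise ValidationError("table needs an 'extension_A' column")
        work_cols = [c for c in df.columns if c != "extension_A"]
        if not work_cols:
            raise ValidationError("table has no work columns")
        return cls(
            WorkEnsemble(
                extension=df["extension_A"].to_numpy(),
                works=df[work_cols].to_numpy().T,
                temperature=temperature,
                strain_reference=strain_reference,
            )
        )

    def fit(
        self,
        smoothing_window: float | None = None,
        window_ns: float = _pmf.DEFAULT_WINDOW_NS,
    ) -> "JarzynskiPMFResults":
        profile = _pmf.jarzynski_pmf(self.ensemble)
        force = _pmf.force_profile(profile, window=smoothing_window, window_ns=window_ns)
        return JarzynskiPMFResults(model=self, pmf=profile, force=force)


@dataclass
class JarzynskiPMFResults:
    """Fitted PMF and force profiles with scalar summaries."""

    model: JarzynskiPMF
    pmf: PMFProfile
    force: ForceProfile

    def delta_g_at_strain(self, strain: float) -> float:
        return _pmf.delta_g_at_strain(self.pmf, strain)

    @property
    def delta_g50(self) -> float:
        """Free-energy change from 0 to 50% strain, kcal/mol."""
        return self.delta_g_at_strain(50.0)

    def force_summary(self, windows=((0.0, 20.0), (20.0, 50.0))):
        return _pmf.summarize_forces(self.force, windows)

    def histogram(self, strain: float = 50.0):
        return _pmf.fit_delta_g_histogram(self.model.ensemble, strain)

    def summary(self) -> str:
        ens = self.model.ensemble
        lines = [
            "Jarzynski PMF reconstruction",
            "=" * 34,
            f"replicates:          {ens.n_replicates}",
            f"temperature:         {ens.temperature:.1f} K",
            f"strain reference:    {ens.strain_reference:.2f} Å",
            f"extension range:     0 – {ens.extension[-1]:.2f} Å",
            f"ΔG(endpoint):        {self.pmf.delta_g[-1]:.3f} kcal/mol",
        ]
        max_strain = self.pmf.strain[-1]
        if max_strain >= 50.0:
            lines.append(f"ΔG₅₀ (0–50% strain): {self.delta_g50:.3f} kcal/mol")
        try:
            windows = (
                ((0.0, 20.0), (20.0, 50.0)) if max_strain >= 50.0 else ((0.0, max_strain / 2),)
            )
            fs = self.force_summary(windows)
            lines.append(
                f"peak force:          {fs.peak_force:.1f} pN at {fs.peak_strain:.1f}% strain"
            )
            for row in fs.window_means.itertuples():
                lines.append(
                    f"mean force {row.lo:>4.0f}–{row.hi:<4.0f}%: "
                    f"{row.mean_pN:.1f} ± {row.sd_pN:.1f} pN"
                )
        except ValidationError:
            pass
        if ens.n_replicates >= 2:
            hist = self.histogram(min(50.0, max_strain))
            lines.append(
                f"endpoint works:      {hist.location:.2f} ± {hist.scale:.2f} kcal/mol"
            )
        return "\n".join(lines)


class StiffnessModel:
    """Apparent-stiffness model of equilibrium length fluctuations."""

    def __init__(self, lengths, temperature: float = 300.0):
        self.series = (
            lengths
            if isinstance(lengths, LengthSeries)
            else LengthSeries(np.asarray(lengths, dtype=float), temperature)
        )

    def fit(self, ddof: int = 0) -> "StiffnessResults":
        return StiffnessResults(series=self.series, estimate=apparent_stiffness(self.series, ddof=ddof))


@dataclass
class StiffnessResults:
    series: LengthSeries
    estimate: StiffnessEstimate

    @property
    def stiffness_pn(self) -> float:
        return self.estimate.stiffness_pn

    def compare_to(self, other: "StiffnessResults"):
        """(Welch t, p) on mean lengths and (F, p) on length variances."""
        t, p_t = compare_means(self.series.lengths, other.series.lengths)
        f, p_f = compare_variances(self.series.lengths, other.series.lengths)
        return {"t": t, "p_mean": p_t, "F": f, "p_variance": p_f}

    def summary(self) -> str:
        e = self.estimate
        return "\n".join(
            [
                "Apparent stiffness (length-fluctuation estimator)",
                "=" * 49,
                f"frames:          {self.series.lengths.size}",
                f"temperature:     {e.temperature:.1f} K",
                f"mean length:     {e.mean_length:.2f} Å",
                f"length variance: {e.variance:.4f} Å² (ddof={e.ddof})",
                f"stiffness K:     {e.stiffness_kcal_mol_ang:.3f} kcal/mol/Å "
                f"= {e.stiffness_pn:.0f} pN",
            ]
        )


class MutationCohortModel:
    """Cohort classification model over a mutation-record table."""

    def __init__(self, records, domain_map: DomainMap):
        self.records = records
        self.domain_map = domain_map

    def fit(self, nmfs_keywords=None, cmfs_keywords=None) -> "MutationCohortResults":
        kwargs = {}
        if nmfs_keywords is not None:
            kwargs["nmfs_keywords"] = nmfs_keywords
        if cmfs_keywords is not None:
            kwargs["cmfs_keywords"] = cmfs_keywords
        partition = filter_records(self.records, **kwargs)
        return MutationCohortResults(
            model=self,
            partition=partition,
            nmfs=summarize_cohort(partition.nmfs, self.domain_map, "nMFS"),
            cmfs=summarize_cohort(partition.cmfs, self.domain_map, "cMFS"),
        )


@dataclass
class MutationCohortResults:
    model: MutationCohortModel
    partition: FilterResult
    nmfs: CohortSummary
    cmfs: CohortSummary

    def compare(self, key, yates: bool = False) -> ComparisonResult:
        return compare_cohorts(self.nmfs, self.cmfs, key, yates=yates)

    def random_baseline(self, n_draws: int = 0, seed: int = 0) -> pd.DataFrame:
        return uniform_random_baseline(self.model.domain_map, n_draws, seed)

    def summary(self) -> str:
        p = self.partition
        lines = [
            "Mutation cohort classification",
            "=" * 33,
            f"records:  {p.n_total} total, {p.n_included} included "
            f"({len(p.nmfs)} nMFS, {len(p.cmfs)} cMFS), {len(p.excluded)} excluded",
        ]
        for summary in (self.nmfs, self.cmfs):
            if summary.n == 0:
                continue
            parts = []
            for cls in ("calcium_binding", "cysteine", "other"):
                pct, se, *_ = summary.proportion(cls)
                parts.append(f"{cls} {100 * pct:.0f}±{100 * se:.0f}%")
            lines.append(f"{summary.name} (n={summary.n}): " + ", ".join(parts))
            if summary.class_counts["cysteine"] > 0:
                bonds = []
                for bond in (1, 2, 3):
                    pct, se, *_ = summary.proportion(bond)
                    bonds.append(f"bond{bond} {100 * pct:.0f}±{100 * se:.0f}%")
                lines.append("    cysteine records by bond: " + ", ".join(bonds))
        return "\n".join(lines)
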