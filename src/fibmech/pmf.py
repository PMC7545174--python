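"""Free-energy reconstruction from nonequilibrium work ensembles.

The central operation is the Jarzynski estimator

    exp(−ΔG/kT) = ⟨exp(−W/kT)⟩  ⇒  ΔG(z) = −kT ln (1/n) Σᵢ exp(−Wᵢ(z)/kT)

evaluated pointwise along the extension grid with a max-shifted
log-sum-exp, so ensembles with works of thousands of kT neither overflow
nor underflow. By Jensen's inequality the estimate never exceeds the mean
work; with a single replicate it equals that replicate's work profile.

Force profiles are the distance derivative of the PMF converted to pN.
The pulling literature states its smoothing window in time (10 ns); for a
profile parameterised by extension this corresponds to a window of
pull_speed × window_ns Å (1 Å at 0.1 Å/ns). The PMF is smoothed, then
differentiated, then the force is smoothed once more with the same window;
edge windows shrink symmetrically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import PN_PER_KCAL_PER_MOL_ANG, kt
from .errors import RangeError, ValidationError
from .profiles import ForceProfile, PMFProfile, WorkEnsemble

__all__ = [
    "jarzynski_pmf",
    "delta_g_at_strain",
    "force_profile",
    "summarize_forces",
    "ForceSummary",
    "report_relative_change",
    "relative_change",
    "convergence_study",
    "fit_delta_g_histogram",
    "DeltaGHistogram",
]

#: Default smoothing window of the pulling protocol, ns.
DEFAULT_WINDOW_NS = 10.0


def jarzynski_pmf(ensemble: WorkEnsemble) -> PMFProfile:
    """Jarzynski free-energy profile of a work ensemble.

    ΔG(z) = −kT · ln[(1/n) Σᵢ exp(−Wᵢ(z)/kT)] per grid point, computed with
    a shifted log-sum-exp. ΔG(0) = 0 exactly (all works start at 0), the
    estimate is invariant under replicate permutation, and a replicate with
    overwhelmingly large work leaves the sum unchanged to machine precision.
    """
    thermal = kt(ensemble.temperature)
    n = ensemble.n_replicates
    log_mean = logsumexp(-ensemble.works / thermal, axis=0) - math.log(n)
    delta_g = -thermal * log_mean
    delta_g[0] = 0.0  # exact by construction; clears -0.0
    return PMFProfile(
        extension=ensemble.extension,
        delta_g=delta_g,
        strain_reference=ensemble.strain_reference,
        temperature=ensemble.temperature,
        metadata={**ensemble.metadata, "estimator": "jarzynski", "n": n},
    )


def delta_g_at_strain(pmf: PMFProfile, strain: float) -> float:
    """ΔG (kcal/mol) at a strain given in percent, by linear interpolation.

    The free-energy change accumulated from 0% to 50% strain is the ΔG₅₀
    summary statistic of a pulling experiment.
    """
    axis = pmf.strain
    if strain < axis[0] - 1e-9 or strain > axis[-1] + 1e-9:
        raise RangeError(
            f"strain {strain}% outside profile range [{axis[0]:.3g}, {axis[-1]:.3g}]%"
        )
    return float(np.interp(strain, axis, pmf.delta_g))


def _moving_average(y: np.ndarray, n_window: int) -> np.ndarray:
    """Centred moving average with symmetrically shrinking edge windows."""
    if n_window <= 1:
        return y.astype(float, copy=True)
    half = n_window // 2
    out = np.empty_like(y, dtype=float)
    for i in range(y.size):
        k = min(half, i, y.size - 1 - i)
        out[i] = y[i - k : i + k + 1].mean()
    return out


def _window_points(window: float, spacing: float) -> int:
    n = int(round(window / spacing))
    if n % 2 == 0:
        n += 1  # centred window needs odd support
    return max(n, 1)


def force_profile(
    pmf: PMFProfile,
    window: float | None = None,
    window_ns: float = DEFAULT_WINDOW_NS,
) -> ForceProfile:
    """Force profile (pN) as the distance derivative of a smoothed PMF.

    Parameters
    ----------
    pmf : PMFProfile
    window : float, Å, optional
        Explicit smoothing window. When omitted, the window is derived from
        protocol metadata as pull_speed × ``window_ns`` (the field's
        time-stated window mapped onto the extension axis); with no
        metadata either, no smoothing is applied.
    window_ns : float
        Time width of the protocol smoothing window, ns.

    The PMF is smoothed, differentiated by central finite differences, and
    the resulting force is smoothed again with the same window.
    """
    spacing = float(np.min(np.diff(pmf.extension)))
    if window is None:
        speed = pmf.metadata.get("pull_speed")
        window = speed * window_ns if speed is not None else 0.0
    if window and window < spacing - 1e-12:
        raise ValidationError(
            f"smoothing window {window} Å is below the grid spacing {spacing} Å"
        )
    n_window = _window_points(window, spacing) if window else 1
    smoothed = _moving_average(pmf.delta_g, n_window)
    force_kcal = np.gradient(smoothed, pmf.extension)
    force_kcal = _moving_average(force_kcal, n_window)
    return ForceProfile(
        extension=pmf.extension,
        force=force_kcal * PN_PER_KCAL_PER_MOL_ANG,
        strain_reference=pmf.strain_reference,
        smoothing_window=float(window or 0.0),
        metadata={**pmf.metadata, "window_A": float(window or 0.0)},
    )


@dataclass(frozen=True)
class ForceSummary:
    """Windowed force statistics and the global peak of a force profile."""

    window_means: pd.DataFrame  # columns: lo, hi, mean_pN, sd_pN, n
    peak_force: float  # pN
    peak_strain: float  # %


def summarize_forces(
    force: ForceProfile,
    strain_windows: Sequence[tuple[float, float]] = ((0.0, 20.0), (20.0, 50.0)),
) -> ForceSummary:
    """Mean ± sd of the force in half-open strain windows [lo, hi), plus peak.

    The default windows, 0–20% and 20–50% strain, separate the low-strain
    regime where calcium dominates stiffness from the high-strain unfolding
    regime.
    """
    axis = force.strain
    rows = []
    for lo, hi in strain_windows:
        if hi <= lo:
            raise ValidationError(f"empty strain window [{lo}, {hi})")
        mask = (axis >= lo) & (axis < hi)
        if not mask.any():
            raise ValidationError(f"no profile points in strain window [{lo}, {hi})")
        vals = force.force[mask]
        rows.append(
            {
                "lo": lo,
                "hi": hi,
                "mean_pN": float(vals.mean()),
                "sd_pN": float(vals.std(ddof=0)),
                "n": int(mask.sum()),
            }
        )
    peak_idx = int(np.argmax(force.force))
    return ForceSummary(
        window_means=pd.DataFrame(rows),
        peak_force=float(force.force[peak_idx]),
        peak_strain=float(axis[peak_idx]),
    )


def relative_change(reference: float, comparison: float) -> float:
    """Unrounded percent change, 100 · (reference − comparison)/reference.

    Positive values mean the comparison decreased relative to the reference.
    """
    if reference == 0:
        raise ValidationError("reference value must be nonzero")
    return 100.0 * (reference - comparison) / reference


def report_relative_change(reference: float, comparison: float) -> int:
    """Percent change rounded to the nearest integer (half away from zero).

    Matches the printed precision of reported comparisons, e.g. a drop from
    51 to 36 kcal/mol is reported as 29%.
    """
    x = relative_change(reference, comparison)
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class DeltaGHistogram:
    """Per-replicate endpoint works at one strain with a normal moment fit.

    The values are per-trajectory work readings (not jackknifed Jarzynski
    estimates); location/scale are the sample mean and sample standard
    deviation (ddof = 1).
    """

    values: np.ndarray  # kcal/mol
    strain: float  # %
    location: float
    scale: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"work_kcal_mol": self.values})


def fit_delta_g_histogram(ensemble: WorkEnsemble, strain: float = 50.0) -> DeltaGHistogram:
    """Gaussian moment fit to the per-replicate works at the given strain."""
    if ensemble.n_replicates < 2:
        raise ValidationError("histogram fit needs at least two replicates")
    axis = ensemble.strain
    if strain < axis[0] - 1e-9 or strain > axis[-1] + 1e-9:
        raise RangeError(f"strain {strain}% outside ensemble range")
    values = np.array(
        [np.interp(strain, axis, w) for w in ensemble.works]
    )
    return DeltaGHistogram(
        values=values,
        strain=float(strain),
        location=float(values.mean()),
        scale=float(values.std(ddof=1)),
    )


def convergence_study(
    potential,
    steer_template,
    speeds: Sequence[float],
    sample_sizes: Sequence[int],
    cfg,
    strain_reference: float | None = None,
) -> pd.DataFrame:
    """Endpoint-ΔG convergence across pull speeds and ensemble sizes.

    For every (speed, n) pair an ensemble is generated with the template
    protocol re-timed to that speed (the extension grid is kept fixed by
    rescaling the output interval), the Jarzynski endpoint estimate is
    computed from the first *n* replicates, and the bias against the
    analytic reference is tabulated. Slower pulling dissipates less, so the
    expected bias decreases with speed — a statistical property over seeds,
    not a per-run guarantee.
    """
    from .synthetic import analytic_pmf, generate_work_ensemble  # cycle-free at call time

    if not speeds or not sample_sizes:
        raise ValidationError("need at least one speed and one sample size")
    n_max = max(sample_sizes)
    reference = analytic_pmf(potential, steer_template)
    ref_endpoint = reference.delta_g[-1]

    rows = []
    for speed in speeds:
        steer = replace(
            steer_template,
            pull_speed=speed,
            output_interval=steer_template.output_interval
            * steer_template.pull_speed
            / speed,
        )
        run_cfg = replace(cfg, n_replicates=n_max)
        ensemble = generate_work_ensemble(
            potential,
            steer,
            run_cfg,
            strain_reference=strain_reference or ensemble_default_reference(steer),
        )
        for n in sample_sizes:
            sub = WorkEnsemble(
                extension=ensemble.extension,
                works=ensemble.works[:n],
                temperature=ensemble.temperature,
                strain_reference=ensemble.strain_reference,
                metadata=ensemble.metadata,
            )
            estimate = jarzynski_pmf(sub).delta_g[-1]
            rows.append(
                {
                    "pull_speed": speed,
                    "n_samples": n,
                    "delta_g_end": float(estimate),
                    "bias": float(estimate - ref_endpoint),
                }
            )
    return pd.DataFrame(rows)


def ensemble_default_reference(steer) -> float:
    """Fallback strain reference: twice the stretch distance (50% strain span)."""
    return 2.0 * steer.total_distance
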