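"""Behavioral scoring: Gridwalk, cylinder test, skilled-reaching outcomes,
robotic-platform trials, lesion volume and the study power computation.

Scores are kept deliberately simple (percentages, normalized differences,
event counts); group-level inference is left to external statistics
packages, the pipeline only emits tidy tables and mean +/- SEM summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal, stats

__all__ = [
    "BehaviorCounts",
    "PlatformTrial",
    "PlatformMetrics",
    "LesionSections",
    "PowerParams",
    "foot_fault_percentage",
    "asymmetry_index",
    "reach_error_percentage",
    "platform_metrics",
    "lesion_volume",
    "ttest_power",
]


@dataclass
class BehaviorCounts:
    """Event tallies from the three behavioral tests.

    Gridwalk: per-limb correct steps and foot faults (steps not providing
    body support, the foot falling into a grid hole).  Cylinder: wall
    contacts with the impaired vs unimpaired forelimb.  Skilled reaching:
    correct movements (reach-grasp-eat), incorrect ones (missed or dropped
    pellet), and total attempts (paw crossings of the slot).
    """

    correct_steps: Mapping[str, int] = field(default_factory=dict)
    foot_faults: Mapping[str, int] = field(default_factory=dict)
    n_impaired: int = 0
    n_unimpaired: int = 0
    n_correct: int = 0
    n_incorrect: int = 0
    n_attempts_total: int = 0

    def __post_init__(self) -> None:
        counts = [*self.correct_steps.values(), *self.foot_faults.values(),
                  self.n_impaired, self.n_unimpaired,
                  self.n_correct, self.n_incorrect, self.n_attempts_total]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if self.n_correct + self.n_incorrect > self.n_attempts_total:
            raise ValueError("n_correct + n_incorrect cannot exceed n_attempts_total")


@dataclass
class PlatformTrial:
    """Synchronized force/position trace of one forelimb-retraction trial.

    The motor first extends the forelimb by ``target_extension`` mm; the
    animal must exceed the static-friction threshold (0.2 N) to pull the
    handle back to the start position.
    """

    t: np.ndarray
    force: np.ndarray           # N
    position: np.ndarray        # mm along the slide; 0 = fully retracted
    friction_threshold: float = 0.2
    target_extension: float = 10.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if not (self.t.shape == self.force.shape == self.position.shape):
            raise ValueError("t, force, position must be aligned")
        if self.friction_threshold <= 0:
            raise ValueError("friction threshold must be positive")


@dataclass
class PlatformMetrics:
    t_target: float             # s; NaN if the retraction never completed
    n_attempts: int


@dataclass
class LesionSections:
    """Damaged areas of regularly sampled coronal sections (1 of every 6)."""

    areas: np.ndarray           # mm^2
    section_thickness: float = 0.05   # mm
    spacing_factor: float = 6.0

    def __post_init__(self) -> None:
        self.areas = np.atleast_1d(np.asarray(self.areas, dtype=float))
        if self.areas.size < 1:
            raise ValueError("at least one section is required")
        if np.any(self.areas < 0):
            raise ValueError("section areas must be non-negative")
        if self.section_thickness <= 0:
            raise ValueError("section thickness must be positive")


@dataclass
class PowerParams:
    """Two-sample t-test power parameters (Cohen's d effect size)."""

    effect_size: float
    n_per_group: int
    alpha: float = 0.05
    tails: str = "one"

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect size must be non-negative")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")


# ---------------------------------------------------------------------------
# simple scores
# ---------------------------------------------------------------------------

def foot_fault_percentage(counts: BehaviorCounts, limb: str) -> float:
    """Percentage of foot faults among all steps of one limb."""
    faults = counts.foot_faults.get(limb, 0)
    correct = counts.correct_steps.get(limb, 0)
    total = faults + correct
    if total == 0:
        warnings.warn(f"no steps recorded for limb {limb!r}; returning NaN")
        return float("nan")
    return 100.0 * faults / total


def asymmetry_index(counts: BehaviorCounts) -> float:
    """Normalized forelimb-use asymmetry during cylinder exploration.

    ``(unimpaired - impaired) / (unimpaired + impaired)`` wall contacts;
    positive values indicate preference for the unimpaired limb, range
    [-1, 1].
    """
    total = counts.n_impaired + counts.n_unimpaired
    if total == 0:
        warnings.warn("no wall contacts recorded; returning NaN")
        return float("nan")
    return (counts.n_unimpaired - counts.n_impaired) / total


def reach_error_percentage(counts: BehaviorCounts) -> float:
    """Percentage of incorrect grasps over total reaching attempts."""
    if counts.n_attempts_total == 0:
        warnings.warn("no reaching attempts recorded; returning NaN")
        return float("nan")
    return 100.0 * counts.n_incorrect / counts.n_attempts_total


# ---------------------------------------------------------------------------
# robotic platform
# ---------------------------------------------------------------------------

def platform_metrics(
    trial: PlatformTrial,
    noise_floor: float = 0.05,
    position_epsilon: float = 0.5,
    coincidence_ms: float = 100.0,
    smooth_ms: float = 50.0,
) -> PlatformMetrics:
    """t-target and attempt count from a force/position trace.

    Attempts are local force maxima above ``noise_floor`` during which the
    handle did not move (position excursion <= ``position_epsilon`` within
    +/- ``coincidence_ms``), i.e. force pulses that failed to overcome static
    friction.  The force trace is moving-average smoothed over ``smooth_ms``
    before peak detection so sensor noise cannot split one pulse into
    several maxima.  The t-target is the time from trial start until the
    handle position first returns within ``position_epsilon`` of zero
    (completed retraction); if retraction never completes the t-target is
    NaN but attempts are still reported.
    """
    t, pos = trial.t, trial.position
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    half = max(1, int(round(coincidence_ms * 1e-3 / dt)))
    win = max(1, int(round(smooth_ms * 1e-3 / dt)))
    from scipy.ndimage import uniform_filter1d

    force = uniform_filter1d(trial.force, size=win, mode="nearest") if win > 1 else trial.force

    peaks, _ = signal.find_peaks(force, height=noise_floor)
    n_attempts = 0
    for p in peaks:
        lo, hi = max(0, p - half), min(t.size, p + half + 1)
        if np.max(np.abs(pos[lo:hi] - pos[p])) <= position_epsilon:
            n_attempts += 1

    done = np.nonzero(np.abs(pos) <= position_epsilon)[0]
    t_target = float(t[done[0]] - t[0]) if done.size else float("nan")
    return PlatformMetrics(t_target=t_target, n_attempts=n_attempts)


# ---------------------------------------------------------------------------
# lesion volume and power
# ---------------------------------------------------------------------------

def lesion_volume(sections: LesionSections) -> float:
    """Lesion volume in mm^3: sum of damaged areas x thickness x spacing factor."""
    return float(sections.areas.sum() * sections.section_thickness * sections.spacing_factor)


def ttest_power(params: PowerParams) -> float:
    """Power of the two-sample t-test via the noncentral t distribution.

    With ``n`` subjects per group the test statistic under the alternative is
    noncentral t with ``df = 2n - 2`` and noncentrality ``d * sqrt(n/2)``.
    One-tailed by default.
    """
    d, n, alpha = params.effect_size, params.n_per_group, params.alpha
    df = 2 * n - 2
    nc = d * np.sqrt(n / 2.0)
    if params.tails == "one":
        crit = stats.t.ppf(1 - alpha, df)
        return float(1 - stats.nct.cdf(crit, df, nc))
    crit = stats.t.ppf(1 - alpha / 2, df)
    return float((1 - stats.nct.cdf(crit, df, nc)) + stats.nct.cdf(-crit, df, nc))
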