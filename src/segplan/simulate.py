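"""Synthetic-data engine: virtual lungs for the planner, virtual cohorts and
Monte-Carlo power checks for the statistics, and the trial visit calendar.

The cohort generator draws normally distributed outcome changes with a
common per-arm SD (the t-test design assumption) and assigns missingness
with recorded causes so the endpoint-assembly ladder is exercised on every
branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy import stats

from .densitometry import (
    LEFT_TREATABLE,
    LINGULA,
    RIGHT_TREATABLE,
    LungModel,
    SegmentDensitometry,
)
from .trial import ENDPOINTS, EndpointSeries, TrialDesignError

__all__ = [
    "VisitSchedule",
    "visit_schedule",
    "CohortParams",
    "generate_cohort",
    "simulate_trial_power",
    "LungFixtureSpec",
    "generate_lung_fixture",
    "random_lung_model",
]

# Endpoint follow-up measurement visits (weeks); week 52 is the 12-month
# primary-analysis visit.
MEASUREMENT_WEEKS = (26, 39, 52)

# Baseline distributions for the synthetic cohort (chosen to sit inside the
# screening windows: FEV1 20-45 %pred, walking > 140 m, SGRQ severe-COPD
# range).
_BASELINES = {"FEV1": (32.0, 5.0), "SGRQ": (60.0, 10.0), "6MWT": (320.0, 70.0)}


@dataclass(frozen=True)
class VisitSchedule:
    """Follow-up calendar for one arm (weeks from study day 1)."""

    arm: str
    phone_weeks: frozenset[int]
    clinic_weeks: frozenset[int]
    second_session_nominal_day: Optional[int] = None
    second_session_window_days: Optional[tuple[int, int]] = None
    second_session_max_delay_day: Optional[int] = None


def visit_schedule(arm: str) -> VisitSchedule:
    """The printed follow-up calendar.

    Treatment arm: phone calls at weeks 1, 4, 14, 17, 32, 45 and clinic
    visits at 2, 8, 12, 15, 21, 26, 39, 52; the second treatment session is
    nominally 13 weeks (day 91) after the first, +/- 7 days, and may be
    delayed by up to 4 further weeks if healing is incomplete.  Control arm:
    weeks 1, 14 and 15 are dropped and week 2 becomes a phone call.
    """
    if arm == "treatment":
        return VisitSchedule(
            arm=arm,
            phone_weeks=frozenset({1, 4, 14, 17, 32, 45}),
            clinic_weeks=frozenset({2, 8, 12, 15, 21, 26, 39, 52}),
            second_session_nominal_day=91,
            second_session_window_days=(84, 98),
            second_session_max_delay_day=126,  # window end + 4 weeks
        )
    if arm == "control":
        return VisitSchedule(
            arm=arm,
            phone_weeks=frozenset({2, 4, 17, 32, 45}),
            clinic_weeks=frozenset({8, 12, 21, 26, 39, 52}),
        )
    raise TrialDesignError(f"unknown arm {arm!r}")


@dataclass(frozen=True)
class CohortParams:
    """Outcome-model parameters for a two-arm synthetic cohort.

    ``effects`` maps endpoint -> (improvement magnitude, SD); the direction
    is applied per endpoint (SGRQ improves downward).  Missingness is
    Bernoulli per subject: ``dropout_prob`` removes the 12-month visit (with
    probability ``sae_given_missing`` the cause is a serious adverse event,
    triggering worst-prior imputation), and ``no_followup_prob`` removes all
    follow-up, exercising the baseline intent-to-treat branch.
    """

    n_treatment: int = 40
    n_control: int = 20
    effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"FEV1": (12.0, 15.0), "SGRQ": (11.0, 14.0), "6MWT": (30.0, 60.0)}
    )
    dropout_prob: float = 0.15
    sae_given_missing: float = 0.4
    no_followup_prob: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (eff, sd) in self.effects.items():
            if name not in ENDPOINTS:
                raise TrialDesignError(f"unknown endpoint {name!r}")
            if sd <= 0:
                raise TrialDesignError(f"{name}: SD must be > 0, got {sd}")
        for p in (self.dropout_prob, self.sae_given_missing, self.no_followup_prob):
            if not 0 <= p <= 1:
                raise TrialDesignError(f"probability out of [0,1]: {p}")
        if min(self.n_treatment, self.n_control) < 2:
            raise TrialDesignError("need at least 2 subjects per arm")


def generate_cohort(params: CohortParams) -> list[dict]:
    """Subject-level endpoint series for both arms, reproducible under seed.

    Returns one record per subject: ``{"subject_id", "arm", "series":
    {endpoint: EndpointSeries}}``.  Follow-up values are baseline + arm mean
    change + N(0, SD) noise at each measurement visit.
    """
    rng = np.random.default_rng(params.seed)
    subjects: list[dict] = []
    arms = ["treatment"] * params.n_treatment + ["control"] * params.n_control
    for i, arm in enumerate(arms):
        sid = f"S{i + 1:03d}"
        missing_all = rng.random() < params.no_followup_prob
        missing_final = (not missing_all) and rng.random() < params.dropout_prob
        cause = "sae" if rng.random() < params.sae_given_missing else "other"
        series: dict[str, EndpointSeries] = {}
        for name, (eff, sd) in params.effects.items():
            base_mu, base_sd = _BASELINES[name]
            base = float(rng.normal(base_mu, base_sd))
            sign = 1.0 if ENDPOINTS[name]["higher_better"] else -1.0
            mean_change = sign * eff if arm == "treatment" else 0.0
            followups: dict[int, float] = {}
            causes: dict[int, str] = {}
            if not missing_all:
                for week in MEASUREMENT_WEEKS:
                    # ramp: half effect by 6 months, full effect later
                    frac = 0.5 if week == 26 else 1.0
                    followups[week] = float(base + frac * mean_change + rng.normal(0.0, sd))
                if missing_final:
                    followups.pop(52)
                    causes[52] = cause
            series[name] = EndpointSeries(
                subject_id=sid,
                endpoint=name,
                baseline=base,
                followups=followups,
                missing_causes=causes,
            )
        subjects.append({"subject_id": sid, "arm": arm, "series": series})
    return subjects


def simulate_trial_power(
    effect: float,
    sd: float,
    n_treatment: int = 40,
    n_control: int = 20,
    replicates: int = 10_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Monte-Carlo rejection rate of the two-sided two-sample t-test.

    Draws ``replicates`` virtual trials with normal outcomes
    N(effect, sd) vs N(0, sd) and reports the fraction rejecting at
    ``alpha`` together with its binomial standard error.
    """
    if min(n_treatment, n_control) < 2:
        raise TrialDesignError("need at least 2 subjects per arm")
    if replicates < 1:
        raise TrialDesignError("need at least one replicate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    batch = 20_000
    rejections = 0
    done = 0
    while done < replicates:
        b = min(batch, replicates - done)
        t_arm = rng.normal(effect, sd, size=(b, n_treatment))
        c_arm = rng.normal(0.0, sd, size=(b, n_control))
        res = stats.ttest_ind(t_arm, c_arm, axis=1)
        rejections += int(np.sum(res.pvalue <= alpha))
        done += b
    frac = rejections / replicates
    se = float(np.sqrt(frac * (1.0 - frac) / replicates))
    return {
        "rejection_fraction": frac,
        "standard_error": se,
        "replicates": replicates,
        "alpha": alpha,
        "n_treatment": n_treatment,
        "n_control": n_control,
    }


@dataclass(frozen=True)
class LungFixtureSpec:
    """Generator ranges for a synthetic upper-lobe-predominant lung.

    ``heterogeneity_strength`` scales how much lower the upper-segment TARs
    sit relative to the lower lobes: each treatable segment's HI is drawn as
    1 + strength * U(0.3, 1.0), so strength 0 gives a homogeneous lung
    (HI = 1 everywhere) and strength 1 guarantees HI >= 1.3.
    """

    segment_volume_ml: tuple[float, float] = (400.0, 900.0)
    lingula_volume_ml: tuple[float, float] = (200.0, 500.0)
    lower_lobe_tar: tuple[float, float] = (11.0, 20.0)
    heterogeneity_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.segment_volume_ml, self.lingula_volume_ml, self.lower_lobe_tar):
            if not (0 < lo <= hi):
                raise TrialDesignError(f"range must be positive and ordered, got ({lo}, {hi})")
        if self.heterogeneity_strength < 0:
            raise TrialDesignError("heterogeneity strength must be >= 0")


def _segment_from_tar(seg_id: str, total_ml: float, tar_percent: float) -> SegmentDensitometry:
    air = total_ml / (1.0 + tar_percent / 100.0)
    return SegmentDensitometry(
        segment_id=seg_id, tissue_volume=total_ml - air, air_volume=air
    )


def generate_lung_fixture(spec: LungFixtureSpec) -> LungModel:
    """Reproducible synthetic LungModel matching the fixture spec."""
    rng = np.random.default_rng(spec.seed)
    lower = {
        side: float(rng.uniform(*spec.lower_lobe_tar)) for side in ("left", "right")
    }
    segments: dict[str, SegmentDensitometry] = {}
    for seg_id in LEFT_TREATABLE + RIGHT_TREATABLE:
        side = "left" if seg_id.startswith("L") else "right"
        vol = float(rng.uniform(*spec.segment_volume_ml))
        hi = 1.0 + spec.heterogeneity_strength * float(rng.uniform(0.3, 1.0))
        segments[seg_id] = _segment_from_tar(seg_id, vol, lower[side] / hi)
    for seg_id in LINGULA:
        vol = float(rng.uniform(*spec.lingula_volume_ml))
        segments[seg_id] = _segment_from_tar(seg_id, vol, lower["left"])
    return LungModel(segments=segments, lower_lobe_tar=lower)


def random_lung_model(seed: int | np.random.Generator) -> LungModel:
    """Unconstrained random lung for planner stress tests.

    Unlike :func:`generate_lung_fixture` this draws HIs spanning both sides
    of the 1.2 eligibility floor and wide segment volumes, so constraint
    filtering and infeasible cases are exercised.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lower = {side: float(rng.uniform(8.0, 22.0)) for side in ("left", "right")}
    segments: dict[str, SegmentDensitometry] = {}
    for seg_id in LEFT_TREATABLE + RIGHT_TREATABLE:
        side = "left" if seg_id.startswith("L") else "right"
        vol = float(rng.uniform(250.0, 1600.0))
        hi = float(rng.uniform(0.8, 2.2))
        segments[seg_id] = _segment_from_tar(seg_id, vol, lower[side] / hi)
    for seg_id in LINGULA:
        segments[seg_id] = _segment_from_tar(
            seg_id, float(rng.uniform(150.0, 600.0)), lower["left"] * float(rng.uniform(0.9, 1.1))
        )
    return LungModel(segments=segments, lower_lobe_tar=lower)
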