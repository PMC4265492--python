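"""Design statistics: sample size, multiplicity rule, responders, imputation,
and site-stratified blocked randomization.

Power is exact noncentral-t (no normal approximation) and group sizes are
held to the exact allocation ratio, so the returned totals are multiples of
``ratio + 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DesignAssumptions",
    "EndpointSeries",
    "RandomizationScheme",
    "ENDPOINTS",
    "sample_size_two_sample",
    "two_sample_t_power",
    "inflate_for_dropout",
    "hochberg_decision",
    "responder_flags",
    "assemble_primary_endpoint",
    "blocked_randomization",
]


class TrialDesignError(ValueError):
    pass


# Endpoint improvement directions and responder thresholds: FEV1 %predicted
# relative gain >= 12% of baseline, SGRQ drop >= 8 points, 6MWT gain >= 30 m.
ENDPOINTS = {
    "FEV1": {"higher_better": True, "responder": ("relative", 0.12)},
    "SGRQ": {"higher_better": False, "responder": ("absolute", 8.0)},
    "6MWT": {"higher_better": True, "responder": ("absolute", 30.0)},
}


@dataclass(frozen=True)
class DesignAssumptions:
    """Two-sample design inputs: effect, spread, error rates, allocation."""

    mean_difference: float
    sd: float
    power: float = 0.80
    alpha: float = 0.05
    allocation_ratio: float = 2.0  # treatment : control
    dropout_rate: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.power < 1:
            raise TrialDesignError(f"power must be in (0,1), got {self.power}")
        if not 0 < self.alpha < 1:
            raise TrialDesignError(f"alpha must be in (0,1), got {self.alpha}")
        if not self.sd > 0:
            raise TrialDesignError(f"sd must be > 0, got {self.sd}")
        if self.allocation_ratio < 1:
            raise TrialDesignError(f"allocation ratio must be >= 1, got {self.allocation_ratio}")
        if not 0 <= self.dropout_rate < 1:
            raise TrialDesignError(f"dropout rate must be in [0,1), got {self.dropout_rate}")


def two_sample_t_power(
    n_control: int, n_treatment: int, mean_difference: float, sd: float, alpha: float = 0.05
) -> float:
    """Exact two-sided power of the pooled two-sample t-test (noncentral t)."""
    df = n_control + n_treatment - 2
    if df < 1:
        return 0.0
    ncp = abs(mean_difference) / (sd * math.sqrt(1.0 / n_treatment + 1.0 / n_control))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def sample_size_two_sample(assumptions: DesignAssumptions, n_max: int = 100_000) -> tuple[int, int, int]:
    """Smallest (n_control, n_treatment, n_total) reaching the target power.

    The treatment group is held to exactly ``ratio * n_control``; the search
    increments n_control from 2 until the noncentral-t power meets the target.
    """
    a = assumptions
    if a.mean_difference == 0:
        raise TrialDesignError("zero mean difference: power never reaches the target")
    n_c = 2
    while n_c <= n_max:
        n_t = int(round(a.allocation_ratio * n_c))
        if two_sample_t_power(n_c, n_t, a.mean_difference, a.sd, a.alpha) >= a.power:
            return n_c, n_t, n_c + n_t
        n_c += 1
    raise TrialDesignError("target power unreachable within search bounds")


def inflate_for_dropout(n_total: int, rate: float) -> int:
    """Inflate enrolment for anticipated loss to follow-up: ceil(n*(1+rate))."""
    if n_total < 1:
        raise TrialDesignError(f"n_total must be >= 1, got {n_total}")
    if not 0 <= rate < 1:
        raise TrialDesignError(f"rate must be in [0,1), got {rate}")
    # round first: ceil(100 * 1.1) must be 110, not 111 from float noise
    return math.ceil(round(n_total * (1.0 + rate), 9))


def hochberg_decision(p_fev1: float, p_sgrq: float, alpha: float = 0.05) -> str:
    """Two-endpoint Hochberg rule for co-primary endpoints.

    Positive iff both p-values are <= alpha, or the smaller is <= alpha/2.
    """
    for p in (p_fev1, p_sgrq):
        if not 0 <= p <= 1:
            raise TrialDesignError(f"p-value out of [0,1]: {p}")
    if max(p_fev1, p_sgrq) <= alpha or min(p_fev1, p_sgrq) <= alpha / 2.0:
        return "positive"
    return "negative"


@dataclass
class EndpointSeries:
    """One subject's longitudinal values for one endpoint.

    ``followups`` maps visit week -> value; missing visits may carry a cause
    in ``missing_causes`` (week -> "sae" including death, or "other").
    """

    subject_id: str
    endpoint: str
    baseline: float
    followups: dict[int, float] = field(default_factory=dict)
    missing_causes: dict[int, str] = field(default_factory=dict)
    final_week: int = 52

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise TrialDesignError(
                f"unknown endpoint {self.endpoint!r}; expected one of {sorted(ENDPOINTS)}"
            )
        if not np.isfinite(self.baseline):
            raise TrialDesignError("baseline must be present and finite")
        weeks = sorted(self.followups)
        if weeks != list(self.followups):
            self.followups = {w: self.followups[w] for w in weeks}

    @property
    def higher_better(self) -> bool:
        return ENDPOINTS[self.endpoint]["higher_better"]


def responder_flags(
    series_by_endpoint: Mapping[str, EndpointSeries] | Sequence[EndpointSeries],
    values_at_12m: Mapping[str, float],
    fev1_rule: Literal["relative", "absolute"] = "relative",
) -> dict[str, bool]:
    """Responder status per endpoint at 12 months (boundaries inclusive).

    FEV1: %predicted improvement >= 12% of baseline (or >= 12 absolute points
    under the ``absolute`` rule); SGRQ: decrease >= 8 points; 6MWT: increase
    >= 30 m.
    """
    if not isinstance(series_by_endpoint, Mapping):
        series_by_endpoint = {s.endpoint: s for s in series_by_endpoint}
    flags: dict[str, bool] = {}
    for name, series in series_by_endpoint.items():
        value = values_at_12m[name]
        base = series.baseline
        mode, threshold = ENDPOINTS[name]["responder"]
        if name == "FEV1" and fev1_rule == "absolute":
            mode, threshold = "absolute", 12.0
        change = value - base if series.higher_better else base - value
        if mode == "relative":
            if base == 0:
                raise TrialDesignError("relative responder rule undefined at zero baseline")
            flags[name] = change / base >= threshold
        else:
            flags[name] = change >= threshold
    return flags


def assemble_primary_endpoint(series: EndpointSeries) -> tuple[float, str, bool]:
    """12-month analysis value under the missing-data ladder.

    Returns (value, provenance, sensitivity_exclusion_flag).  Provenance is
    ``observed`` when the final visit is present; ``worst-prior`` when it is
    missing because of a serious adverse event or death (direction-aware
    worst follow-up value); ``locf`` when missing for other reasons (last
    available follow-up); ``baseline-itt`` when no follow-up exists at all
    (flagged for the sensitivity analysis that excludes such subjects).
    """
    final = series.final_week
    if final in series.followups:
        return series.followups[final], "observed", False
    prior = {w: v for w, v in series.followups.items() if w < final}
    if not prior:
        return series.baseline, "baseline-itt", True
    cause = series.missing_causes.get(final, "other")
    if cause == "sae":
        worst = min(prior.values()) if series.higher_better else max(prior.values())
        return worst, "worst-prior", False
    last_week = max(prior)
    return prior[last_week], "locf", False


@dataclass(frozen=True)
class RandomizationScheme:
    """Permuted-block randomization, stratified by site, at a fixed ratio."""

    allocation_ratio: int = 2  # treatment : control (integer)
    block_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        unit = self.allocation_ratio + 1
        if self.block_size % unit != 0:
            raise TrialDesignError(
                f"block size must be a multiple of {unit} for a "
                f"{self.allocation_ratio}:1 ratio, got {self.block_size}"
            )


def blocked_randomization(
    subjects: Sequence[tuple[str, str]] | Sequence[str],
    scheme: RandomizationScheme | None = None,
) -> list[tuple[str, str, str]]:
    """Assign arms to (subject_id, site_id) pairs.

    Within every complete block at a site the treatment:control counts match
    the allocation ratio exactly (block 3 => 2 treatment, 1 control); blocks
    are permuted independently per site from the scheme's seed, so the
    sequence is reproducible and per-site imbalance never exceeds one
    incomplete block.
    """
    scheme = scheme or RandomizationScheme()
    pairs = [(s, "site-1") if isinstance(s, str) else (str(s[0]), str(s[1])) for s in subjects]
    sites = sorted({site for _, site in pairs})
    rng = np.random.default_rng(scheme.seed)
    site_rngs = {site: np.random.default_rng(rng.integers(0, 2**31)) for site in sites}
    unit = scheme.allocation_ratio + 1
    per_block = scheme.block_size
    block_template = ["treatment"] * (per_block * scheme.allocation_ratio // unit) + [
        "control"
    ] * (per_block // unit)
    queues: dict[str, list[str]] = {site: [] for site in sites}
    out: list[tuple[str, str, str]] = []
    for subj, site in pairs:
        if not queues[site]:
            block = list(block_template)
            site_rngs[site].shuffle(block)
            queues[site] = block
        out.append((subj, site, queues[site].pop(0)))
    return out
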