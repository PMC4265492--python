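"""Segmental treatment-option enumeration, constraint filtering and selection.

The planner works on a :class:`~segplan.densitometry.LungModel`.  A candidate
plan treats one segment of the primary upper lobe in session 1 and one or two
segments of the contralateral upper lobe in session 2.  Candidates are
filtered by per-session volume-fraction windows, a per-session absolute
volume cap and a segmental heterogeneity-index (HI) floor, then ranked:
options treating a lobe's unique least-diseased segment are dropped (unless
none would remain), the lowest combined TAR wins, near-ties within a small
combined-TAR tolerance are broken by proximity to the 110% combined-volume
target, and residual ties lexicographically for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .densitometry import (
    LEFT_TREATABLE,
    MERGED_APICOPOSTERIOR,
    RIGHT_TREATABLE,
    LungModel,
    SegmentDensitometry,
)

__all__ = [
    "Constraints",
    "TreatmentOption",
    "OptionAudit",
    "DiseaseRanking",
    "PlanSelection",
    "heterogeneity_index",
    "combined_tar",
    "enumerate_options",
    "apply_constraints",
    "classify_disease_rank",
    "select_plan",
    "plan_case",
]


class PlanningError(ValueError):
    pass


@dataclass(frozen=True)
class Constraints:
    """Planner thresholds.

    Fractions are percent of the upper-lobe volume (one lobe = 100%, both
    treated lobes combined = 200%); TAR tolerances are absolute percentage
    points on the TAR scale.  All comparisons are inclusive.
    """

    session1_fraction: tuple[float, float] = (30.0, 70.0)  # 50% +/- 20%
    session2_fraction: tuple[float, float] = (40.0, 80.0)  # 60% +/- 20%
    combined_fraction: tuple[float, float] = (95.0, 130.0)  # 110% +20/-15
    session_volume_cap_ml: float = 1700.0
    hi_minimum: float = 1.2
    equal_disease_tolerance: float = 2.0
    combined_tar_tolerance: float = 0.30
    combined_target: float = 110.0

    def __post_init__(self) -> None:
        for lo, hi in (self.session1_fraction, self.session2_fraction, self.combined_fraction):
            if not lo < hi:
                raise PlanningError(f"empty constraint window [{lo}, {hi}]")
        for v in (
            self.session_volume_cap_ml,
            self.hi_minimum,
            self.equal_disease_tolerance,
            self.combined_tar_tolerance,
            self.combined_target,
        ):
            if not v > 0:
                raise PlanningError(f"thresholds must be positive, got {v}")


@dataclass(frozen=True, order=True)
class TreatmentOption:
    """One candidate plan: a session-1 segment and 1-2 session-2 segments."""

    primary_side: str
    session1_segment: str
    session2_segments: tuple[str, ...]  # sorted, length 1 or 2

    def __post_init__(self) -> None:
        if self.primary_side not in ("left", "right"):
            raise PlanningError(f"bad primary side {self.primary_side!r}")
        if len(self.session2_segments) not in (1, 2):
            raise PlanningError("session 2 treats one or two segments")
        if tuple(sorted(self.session2_segments)) != self.session2_segments:
            raise PlanningError("session2_segments must be sorted")

    @property
    def key(self) -> str:
        return f"{self.primary_side}:{self.session1_segment}|{'&'.join(self.session2_segments)}"

    def anatomical_segments(self) -> frozenset[str]:
        """All anatomical segments treated (LB1+2 expands to LB1, LB2)."""
        out: set[str] = set()
        for seg in (self.session1_segment, *self.session2_segments):
            out |= _expand(seg)
        return frozenset(out)


def _expand(segment_id: str) -> set[str]:
    if segment_id == MERGED_APICOPOSTERIOR:
        return {"LB1", "LB2"}
    return {segment_id}


def heterogeneity_index(lower_lobe_tar: float, segment_tar: float) -> float:
    """HI = ipsilateral lower-lobe TAR / upper-segment TAR.

    A more diseased (less dense, lower-TAR) upper segment gives HI > 1;
    segments qualify for treatment when HI >= 1.2.
    """
    if not (lower_lobe_tar > 0 and segment_tar > 0):
        raise PlanningError(
            f"TARs must be positive, got lower={lower_lobe_tar}, segment={segment_tar}"
        )
    return lower_lobe_tar / segment_tar


def combined_tar(segments: Iterable[SegmentDensitometry]) -> float:
    """Volume-aggregated TAR over a set of segments: 100 * sum(tissue)/sum(air).

    Equivalent to the air-volume-weighted mean of the segmental TARs.
    """
    segments = list(segments)
    if not segments:
        raise PlanningError("combined TAR of an empty segment set is undefined")
    air = sum(s.air_volume for s in segments)
    if air <= 0:
        raise PlanningError("total air volume must be positive")
    return 100.0 * sum(s.tissue_volume for s in segments) / air


def _lobe_option_sets(side: str, sizes: tuple[int, ...]) -> list[tuple[str, ...]]:
    """Treatable segment subsets of a lobe, canonicalized.

    On the left, LB1 and LB2 may merge into the single LB1+2 segment; the
    pair {LB1, LB2} denotes the same tissue and is deduplicated to it, and
    LB1+2 never co-occurs with LB1 or LB2.
    """
    units = list(LEFT_TREATABLE) + [MERGED_APICOPOSTERIOR] if side == "left" else list(RIGHT_TREATABLE)
    out: set[tuple[str, ...]] = set()
    if 1 in sizes:
        out |= {(u,) for u in units}
    if 2 in sizes:
        for i, a in enumerate(units):
            for b in units[i + 1 :]:
                if _expand(a) & _expand(b):
                    continue  # LB1+2 overlaps LB1/LB2
                if {a, b} == {"LB1", "LB2"}:
                    out.add((MERGED_APICOPOSTERIOR,))  # same tissue as the merged single
                    continue
                out.add(tuple(sorted((a, b))))
    return sorted(out)


def enumerate_options(model: LungModel, primary_side: str = "both") -> list[TreatmentOption]:
    """Exhaustive, duplicate-free matrix of treatment options.

    Session 1 treats one segment of the primary lobe; session 2 treats one
    or two segments of the contralateral lobe.
    """
    if primary_side not in ("left", "right", "both"):
        raise PlanningError(f"primary_side must be left|right|both, got {primary_side!r}")
    sides = ("left", "right") if primary_side == "both" else (primary_side,)
    options: list[TreatmentOption] = []
    for side in sides:
        other = "right" if side == "left" else "left"
        for (s1,) in _lobe_option_sets(side, (1,)):
            for s2 in _lobe_option_sets(other, (1, 2)):
                options.append(
                    TreatmentOption(primary_side=side, session1_segment=s1, session2_segments=s2)
                )
    return options


@dataclass
class OptionAudit:
    """Every computed value and verdict for one enumerated option."""

    option: TreatmentOption
    session1_volume_ml: float = 0.0
    session2_volume_ml: float = 0.0
    session1_fraction: float = 0.0
    session2_fraction: float = 0.0
    combined_fraction: float = 0.0
    combined_tar: float = 0.0
    segment_hi: dict = field(default_factory=dict)
    checks: dict = field(default_factory=dict)  # constraint name -> bool
    removed_by: Optional[str] = None  # None while surviving
    in_tie_group: bool = False
    tie_break_distance: Optional[float] = None

    @property
    def passes_constraints(self) -> bool:
        return all(self.checks.values())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["option"] = {
            "primary_side": self.option.primary_side,
            "session1_segment": self.option.session1_segment,
            "session2_segments": list(self.option.session2_segments),
            "key": self.option.key,
        }
        return d


def _measure(option: TreatmentOption, model: LungModel, constraints: Constraints) -> OptionAudit:
    a = OptionAudit(option=option)
    side1 = option.primary_side
    side2 = "right" if side1 == "left" else "left"
    s1 = model.segment(option.session1_segment)
    s2 = [model.segment(s) for s in option.session2_segments]
    a.session1_volume_ml = s1.total_volume
    a.session2_volume_ml = sum(s.total_volume for s in s2)
    a.session1_fraction = 100.0 * a.session1_volume_ml / model.lobe_volume(side1)
    a.session2_fraction = 100.0 * a.session2_volume_ml / model.lobe_volume(side2)
    a.combined_fraction = a.session1_fraction + a.session2_fraction
    a.combined_tar = combined_tar([s1, *s2])
    for seg_id in (option.session1_segment, *option.session2_segments):
        seg = model.segment(seg_id)
        a.segment_hi[seg_id] = heterogeneity_index(
            model.lower_lobe_tar[model.side_of(seg_id)], seg.tar
        )
    lo1, hi1 = constraints.session1_fraction
    lo2, hi2 = constraints.session2_fraction
    loc, hic = constraints.combined_fraction
    a.checks = {
        "session1_fraction": lo1 <= a.session1_fraction <= hi1,
        "session2_fraction": lo2 <= a.session2_fraction <= hi2,
        "combined_fraction": loc <= a.combined_fraction <= hic,
        "session1_volume_cap": a.session1_volume_ml <= constraints.session_volume_cap_ml,
        "session2_volume_cap": a.session2_volume_ml <= constraints.session_volume_cap_ml,
        "segment_hi": all(h >= constraints.hi_minimum for h in a.segment_hi.values()),
    }
    return a


def apply_constraints(
    options: Sequence[TreatmentOption],
    model: LungModel,
    constraints: Constraints | None = None,
) -> tuple[list[TreatmentOption], dict[str, OptionAudit]]:
    """Filter options by the volume windows, cap and HI floor.

    Returns the survivors and a per-option audit keyed by option key.
    """
    constraints = constraints or Constraints()
    audits: dict[str, OptionAudit] = {}
    survivors: list[TreatmentOption] = []
    for opt in options:
        a = _measure(opt, model, constraints)
        if a.passes_constraints:
            survivors.append(opt)
        else:
            failed = sorted(name for name, ok in a.checks.items() if not ok)
            a.removed_by = "constraint:" + ",".join(failed)
        audits[opt.key] = a
    return survivors, audits


@dataclass(frozen=True)
class DiseaseRanking:
    """Disease-severity classification of a lobe's treatable segments.

    A unique least-diseased (largest-TAR) segment exists only when its TAR
    exceeds every other segment's by more than the equal-disease tolerance;
    symmetrically for the most diseased (smallest TAR).  Segments within
    tolerance of the extreme are tied.
    """

    labels: Mapping[str, str]  # segment id -> most|least|intermediate|tied
    least: Optional[str]
    most: Optional[str]
    least_tied: frozenset[str]
    most_tied: frozenset[str]


def classify_disease_rank(
    segments: Sequence[SegmentDensitometry], tolerance: float = 2.0
) -> DiseaseRanking:
    if len(segments) < 2:
        raise PlanningError("disease ranking needs at least two segments")
    tars = {s.segment_id: s.tar for s in segments}
    max_tar, min_tar = max(tars.values()), min(tars.values())
    least_group = frozenset(s for s, t in tars.items() if max_tar - t <= tolerance)
    most_group = frozenset(s for s, t in tars.items() if t - min_tar <= tolerance)
    least = next(iter(least_group)) if len(least_group) == 1 else None
    most = next(iter(most_group)) if len(most_group) == 1 else None
    labels: dict[str, str] = {}
    for s in tars:
        if s == least:
            labels[s] = "least"
        elif s == most:
            labels[s] = "most"
        elif (least is None and s in least_group) or (most is None and s in most_group):
            labels[s] = "tied"
        else:
            labels[s] = "intermediate"
    return DiseaseRanking(
        labels=labels, least=least, most=most, least_tied=least_group, most_tied=most_group
    )


@dataclass
class PlanSelection:
    """The chosen plan (if any) plus the full decision trace."""

    chosen: Optional[TreatmentOption]
    feasible: bool
    audits: dict[str, OptionAudit]
    rankings: dict[str, DiseaseRanking]
    tie_group: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "feasible": self.feasible,
            "chosen": None
            if self.chosen is None
            else {
                "primary_side": self.chosen.primary_side,
                "session1_segment": self.chosen.session1_segment,
                "session2_segments": list(self.chosen.session2_segments),
                "key": self.chosen.key,
                "metrics": {
                    k: v
                    for k, v in self.audits[self.chosen.key].to_dict().items()
                    if k not in ("option", "checks", "removed_by")
                },
            },
            "tie_group": self.tie_group,
            "rankings": {
                side: {
                    "labels": dict(r.labels),
                    "least": r.least,
                    "most": r.most,
                }
                for side, r in self.rankings.items()
            },
            "notes": self.notes,
            "options": [a.to_dict() for a in self.audits.values()],
        }


def select_plan(
    survivors: Sequence[TreatmentOption],
    model: LungModel,
    constraints: Constraints | None = None,
    audits: dict[str, OptionAudit] | None = None,
) -> PlanSelection:
    """Pick the preferred plan from constraint survivors.

    Steps: drop options treating a lobe's unique least-diseased segment
    (guarded so the set never empties); then minimum combined TAR; near-ties
    within the combined-TAR tolerance go to the option closest to the
    combined-volume target; residual exact ties break lexicographically.
    """
    constraints = constraints or Constraints()
    audits = audits if audits is not None else {}
    for opt in survivors:
        if opt.key not in audits:
            audits[opt.key] = _measure(opt, model, constraints)

    rankings = {
        side: classify_disease_rank(
            [model.segments[s] for s in model.treatable_ids(side)],
            constraints.equal_disease_tolerance,
        )
        for side in ("left", "right")
    }
    sel = PlanSelection(
        chosen=None, feasible=False, audits=audits, rankings=rankings
    )
    cands = list(survivors)
    if not cands:
        sel.notes.append("no option satisfies the volume and HI constraints")
        return sel

    # Dominance: preserve each lobe's unique least-diseased segment when any
    # alternative exists.
    for side in ("left", "right"):
        least = rankings[side].least
        if least is None:
            continue
        kept = [o for o in cands if least not in o.anatomical_segments()]
        if kept:
            for o in cands:
                if o not in kept:
                    audits[o.key].removed_by = f"dominance:{least}"
            cands = kept
            sel.notes.append(f"removed options treating least-diseased {least} ({side})")
        else:
            sel.notes.append(
                f"all remaining options treat least-diseased {least} ({side}); none removed"
            )

    if len(cands) > 1:
        ctars = {o.key: audits[o.key].combined_tar for o in cands}
        best_tar = min(ctars.values())
        tie = [o for o in cands if ctars[o.key] - best_tar <= constraints.combined_tar_tolerance]
        for o in cands:
            if o not in tie:
                audits[o.key].removed_by = "combined_tar"
        for o in tie:
            audits[o.key].in_tie_group = True
            audits[o.key].tie_break_distance = abs(
                audits[o.key].combined_fraction - constraints.combined_target
            )
        sel.tie_group = [o.key for o in tie]
        cands = sorted(
            tie,
            key=lambda o: (
                audits[o.key].tie_break_distance,
                o.primary_side,
                o.session1_segment,
                o.session2_segments,
            ),
        )
        for o in cands[1:]:
            audits[o.key].removed_by = "tie_break"

    chosen = cands[0]
    audits[chosen.key].removed_by = None
    sel.chosen = chosen
    sel.feasible = True
    return sel


def plan_case(
    model: LungModel,
    constraints: Constraints | None = None,
    primary_side: str = "both",
) -> PlanSelection:
    """Full pipeline: enumerate -> constrain -> select, with audit."""
    constraints = constraints or Constraints()
    options = enumerate_options(model, primary_side)
    survivors, audits = apply_constraints(options, model, constraints)
    return select_plan(survivors, model, constraints, audits)
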