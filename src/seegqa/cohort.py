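"""Plan/implant pairing, per-electrode accuracy records, cohort summaries.

The per-electrode deviation metrics follow the standard stereotactic
vocabulary: LE / LT are lateral shifts (point-to-line distance from the
planned trajectory) of the implanted entry and target points, EE / ET are
the Euclidean distances between corresponding planned and implanted points,
the depth error is the signed along-axis component of the target
displacement (positive = implanted deeper than planned) and the angle is
the angular deviation between the planned and implanted directions.

By construction ``ET^2 = LT^2 + depth^2`` and ``LE <= EE``: lateral shift
cannot see insertion-depth errors, which is why records carry both.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from seegqa.geometry3d import (
    GeometryError,
    Line3,
    angle_between,
    axial_coordinate,
    euclidean_distance,
    lateral_shift,
)
from seegqa.electrode import (
    EntrySurface,
    ImplantedElectrode,
    PlannedTrajectory,
    A4_OUTSIDE_MARGIN_MM,
    A4_WINDOW_MM,
    bolt_axis_trajectory,
    electrode_length,
    estimate_trajectory,
    implanted_target_point,
    skull_thickness,
    surface_entry_point,
)

__all__ = [
    "AccuracyRecord",
    "CohortSummary",
    "ElectrodePair",
    "compare_surfaces",
    "compute_accuracy",
    "pair_electrodes",
    "records_to_frame",
    "summarize_cohort",
]

#: candidate plan/implant pairs further apart than this at the entry are
#: never matched (guards against nonsense matches; no clinical basis needed
#: at sane implantation accuracies of a few mm)
MAX_EP_DISTANCE_MM = 15.0
#: entry distances within this tolerance are considered tied, letting the
#: second pairing criterion (angle) decide
DISTANCE_TIE_TOL_MM = 0.5


@dataclass(frozen=True)
class ElectrodePair:
    planned: PlannedTrajectory
    implanted: ImplantedElectrode
    pairing_distance: float
    pairing_angle: float


@dataclass(frozen=True)
class AccuracyRecord:
    """All deviation metrics for one paired electrode under one
    (trajectory estimator, entry surface) choice."""

    electrode_id: str
    method: str
    surface_kind: str
    source_tag: str
    LE: float
    EE: float
    LT: float
    ET: float
    depth_error: float
    angle: float
    length: float
    max_contact_displacement: float
    skull_thickness: float | None = None
    group_label: str | None = None


def pair_electrodes(
    planned,
    implanted,
    surface: EntrySurface | None = None,
    max_ep_distance: float = MAX_EP_DISTANCE_MM,
    distance_tie_tol: float = DISTANCE_TIE_TOL_MM,
):
    """Automatically pair planned with implanted electrodes.

    Greedy one-to-one matching over all candidate pairs ordered
    lexicographically by (entry distance quantized to ``distance_tie_tol``,
    trajectory angle): the closest entry points win, and within a distance
    tie the lowest angle between trajectories decides.  When a surface is
    given both entries are re-projected onto it; otherwise the bolt head
    serves as the implanted-entry proxy.

    Returns ``(pairs, unmatched_planned, unmatched_implanted)``.
    """
    if not planned or not implanted:
        raise ValueError("both electrode lists must be nonempty")
    if distance_tie_tol <= 0:
        raise ValueError("distance_tie_tol must be > 0")

    plan_eps, plan_dirs = [], []
    for p in planned:
        line = p.line
        ep = p.planned_ep if surface is None else surface_entry_point(line, p.planned_ep, surface)
        plan_eps.append(ep)
        plan_dirs.append(line.direction)
    impl_eps, impl_dirs = [], []
    for e in implanted:
        traj = bolt_axis_trajectory(e)
        ep = e.bolt_head if surface is None else surface_entry_point(traj.line, e.bolt_head, surface)
        impl_eps.append(ep)
        impl_dirs.append(traj.line.direction)

    candidates = []
    for i, p in enumerate(planned):
        for j, e in enumerate(implanted):
            dist = euclidean_distance(plan_eps[i], impl_eps[j])
            if dist > max_ep_distance:
                continue
            ang = angle_between(plan_dirs[i], impl_dirs[j])
            # quantized distance first, angle breaks ties; ids make the
            # ordering fully deterministic
            key = (round(dist / distance_tie_tol), ang, p.electrode_id, e.electrode_id)
            candidates.append((key, i, j, dist, ang))
    candidates.sort(key=lambda c: c[0])

    pairs = []
    used_p: set[int] = set()
    used_i: set[int] = set()
    for _, i, j, dist, ang in candidates:
        if i in used_p or j in used_i:
            continue
        used_p.add(i)
        used_i.add(j)
        pairs.append(ElectrodePair(planned[i], implanted[j], dist, ang))
    unmatched_planned = [p for i, p in enumerate(planned) if i not in used_p]
    unmatched_implanted = [e for j, e in enumerate(implanted) if j not in used_i]
    return pairs, unmatched_planned, unmatched_implanted


def compute_accuracy(
    pair: ElectrodePair,
    method: str,
    surface: EntrySurface,
    outer_skull: EntrySurface | None = None,
    inner_skull: EntrySurface | None = None,
    window: float = A4_WINDOW_MM,
    outside_margin: float = A4_OUTSIDE_MARGIN_MM,
) -> AccuracyRecord:
    """All accuracy metrics for one pair under one (estimator, surface).

    Both the planned and the implanted entry point are defined at the
    intersection of the respective trajectory with ``surface``; the target
    point is the planned target vs. the most distal contact.
    """
    plan = pair.planned
    impl = pair.implanted
    planned_line = plan.line
    est = estimate_trajectory(impl, method, window=window, outside_margin=outside_margin)

    planned_ep = surface_entry_point(planned_line, plan.planned_ep, surface)
    implanted_ep = surface_entry_point(est.line, impl.bolt_head, surface)
    tp = implanted_target_point(impl)

    le = lateral_shift(implanted_ep, planned_line)
    ee = euclidean_distance(planned_ep, implanted_ep)
    lt = lateral_shift(tp, planned_line)
    et = euclidean_distance(plan.planned_tp, tp)
    depth = axial_coordinate(tp, planned_line) - axial_coordinate(plan.planned_tp, planned_line)
    ang = angle_between(planned_line.direction, est.line.direction)

    thickness = None
    if outer_skull is not None and inner_skull is not None:
        try:
            thickness = skull_thickness(est.line, outer_skull, inner_skull, impl.bolt_head)
        except GeometryError:
            thickness = None

    return AccuracyRecord(
        electrode_id=plan.electrode_id,
        method=method,
        surface_kind=surface.surface_kind,
        source_tag=surface.source_tag,
        LE=le,
        EE=ee,
        LT=lt,
        ET=et,
        depth_error=depth,
        angle=ang,
        length=electrode_length(impl, implanted_ep),
        max_contact_displacement=est.max_contact_displacement,
        skull_thickness=thickness,
        group_label=plan.group_label,
    )


def records_to_frame(records) -> pd.DataFrame:
    """Records as a tidy DataFrame, one row per electrode x method x surface."""
    return pd.DataFrame([asdict(r) for r in records])


_SUMMARY_METRICS = ["length", "skull_thickness", "max_contact_displacement", "LE", "LT", "angle"]


@dataclass
class CohortSummary:
    """Per-case and overall means/SDs, optionally stratified by group label."""

    per_case: pd.DataFrame
    total: pd.DataFrame

    @property
    def n_total(self) -> int:
        return int(self.total.loc[self.total["group"] == "all", "n"].iloc[0])


def _agg(df: pd.DataFrame, by_group: bool) -> list[dict]:
    out = []
    groups = [("all", df)]
    if by_group:
        groups += [(str(g), sub) for g, sub in df.groupby("group_label", dropna=False) if len(sub)]
    for gname, sub in groups:
        row = {"group": gname, "n": len(sub)}
        for m in _SUMMARY_METRICS:
            vals = pd.to_numeric(sub[m], errors="coerce").dropna() if m in sub else pd.Series(dtype=float)
            row[f"{m}_mean"] = float(vals.mean()) if len(vals) else float("nan")
            row[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0 if len(vals) == 1 else float("nan")
        out.append(row)
    return out


def summarize_cohort(records, case_ids: dict | None = None) -> CohortSummary:
    """Cohort summary: per-case and overall mean (SD) of the descriptive
    metrics, overall and stratified by group label.

    ``case_ids`` maps electrode_id -> case/patient id; electrodes without a
    mapping fall into a single implicit case.
    """
    df = records_to_frame(list(records))
    if df.empty:
        raise ValueError("no records to summarize")
    df["case"] = df["electrode_id"].map(case_ids or {}).fillna("case0")

    per_case_rows = []
    for case, sub in df.groupby("case", sort=True):
        for row in _agg(sub, by_group=True):
            per_case_rows.append({"case": case, **row})
    total_rows = _agg(df, by_group=True)
    return CohortSummary(per_case=pd.DataFrame(per_case_rows), total=pd.DataFrame(total_rows))


def compare_surfaces(records_scalp, records_skull) -> pd.DataFrame:
    """Per-electrode LE differences (scalp minus skull) for agreement tests.

    Records are paired by (electrode_id, method); unpairable ids are an
    error.  Returns a frame with one row per pair plus mean/SD attributes.
    """
    a = records_to_frame(list(records_scalp))
    b = records_to_frame(list(records_skull))
    key = ["electrode_id", "method"]
    merged = a[key + ["LE"]].merge(b[key + ["LE"]], on=key, suffixes=("_scalp", "_skull"), how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", "electrode_id"].tolist()
        raise ValueError(f"unpairable electrode ids between surfaces: {bad}")
    merged = merged.drop(columns="_merge")
    merged["LE_diff"] = merged["LE_scalp"] - merged["LE_skull"]
    merged.attrs["mean_diff"] = float(merged["LE_diff"].mean())
    merged.attrs["sd_diff"] = float(merged["LE_diff"].std(ddof=1)) if len(merged) > 1 else 0.0
    return merged
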