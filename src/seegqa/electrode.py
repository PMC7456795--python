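"""Electrode-level estimation: implanted trajectories, entry/target points.

An implanted SEEG electrode is described by three segmented landmark sets in
one world space (mm): the bolt head, the pivot point (the bolt's distal end
at the skull) and the ordered contact centroids, deepest first.  From these,
four straight-trajectory estimators are available:

* **A1** — the bolt axis (bolt head → pivot), the rigid guide direction.
* **A2 / A3** — line of best fit through the 2 / 3 most proximal contacts.
* **A4** — line of best fit through the most superficial contact fully
  outside the bolt and every contact within 20 mm of it.

Entry points are defined by intersecting a trajectory with a head-surface
mesh (scalp or skull); the implanted target point is the most distal contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from seegqa.geometry3d import (
    GeometryError,
    Line3,
    TriMesh,
    axial_coordinate,
    euclidean_distance,
    fit_line_tls,
    lateral_shift,
    line_mesh_intersections,
    unit,
)

__all__ = [
    "EntrySurface",
    "ImplantedElectrode",
    "PlannedTrajectory",
    "TrajectoryEstimate",
    "bolt_axis_trajectory",
    "electrode_length",
    "implanted_target_point",
    "lbf_trajectory",
    "load_electrodes",
    "load_plans",
    "save_electrodes",
    "save_plans",
    "select_a4_contacts",
    "skull_thickness",
    "surface_entry_point",
]

METHODS = ("A1", "A2", "A3", "A4")
SURFACE_KINDS = ("scalp", "outer_skull", "inner_skull")

#: default line-of-best-fit window: contacts within this distance (mm) of the
#: anchor contact are included in the A4 fit
A4_WINDOW_MM = 20.0
#: default margin (mm) past the pivot for a contact to count as fully outside
#: the bolt (about half a typical contact length)
A4_OUTSIDE_MARGIN_MM = 1.2


@dataclass(frozen=True)
class PlannedTrajectory:
    """A planned electrode: entry and target points in world mm."""

    electrode_id: str
    planned_ep: np.ndarray
    planned_tp: np.ndarray
    group_label: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "planned_ep", np.asarray(self.planned_ep, dtype=float))
        object.__setattr__(self, "planned_tp", np.asarray(self.planned_tp, dtype=float))
        if euclidean_distance(self.planned_ep, self.planned_tp) <= 1.0:
            raise ValueError(
                f"plan {self.electrode_id}: entry and target separated by <= 1 mm"
            )

    @property
    def line(self) -> Line3:
        """Planned trajectory, oriented entry → target (proximal → distal)."""
        return Line3.through(self.planned_ep, self.planned_tp)


@dataclass(frozen=True)
class ImplantedElectrode:
    """A segmented implanted electrode.

    ``contacts[0]`` is the most distal (deepest) contact; the loader and the
    constructor validate that contact axial coordinates along the bolt axis
    strictly decrease with index (deepest-first convention).
    """

    electrode_id: str
    bolt_head: np.ndarray
    pivot: np.ndarray
    contacts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "bolt_head", np.asarray(self.bolt_head, dtype=float))
        object.__setattr__(self, "pivot", np.asarray(self.pivot, dtype=float))
        object.__setattr__(self, "contacts", np.atleast_2d(np.asarray(self.contacts, dtype=float)))
        if self.contacts.shape[0] < 2 or self.contacts.shape[1] != 3:
            raise ValueError(f"electrode {self.electrode_id}: need >= 2 contacts")
        if np.allclose(self.bolt_head, self.pivot):
            raise ValueError(f"electrode {self.electrode_id}: bolt head equals pivot")
        axis = self.bolt_axis
        ax = self.contacts @ axis.direction - np.dot(axis.origin, axis.direction)
        if not np.all(np.diff(ax) < 0):
            raise ValueError(
                f"electrode {self.electrode_id}: contacts are not ordered "
                "deepest-first (axial coordinates must strictly decrease)"
            )

    @property
    def bolt_axis(self) -> Line3:
        """Bolt axis through the pivot, oriented into the head."""
        return Line3(self.pivot, self.pivot - self.bolt_head)

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)


@dataclass(frozen=True)
class TrajectoryEstimate:
    """A straight implanted-trajectory estimate with its provenance.

    ``line`` is oriented proximal→distal (entry → target).
    ``max_contact_displacement`` is the largest lateral shift of the
    contacts considered from the estimated line — a bending/segmentation
    quality indicator that should accompany any line-of-best-fit metric.
    """

    line: Line3
    method: str
    contacts_used: tuple[int, ...]
    max_contact_displacement: float

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown trajectory method {self.method!r}")
        n = len(self.contacts_used)
        if self.method == "A1" and n != 0:
            raise ValueError("A1 (bolt axis) uses no contacts")
        if self.method == "A2" and n != 2:
            raise ValueError("A2 uses exactly 2 contacts")
        if self.method == "A3" and n != 3:
            raise ValueError("A3 uses exactly 3 contacts")
        if self.method == "A4" and n < 2:
            raise ValueError("A4 needs >= 2 contacts")


@dataclass(frozen=True)
class EntrySurface:
    """A head-surface mesh used to define entry points."""

    mesh: TriMesh
    surface_kind: str = "scalp"
    source_tag: str = ""

    def __post_init__(self):
        if self.surface_kind not in SURFACE_KINDS:
            raise ValueError(f"unknown surface kind {self.surface_kind!r}")


def bolt_axis_trajectory(e: ImplantedElectrode) -> TrajectoryEstimate:
    """A1 estimator: the bolt axis, origin at the pivot, pointing distally."""
    line = e.bolt_axis
    disp = max(lateral_shift(c, line) for c in e.contacts)
    return TrajectoryEstimate(line=line, method="A1", contacts_used=(), max_contact_displacement=disp)


def select_a4_contacts(
    e: ImplantedElectrode,
    window: float = A4_WINDOW_MM,
    outside_margin: float = A4_OUTSIDE_MARGIN_MM,
) -> list[int]:
    """Contacts entering the A4 line of best fit.

    The anchor is the most superficial (proximal) contact fully outside the
    bolt — axial coordinate past the pivot greater than ``outside_margin`` —
    and the selection is the anchor plus every deeper contact within
    ``window`` mm (Euclidean, inclusive) of it, returned distal-first.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    axis = e.bolt_axis
    ax = np.array([axial_coordinate(c, axis) for c in e.contacts])
    outside = np.nonzero(ax > outside_margin)[0]
    if len(outside) == 0:
        raise GeometryError(f"electrode {e.electrode_id}: no anchor contact outside the bolt")
    anchor = int(outside[np.argmin(ax[outside])])  # most proximal outside contact
    anchor_pt = e.contacts[anchor]
    selected = [
        i
        for i in range(e.n_contacts)
        if ax[i] >= ax[anchor] - 1e-12
        and euclidean_distance(e.contacts[i], anchor_pt) <= window + 1e-12
    ]
    selected.sort()  # index 0 is deepest: ascending index = distal-first
    if len(selected) < 2:
        raise GeometryError(f"electrode {e.electrode_id}: insufficient contacts for fit")
    return selected


def lbf_trajectory(
    e: ImplantedElectrode,
    method: str = "A4",
    window: float = A4_WINDOW_MM,
    outside_margin: float = A4_OUTSIDE_MARGIN_MM,
) -> TrajectoryEstimate:
    """Line-of-best-fit estimators A2/A3/A4.

    A2 and A3 fit the 2 or 3 most proximal contacts (largest indices); A4
    fits the :func:`select_a4_contacts` window.  The fitted line is a total
    least squares fit, re-oriented proximal→distal (nonnegative dot with the
    pivot → deepest-contact vector).
    """
    if method not in ("A2", "A3", "A4"):
        raise ValueError(f"lbf_trajectory handles A2/A3/A4, not {method!r}")
    if method == "A4":
        idx = select_a4_contacts(e, window=window, outside_margin=outside_margin)
    else:
        k = 2 if method == "A2" else 3
        if e.n_contacts < k:
            raise GeometryError(f"electrode {e.electrode_id}: fewer than {k} contacts")
        idx = list(range(e.n_contacts - k, e.n_contacts))  # most proximal = largest indices
    pts = e.contacts[idx]
    line = fit_line_tls(pts)
    distal = e.contacts[0] - e.pivot
    if np.dot(line.direction, distal) < 0:
        line = Line3(line.origin, -line.direction)
    disp = max(lateral_shift(p, line) for p in pts)
    return TrajectoryEstimate(
        line=line, method=method, contacts_used=tuple(idx), max_contact_displacement=disp
    )


def estimate_trajectory(
    e: ImplantedElectrode,
    method: str,
    window: float = A4_WINDOW_MM,
    outside_margin: float = A4_OUTSIDE_MARGIN_MM,
) -> TrajectoryEstimate:
    """Dispatch to the A1 or A2/A3/A4 estimator by name."""
    if method == "A1":
        return bolt_axis_trajectory(e)
    return lbf_trajectory(e, method, window=window, outside_margin=outside_margin)


def implanted_target_point(e: ImplantedElectrode) -> np.ndarray:
    """The implanted target point: the most distal contact."""
    if e.n_contacts < 1:
        raise ValueError("electrode has no contacts")
    return e.contacts[0]


def surface_entry_point(traj: Line3, reference, surface: EntrySurface) -> np.ndarray:
    """Entry point: the trajectory/mesh intersection nearest ``reference``.

    The reference (bolt head for an implanted trajectory, planned entry for
    a plan) disambiguates multi-sheet intersections such as ears or the
    contralateral scalp.
    """
    hits = line_mesh_intersections(traj, surface.mesh)
    if not hits:
        raise GeometryError("trajectory misses surface")
    ref = np.asarray(reference, dtype=float)
    best = min(hits, key=lambda h: float(np.linalg.norm(h[0] - ref)))
    return best[0]


def electrode_length(e: ImplantedElectrode, entry) -> float:
    """Implanted length: entry point to deepest contact (mm)."""
    return euclidean_distance(entry, implanted_target_point(e))


def skull_thickness(traj: Line3, outer: EntrySurface, inner: EntrySurface, reference) -> float:
    """Bone span traversed along the trajectory (mm).

    Distance between the outer-skull intersection nearest ``reference`` and
    the inner-skull intersection nearest that outer point, measured along
    the trajectory.
    """
    outer_pt = surface_entry_point(traj, reference, outer)
    inner_pt = surface_entry_point(traj, outer_pt, inner)
    return euclidean_distance(outer_pt, inner_pt)


# ---------------------------------------------------------------------------
# File I/O — plain CSV/JSON schemas, always world millimetres.

_ELECTRODE_COLS = ["electrode_id", "role", "index", "x_mm", "y_mm", "z_mm"]
_PLAN_COLS = ["electrode_id", "ep_x_mm", "ep_y_mm", "ep_z_mm", "tp_x_mm", "tp_y_mm", "tp_z_mm", "group_label"]


def load_plans(path) -> list[PlannedTrajectory]:
    """Read planned trajectories from CSV (or an equivalent JSON list)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, comment="#")
    missing = [c for c in _PLAN_COLS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: plan file missing columns {missing}")
    plans = []
    for _, r in df.iterrows():
        label = r.get("group_label")
        if pd.isna(label):
            label = None
        plans.append(
            PlannedTrajectory(
                electrode_id=str(r["electrode_id"]),
                planned_ep=[r["ep_x_mm"], r["ep_y_mm"], r["ep_z_mm"]],
                planned_tp=[r["tp_x_mm"], r["tp_y_mm"], r["tp_z_mm"]],
                group_label=None if label is None else str(label),
            )
        )
    return plans


def save_plans(plans, path) -> None:
    rows = [
        {
            "electrode_id": p.electrode_id,
            "ep_x_mm": p.planned_ep[0],
            "ep_y_mm": p.planned_ep[1],
            "ep_z_mm": p.planned_ep[2],
            "tp_x_mm": p.planned_tp[0],
            "tp_y_mm": p.planned_tp[1],
            "tp_z_mm": p.planned_tp[2],
            "group_label": p.group_label if p.group_label is not None else "",
        }
        for p in plans
    ]
    pd.DataFrame(rows, columns=_PLAN_COLS).to_csv(path, index=False)


def load_electrodes(path) -> list[ImplantedElectrode]:
    """Read implanted electrodes from long-format CSV (or equivalent JSON).

    One row per landmark: ``electrode_id,role,index,x_mm,y_mm,z_mm`` with
    role in {bolt_head, pivot, contact}; contacts indexed 0..n-1 deepest
    first.  Files violating the deepest-first ordering are rejected, not
    silently reordered.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path, comment="#")
    missing = [c for c in _ELECTRODE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: electrode file missing columns {missing}")
    out = []
    for eid, grp in df.groupby("electrode_id", sort=True):
        def one(role):
            sel = grp[grp["role"] == role]
            if len(sel) != 1:
                raise ValueError(f"{path}: electrode {eid} needs exactly one {role} row")
            r = sel.iloc[0]
            return [r["x_mm"], r["y_mm"], r["z_mm"]]

        contacts = grp[grp["role"] == "contact"].sort_values("index")
        if len(contacts) < 2:
            raise ValueError(f"{path}: electrode {eid} has fewer than 2 contact rows")
        idx = contacts["index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ValueError(f"{path}: electrode {eid} contact indices must be 0..n-1")
        out.append(
            ImplantedElectrode(
                electrode_id=str(eid),
                bolt_head=one("bolt_head"),
                pivot=one("pivot"),
                contacts=contacts[["x_mm", "y_mm", "z_mm"]].to_numpy(),
            )
        )
    return out


def save_electrodes(electrodes, path) -> None:
    rows = []
    for e in electrodes:
        rows.append({"electrode_id": e.electrode_id, "role": "bolt_head", "index": 0,
                     "x_mm": e.bolt_head[0], "y_mm": e.bolt_head[1], "z_mm": e.bolt_head[2]})
        rows.append({"electrode_id": e.electrode_id, "role": "pivot", "index": 0,
                     "x_mm": e.pivot[0], "y_mm": e.pivot[1], "z_mm": e.pivot[2]})
        for i, c in enumerate(e.contacts):
            rows.append({"electrode_id": e.electrode_id, "role": "contact", "index": i,
                         "x_mm": c[0], "y_mm": c[1], "z_mm": c[2]})
    pd.DataFrame(rows, columns=_ELECTRODE_COLS).to_csv(path, index=False)
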