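"""Synthetic implantation phantom: ground-truthed cohorts of SEEG electrodes.

The phantom emulates a head as a triaxial ellipsoid (scalp) with an offset
outer-skull surface and an inner-skull surface whose thickness is reduced
over a lateral "temporal" sector.  Planned trajectories start on the scalp
and run near-radially inward; implanted electrodes are derived from the
plan by applying controlled, individually recoverable deviations:

* an entry shift perpendicular to the planned direction (translating the
  whole trajectory laterally, approximately tangent to the scalp for the
  near-radial trajectories generated here),
* a tilt of the trajectory about the (shifted) entry point,
* a signed insertion-depth error along the tilted axis,
* optional quadratic bending beyond the pivot, and
* isotropic Gaussian noise on each contact centroid.

Every generated electrode carries its exact ground-truth deviations, so
the full pipeline (mesh entry points, line fitting, pairing, metrics) can
be validated by parameter recovery.  A rasterized CT counterpart with
documented intensity bands exercises the image-domain operators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from seegqa.geometry3d import Line3, TriMesh, lateral_shift, axial_coordinate, unit
from seegqa.electrode import EntrySurface, ImplantedElectrode, PlannedTrajectory
from seegqa.cohort import AccuracyRecord

__all__ = [
    "Cohort",
    "GroundTruth",
    "PhantomSpec",
    "generate_cohort",
    "rasterize_ct",
    "true_metrics",
    "INTENSITY_BANDS",
]

#: rasterized-CT intensity bands (arbitrary units, documented contract):
#: thresholding strictly above a band's lower neighbour isolates it.  The
#: "tissue" band fills the whole head interior (so the scalp level set is a
#: single closed sheet); skull, bolts and contacts overwrite it.
INTENSITY_BANDS = {
    "background": 0.0,
    "tissue": 100.0,
    "skull": 400.0,
    "bolt": 900.0,
    "contact": 1600.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Generator conventions for one synthetic cohort.

    All lengths in mm, angles in degrees.  The deviation magnitudes are the
    *true* per-electrode values when ``randomize_magnitudes`` is False; when
    True, each electrode draws its own magnitude uniformly from
    [0.25, 1.75] x the nominal value, which spreads the ground truth for
    recovery-regression experiments.
    """

    seed: int = 0
    n_cases: int = 1
    electrodes_per_case: int = 10
    scalp_semi_axes: tuple[float, float, float] = (95.0, 80.0, 70.0)
    skull_offset_mm: float = 5.0
    skull_thickness_mm: float = 7.0
    thin_patch_factor: float = 0.45  # temporal-sector thickness multiplier
    contact_spacing_mm: float = 5.0
    contacts_per_electrode: int = 10
    bolt_length_mm: float = 25.0
    # deviation magnitudes
    entry_shift_mm: float = 0.0
    tilt_deg: float = 0.0
    depth_error_mm: float = 0.0  # signed: positive = deeper than planned
    bend_deg_per_10mm: float = 0.0
    contact_noise_mm: float = 0.0
    randomize_magnitudes: bool = False
    mesh_subdivisions: int = 4

    def __post_init__(self):
        if min(self.scalp_semi_axes) <= 0:
            raise ValueError("scalp semi-axes must be positive")
        for name in ("entry_shift_mm", "tilt_deg", "bend_deg_per_10mm", "contact_noise_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.contacts_per_electrode < 2:
            raise ValueError("need at least 2 contacts per electrode")


@dataclass
class GroundTruth:
    """Per-electrode generative truth (one row per electrode).

    Columns: electrode_id, case_id, group_label, true_angle_deg,
    true_entry_offset_mm, true_target_offset_mm, true_depth_mm, bent,
    planned/implanted entry, direction and target coordinates.
    """

    frame: pd.DataFrame
    seed: int


@dataclass
class Cohort:
    """A generated phantom cohort: plans, implants, surfaces, truth."""

    plans: list
    implants: list
    surfaces: dict
    ground_truth: GroundTruth
    spec: PhantomSpec

    @property
    def case_ids(self) -> dict:
        return dict(zip(self.ground_truth.frame["electrode_id"], self.ground_truth.frame["case_id"]))


# --- ellipsoid helpers ------------------------------------------------------

def _ellipsoid_radius(dirs: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Radius of the ellipsoid with semi-axes ``axes`` along unit rays."""
    d = np.atleast_2d(dirs)
    return 1.0 / np.sqrt(np.sum((d / axes) ** 2, axis=1))


def _temporal_weight(u: np.ndarray) -> np.ndarray:
    """Smooth membership of unit-sphere points in the lateral temporal sector."""
    u = np.atleast_2d(u)

    def smoothstep(x):
        x = np.clip(x, 0.0, 1.0)
        return x * x * (3.0 - 2.0 * x)

    wx = smoothstep((np.abs(u[:, 0]) - 0.55) / 0.15)
    wz = smoothstep((0.40 - np.abs(u[:, 2])) / 0.15)
    return wx * wz


def _skull_thickness_at(u: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    w = _temporal_weight(u)
    return spec.skull_thickness_mm * (1.0 - (1.0 - spec.thin_patch_factor) * w)


def _line_ellipsoid_hits(origin, direction, axes):
    """Analytic intersections of a line with an origin-centered ellipsoid.

    Returns sorted line parameters t (may be empty).
    """
    o = np.asarray(origin, dtype=float) / axes
    d = np.asarray(direction, dtype=float) / axes
    a = float(d @ d)
    b = 2.0 * float(o @ d)
    c = float(o @ o) - 1.0
    disc = b * b - 4 * a * c
    if disc < 0:
        return np.array([])
    r = np.sqrt(disc)
    return np.sort(np.array([(-b - r) / (2 * a), (-b + r) / (2 * a)]))


def _ellipsoid_mesh(axes: np.ndarray, subdivisions: int, inner_offset=None) -> TriMesh:
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = np.asarray(ico.vertices)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    verts = u * axes
    if inner_offset is not None:
        r = np.linalg.norm(verts, axis=1, keepdims=True)
        verts = verts * (1.0 - inner_offset[:, None] / r)
    return TriMesh(verts, np.asarray(ico.faces))


def _perp_unit(d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A uniformly random unit vector perpendicular to ``d``."""
    while True:
        v = rng.normal(size=3)
        v = v - np.dot(v, d) * d
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def _rotate(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis``."""
    th = np.radians(angle_deg)
    return (
        v * np.cos(th)
        + np.cross(axis, v) * np.sin(th)
        + axis * np.dot(axis, v) * (1.0 - np.cos(th))
    )


# --- cohort generation ------------------------------------------------------

def build_surfaces(spec: PhantomSpec) -> dict:
    """Scalp, outer-skull and inner-skull meshes for a spec."""
    axes = np.asarray(spec.scalp_semi_axes, dtype=float)
    scalp = _ellipsoid_mesh(axes, spec.mesh_subdivisions)
    outer_axes = axes - spec.skull_offset_mm
    outer = _ellipsoid_mesh(outer_axes, spec.mesh_subdivisions)
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=spec.mesh_subdivisions, radius=1.0)
    u = np.asarray(ico.vertices)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    inner = _ellipsoid_mesh(outer_axes, spec.mesh_subdivisions, inner_offset=_skull_thickness_at(u, spec))
    return {
        "scalp": EntrySurface(scalp, "scalp", "phantom"),
        "outer_skull": EntrySurface(outer, "outer_skull", "phantom"),
        "inner_skull": EntrySurface(inner, "inner_skull", "phantom"),
    }


def _sample_entry_dirs(rng, n, axes, min_spacing):
    """Unit-sphere directions whose scalp points are pairwise >= min_spacing."""
    chosen_u: list[np.ndarray] = []
    chosen_p: list[np.ndarray] = []
    tries = 0
    while len(chosen_u) < n:
        tries += 1
        if tries > 20000:
            raise ValueError("infeasible entry spacing for this cohort size")
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if v[2] < -0.15:  # keep entries off the skull base
            continue
        p = v * _ellipsoid_radius(v, axes)[0]
        if all(np.linalg.norm(p - q) >= min_spacing for q in chosen_p):
            chosen_u.append(v)
            chosen_p.append(p)
    return chosen_u, chosen_p


def generate_cohort(spec: PhantomSpec) -> Cohort:
    """Generate a ground-truthed cohort of planned + implanted electrodes.

    Deterministic for a fixed seed.  Planned entry points are sampled on
    the scalp ellipsoid with minimum pairwise spacing
    ``4 * max(entry_shift_mm, 2)`` so that automatic pairing is well posed;
    planned targets lie in the head interior along a jittered inward
    normal.  The implanted electrode is derived from the plan by the
    deviation chain documented in the module docstring, the pivot is placed
    on the outer-skull surface and the bolt head one bolt length proximal.
    """
    rng = np.random.default_rng(spec.seed)
    axes = np.asarray(spec.scalp_semi_axes, dtype=float)
    outer_axes = axes - spec.skull_offset_mm
    surfaces = build_surfaces(spec)

    min_spacing = 4.0 * max(spec.entry_shift_mm, 2.0)
    span = spec.contact_spacing_mm * (spec.contacts_per_electrode - 1)

    # all cases share one head geometry, so spacing is enforced cohort-wide:
    # pooled plan/implant pairing then stays unambiguous by construction
    all_us, all_eps = _sample_entry_dirs(
        rng, spec.n_cases * spec.electrodes_per_case, axes, min_spacing
    )

    plans, implants, rows = [], [], []
    for case in range(spec.n_cases):
        case_id = f"case{case:02d}"
        sl = slice(case * spec.electrodes_per_case, (case + 1) * spec.electrodes_per_case)
        us, eps = all_us[sl], all_eps[sl]
        for k, (u, ep) in enumerate(zip(us, eps)):
            eid = f"{case_id}_E{k:02d}"
            group = "temporal" if _temporal_weight(u)[0] > 0.5 else "non-temporal"

            # planned trajectory: jittered inward normal, interior target
            normal = unit(ep / axes**2)
            for _ in range(200):
                jitter = 0.12 * rng.normal(size=3)
                d_plan = unit(-(normal + jitter - np.dot(jitter, normal) * normal))
                length = float(rng.uniform(span + 6.0, span + 20.0))
                tp = ep + length * d_plan
                inner_axes = outer_axes - spec.skull_thickness_mm
                if float(np.sum((tp / (0.94 * inner_axes)) ** 2)) < 1.0:
                    break
            else:
                raise ValueError("could not place an interior target point")

            scale = float(rng.uniform(0.25, 1.75)) if spec.randomize_magnitudes else 1.0
            shift_mag = spec.entry_shift_mm * scale
            tilt = spec.tilt_deg * scale
            depth = spec.depth_error_mm * scale

            # 1) entry shift perpendicular to the planned direction
            e_imp = ep + shift_mag * _perp_unit(d_plan, rng)
            # 2) tilt about the shifted entry point
            d_imp = _rotate(d_plan, _perp_unit(d_plan, rng), tilt) if tilt > 0 else d_plan
            d_imp = unit(d_imp)
            # 3) depth error along the tilted axis
            tp_imp = e_imp + (length + depth) * d_imp

            line_imp = Line3(e_imp, d_imp)
            t_hits = _line_ellipsoid_hits(e_imp, d_imp, outer_axes)
            if t_hits.size == 0:
                raise ValueError(f"{eid}: implanted trajectory misses the outer skull")
            t_pivot = float(t_hits[np.argmin(np.abs(t_hits))])
            pivot = line_imp.point_at(t_pivot)
            bolt_head = pivot - spec.bolt_length_mm * d_imp

            # contacts, deepest first, with optional bend + noise
            idx = np.arange(spec.contacts_per_electrode)
            contacts = tp_imp[None, :] - np.outer(idx * spec.contact_spacing_mm, d_imp)
            if spec.bend_deg_per_10mm > 0:
                curvature = np.radians(spec.bend_deg_per_10mm) / 10.0  # rad per mm
                b_dir = _perp_unit(d_imp, rng)
                s_past = (contacts - pivot) @ d_imp
                s_past = np.clip(s_past, 0.0, None)
                contacts = contacts + 0.5 * curvature * (s_past**2)[:, None] * b_dir[None, :]
                tp_true = contacts[0].copy()
            else:
                tp_true = tp_imp
            if spec.contact_noise_mm > 0:
                contacts = contacts + rng.normal(scale=spec.contact_noise_mm, size=contacts.shape)

            plan_line = Line3.through(ep, tp)
            plans.append(PlannedTrajectory(eid, ep, tp, group_label=group))
            implants.append(ImplantedElectrode(eid, bolt_head, pivot, contacts))
            rows.append(
                {
                    "electrode_id": eid,
                    "case_id": case_id,
                    "group_label": group,
                    "true_angle_deg": tilt,
                    "true_entry_offset_mm": shift_mag,
                    "true_target_offset_mm": lateral_shift(tp_true, plan_line),
                    "true_depth_mm": axial_coordinate(tp_true, plan_line) - length,
                    "bent": spec.bend_deg_per_10mm > 0,
                    "plan_ep_x": ep[0], "plan_ep_y": ep[1], "plan_ep_z": ep[2],
                    "plan_tp_x": tp[0], "plan_tp_y": tp[1], "plan_tp_z": tp[2],
                    "impl_ep_x": e_imp[0], "impl_ep_y": e_imp[1], "impl_ep_z": e_imp[2],
                    "impl_dir_x": d_imp[0], "impl_dir_y": d_imp[1], "impl_dir_z": d_imp[2],
                    "impl_tp_x": tp_true[0], "impl_tp_y": tp_true[1], "impl_tp_z": tp_true[2],
                }
            )

    gt = GroundTruth(frame=pd.DataFrame(rows), seed=spec.seed)
    return Cohort(plans=plans, implants=implants, surfaces=surfaces, ground_truth=gt, spec=spec)


def true_metrics(cohort: Cohort) -> list[AccuracyRecord]:
    """Analytic accuracy records from the generative truth (no meshes, no
    line fitting) — the recovery oracle for the measurement pipeline.

    Entry points are intersections with the analytic scalp ellipsoid, so
    the oracle is independent of both the triangle meshes and the
    trajectory estimators.
    """
    axes = np.asarray(cohort.spec.scalp_semi_axes, dtype=float)
    out = []
    for _, r in cohort.ground_truth.frame.iterrows():
        ep = np.array([r["plan_ep_x"], r["plan_ep_y"], r["plan_ep_z"]])
        tp = np.array([r["plan_tp_x"], r["plan_tp_y"], r["plan_tp_z"]])
        e_imp = np.array([r["impl_ep_x"], r["impl_ep_y"], r["impl_ep_z"]])
        d_imp = np.array([r["impl_dir_x"], r["impl_dir_y"], r["impl_dir_z"]])
        tp_imp = np.array([r["impl_tp_x"], r["impl_tp_y"], r["impl_tp_z"]])
        plan_line = Line3.through(ep, tp)

        t_hits = _line_ellipsoid_hits(e_imp, d_imp, axes)
        if t_hits.size == 0:
            raise ValueError(f"{r['electrode_id']}: implanted line misses the scalp")
        t_entry = float(t_hits[np.argmin(np.abs(t_hits))])
        ep_imp = e_imp + t_entry * d_imp

        lt = lateral_shift(tp_imp, plan_line)
        depth = axial_coordinate(tp_imp, plan_line) - axial_coordinate(tp, plan_line)
        out.append(
            AccuracyRecord(
                electrode_id=str(r["electrode_id"]),
                method="truth",
                surface_kind="scalp",
                source_tag="analytic",
                LE=lateral_shift(ep_imp, plan_line),
                EE=float(np.linalg.norm(ep_imp - ep)),
                LT=lt,
                ET=float(np.linalg.norm(tp_imp - tp)),
                depth_error=depth,
                angle=float(r["true_angle_deg"]),
                length=float(np.linalg.norm(tp_imp - ep_imp)),
                max_contact_displacement=0.0,
                skull_thickness=None,
                group_label=str(r["group_label"]),
            )
        )
    return out


# --- CT rasterization -------------------------------------------------------

def rasterize_ct(cohort: Cohort, voxel_mm: float = 0.75, margin_mm: float = 35.0,
                 hardware: bool = True):
    """Rasterize a cohort into a synthetic CT volume with documented bands.

    Background 0; head interior (soft tissue), skull shell (outer to inner
    skull, with the temporal thin patch), bolt cylinders (radius 2 mm) and
    contact spheres (radius 1 mm) are painted with the
    :data:`INTENSITY_BANDS` values, later bands overwriting earlier ones.
    ``hardware=False`` emulates a pre-implantation navigation CT (no bolts
    or contacts), the image scalp meshes are generated from.  The affine
    maps voxel centers to world mm.
    """
    from seegqa.imageops import Volume

    spec = cohort.spec
    axes = np.asarray(spec.scalp_semi_axes, dtype=float)
    lo = -(axes + margin_mm)
    hi = axes + margin_mm
    shape = np.ceil((hi - lo) / voxel_mm).astype(int)
    affine = np.eye(4)
    affine[:3, :3] *= voxel_mm
    affine[:3, 3] = lo + voxel_mm / 2.0

    for e in cohort.implants:
        pts = np.vstack([e.contacts, e.bolt_head[None, :], e.pivot[None, :]])
        if np.any(pts < lo + voxel_mm) or np.any(pts > hi - voxel_mm):
            raise ValueError(f"electrode {e.electrode_id} outside the field of view")

    ii = [np.arange(n, dtype=np.float32) * voxel_mm + (lo[d] + voxel_mm / 2.0) for d, n in enumerate(shape)]
    X, Y, Z = np.meshgrid(*ii, indexing="ij", copy=False)
    P = np.stack([X, Y, Z], axis=-1)
    rad = np.sqrt(X**2 + Y**2 + Z**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        U = P / np.maximum(rad, 1e-6)[..., None]
    r_scalp = 1.0 / np.sqrt(np.sum((U / axes) ** 2, axis=-1))
    r_outer = 1.0 / np.sqrt(np.sum((U / (axes - spec.skull_offset_mm)) ** 2, axis=-1))
    thick = _skull_thickness_at(U.reshape(-1, 3), spec).reshape(shape).astype(np.float32)
    r_inner = r_outer - thick

    data = np.zeros(tuple(shape), dtype=np.float32)
    data[rad <= r_scalp] = INTENSITY_BANDS["tissue"]
    data[(rad <= r_outer) & (rad > r_inner)] = INTENSITY_BANDS["skull"]

    inv_vox = 1.0 / voxel_mm

    def paint_ball(center, radius, value):
        c_idx = (center - (lo + voxel_mm / 2.0)) * inv_vox
        r_idx = int(np.ceil(radius * inv_vox)) + 1
        sl = tuple(
            slice(max(0, int(np.floor(c_idx[d])) - r_idx), min(shape[d], int(np.ceil(c_idx[d])) + r_idx + 1))
            for d in range(3)
        )
        gi = np.meshgrid(*[np.arange(s.start, s.stop) for s in sl], indexing="ij")
        w = np.stack(gi, axis=-1) * voxel_mm + (lo + voxel_mm / 2.0)
        inside = np.sum((w - center) ** 2, axis=-1) <= radius**2
        data[sl][inside] = value

    def paint_cylinder(p0, p1, radius, value):
        axis = p1 - p0
        L = np.linalg.norm(axis)
        axis = axis / L
        bmin = np.minimum(p0, p1) - radius
        bmax = np.maximum(p0, p1) + radius
        i0 = np.maximum(((bmin - (lo + voxel_mm / 2.0)) * inv_vox).astype(int), 0)
        i1 = np.minimum(((bmax - (lo + voxel_mm / 2.0)) * inv_vox).astype(int) + 2, shape)
        sl = tuple(slice(int(i0[d]), int(i1[d])) for d in range(3))
        gi = np.meshgrid(*[np.arange(s.start, s.stop) for s in sl], indexing="ij")
        w = np.stack(gi, axis=-1) * voxel_mm + (lo + voxel_mm / 2.0)
        rel = w - p0
        t = rel @ axis
        perp = rel - t[..., None] * axis
        inside = (t >= 0) & (t <= L) & (np.sum(perp**2, axis=-1) <= radius**2)
        data[sl][inside] = value

    if hardware:
        for e in cohort.implants:
            paint_cylinder(e.bolt_head, e.pivot, 2.0, INTENSITY_BANDS["bolt"])
        for e in cohort.implants:
            for c in e.contacts:
                paint_ball(c, 1.0, INTENSITY_BANDS["contact"])

    return Volume(data=data, affine=affine)
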