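# Methods

## Deviation metrics

All computation happens in one common world space in millimetres; the
package never resamples or re-orients images, and assumes planned data,
segmented landmarks and meshes are already co-registered.

A planned trajectory is the oriented line through the planned entry point
(EP) and target point (TP); an implanted trajectory is a straight-line
estimate of the electrode's course. All trajectories are oriented
proximal→distal (entry→target), and angles are computed on these oriented
directions without folding to [0°, 90°]: a near-180° angle between a plan
and an implant would indicate an orientation bug upstream, not a valid
measurement, and should surface as an outlier rather than be silently
folded away.

Given the implanted entry point `EP_i` (trajectory ∩ surface mesh) and the
implanted target `TP_i` (most distal contact centroid):

| metric | definition | units |
|---|---|---|
| LE, LT | shortest distance from `EP_i` / `TP_i` to the planned line | mm |
| EE, ET | `‖EP_p* − EP_i‖`, `‖TP_p − TP_i‖` | mm |
| depth | axial coordinate of `TP_i` minus that of `TP_p` on the planned line | mm, signed |
| angle | angle between planned and implanted directions | degrees |

`EP_p*` is the planned entry re-projected onto the same surface mesh, so EE
and LE are measured between like-for-like points. Because `TP_p` lies on
the planned line, `ET² = LT² + depth²` holds exactly: Euclidean target
error decomposes into the lateral component and the insertion-depth
component that lateral shift cannot see. This is why records always carry
the signed depth error (positive = implanted deeper than planned — a
convention this package fixes; the sign itself is a free choice).

## Trajectory estimators

* **A1 (bolt axis)**: line through the pivot in the direction
  bolt-head→pivot. Robust to electrode bending but blind to it; its
  `max_contact_displacement` (largest lateral shift of any contact from the
  line) quantifies how much the physical electrode departs from the rigid
  axis.
* **A2/A3**: total-least-squares fit of the 2/3 most proximal contacts.
  Included as comparison baselines; with only 2–3 points, contact
  localization noise propagates strongly into the direction.
* **A4**: TLS fit of the contact window starting at the anchor — the most
  superficial contact fully outside the bolt — plus every deeper contact
  within 20 mm (Euclidean, inclusive) of it. "Fully outside the bolt" is
  operationalized as an axial offset past the pivot greater than
  `outside_margin` (default 1.2 mm, roughly half a contact length); the
  margin is configurable because bolt geometry varies between vendors.

Line fitting is orthogonal (total) least squares — the line through the
centroid along the principal axis of the centered contact cloud — because
perpendicular residuals are the geometrically meaningful ones for a
trajectory; ordinary regression residuals would depend on an arbitrary
axis choice. Degenerate inputs fail loudly: fewer than 2 points or
coincident points raise "degenerate fit", and a cloud whose two leading
singular values agree to better than 1e-9 relative raises "ambiguous
direction" rather than returning an arbitrary axis.

Entry points come from exact Möller–Trumbore line/triangle intersection
over every mesh face (barycentric tolerance 1e-9, duplicate hits within
1e-6 mm merged), keeping the intersection nearest a reference point (bolt
head, or planned EP for plans) to disambiguate multi-sheet surfaces such
as ears or the contralateral scalp. Skull thickness is measured along the
implanted trajectory between the outer- and inner-skull intersections —
the bone span the drill actually traverses — rather than along the surface
normal. Electrode length is entry-point-to-deepest-contact distance.

## Pairing

Plans and implants are paired greedily over all candidate pairs sorted by
the lexicographic key (entry distance quantized to 0.5 mm, angle): the
paired criteria "closest entry distance, then lowest angle" are encoded
literally, with the quantization tolerance deciding when distances count
as tied and the angle takes over. Candidates further than 15 mm apart at
the entry are never matched. A global assignment optimizer was
deliberately not used: greedy matching on the ordered two-part key is
deterministic, order-independent (ties broken by electrode id), and
transparent to audit. When a surface mesh is supplied, both entries are
re-projected onto it; otherwise the bolt head stands in for the implanted
entry (note it sits one bolt length above the scalp, so the 15 mm gate
should be widened in that mode).

## Agreement statistics

Bland-Altman analysis of paired measurements reports the bias μ = mean of
differences, SD σ (n−1), limits of agreement μ ± 1.96σ, a t-based CI for
the bias (se = σ/√n) and the classical large-sample approximation for each
limit's CI (se = σ·√(3/n)). Wilcoxon signed-rank (zeros discarded, W = the
smaller signed rank sum, exact p by enumeration up to effective n = 15,
tie/continuity-corrected normal approximation beyond) and Mann-Whitney U
(exact up to combined n = 12 without ties) cover paired and group
comparisons; all p-values are two-sided and no multiplicity correction is
applied — the CLI tables record how many tests each file contains so users
can correct downstream. Box-Cox transforms use profile-ML λ on [−5, 5]
with an automatic positivity shift of −min + 1e-6 recorded in the fit;
D'Agostino-Pearson K² tests normality (n ≥ 8 required, warning below 20).

## The phantom

The synthetic cohort generator is the package's entire test substrate and
defines the conditions under which every validation claim holds. The head
is a triaxial ellipsoid (scalp semi-axes 95/80/70 mm), with an outer skull
offset 5 mm inward and an inner skull a further 7 mm in, thinned to 45 %
over a smooth lateral "temporal" sector (electrodes entering there carry
`group_label="temporal"`, so stratified summaries are exercisable).
Surfaces are icosphere meshes (subdivision 4, chord error ≈ 0.05 mm at
these radii) deformed to the ellipsoids.

Planned entries are sampled on the scalp with cohort-wide minimum spacing
`4·max(σ_entry, 2 mm)` — cohort-wide rather than per case because all
synthetic cases share one head geometry and pooled pairing must stay well
posed. Planned directions are jittered inward normals; planned lengths are
uniform on [span+6, span+20] mm where span is the contact array length
(default 10 contacts at 5 mm), so the whole array fits inside the head.

Implanted electrodes apply, in order: an entry shift of the given
magnitude **perpendicular to the planned direction** (for these
near-radial trajectories this is nearly tangent to the scalp; the
perpendicular convention is chosen so the injected lateral target offset
is exactly the nominal value and hence exactly recoverable), a tilt of the
given angle about the shifted entry around a random perpendicular axis, a
signed depth offset along the tilted axis, optional circular-arc-style
quadratic bending beyond the pivot, and finally iid Gaussian noise on each
contact coordinate. The pivot is the implanted line's entry into the outer
skull; the bolt head sits one bolt length (25 mm) proximal. Deviation
magnitudes are exact per electrode by default; `randomize_magnitudes`
draws each electrode's magnitude from U[0.25, 1.75] × nominal so that
recovery regressions (estimate vs. truth) have spread on the x-axis.

`true_metrics` computes the oracle records analytically from the
generative parameters — entry points via closed-form line/ellipsoid
intersection, no meshes, no fitting — so pipeline-vs-truth comparisons
never share code with the pipeline.

The rasterized CT paints documented intensity bands (tissue 100 filling
the head interior, skull 400, bolts 900, contacts 1600 on background 0) at
0.75 mm default voxels; `hardware=False` emulates a pre-implantation
navigation CT, the image scalp surfaces are extracted from (with bolts
painted, the scalp level set is bridged through the bolt holes to interior
sheets and is no longer a clean ellipsoid — as in real post-implantation
CT). Contact centroids are intensity-weighted over 26-connected
supra-threshold components (weighting reduces quantization bias;
`min_voxels=2` suppresses single-voxel noise).

What the phantom does **not** emulate: realistic CT noise, beam-hardening
or metal artefacts, brain shift / CSF-loss electrode bending mechanics,
non-ellipsoidal anatomy, or segmentation failures. Passing the recovery
suite therefore demonstrates that the *measurement* pipeline is unbiased
and sub-voxel accurate given correct segmentations in a common space — not
that segmentation or registration of clinical images would be.

## Problem sizes and numerical choices

Validation uses cohorts of 100–150 electrodes (10–15 cases × 10) for
identity and recovery experiments, 50 seeded repetitions for pairing and
robustness properties, and 1000 seeded instances per geometric primitive
against brute-force oracles (dense line sampling at 50 µm steps; unit-
sphere grid search with shrinking local refinement; analytic sphere
intersections with the icosphere chord-error bound of 0.2 mm as the
tolerance). Rank-test p-values are verified against full enumeration for
every configuration up to n = 8. These sizes make the whole validation
run in a few minutes on a single CPU while keeping every statistical
property comfortably identifiable.

Known limitations: trajectories are modelled as straight lines (A1–A4);
curved electrode models are out of scope, and bending appears only through
`max_contact_displacement` and estimator disagreement. Anatomical region
labels are caller-supplied strings; no parcellation is performed. Linear
mixed-effects modelling of cohort effects is intentionally left to
external tools via the exported per-electrode CSV.
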