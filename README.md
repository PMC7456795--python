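# seegqa — automated accuracy assessment of SEEG electrode implantation

Stereo-electroencephalography (SEEG) implants multiple depth electrodes
through skull-mounted guide bolts to localize the epileptogenic zone in
drug-resistant epilepsy. After surgery, clinicians need to know how far each
implanted electrode ended up from its planned trajectory. Doing this by
visual inspection is slow and biased; `seegqa` computes the standard
deviation metrics automatically from segmented landmarks and head-surface
meshes, for neurosurgical and imaging researchers who have planned and
post-implantation data in a common world space (millimetres).

## The measurement model

Each implanted electrode is reduced to a straight **implanted trajectory**
using one of four estimators:

* **A1** — the bolt axis, the line from the bolt head through the pivot
  point (the bolt's distal end at the skull);
* **A2 / A3** — a total-least-squares line of best fit through the 2 or 3
  most proximal contact centroids;
* **A4** — a line of best fit through the most superficial contact fully
  outside the bolt and every contact within 20 mm of it.

With the planned trajectory `P` (entry point `EP_p` → target point `TP_p`)
and the implanted trajectory intersected with a scalp (or skull) mesh at
`EP_i`, and the most distal contact as the implanted target `TP_i`, the
per-electrode metrics are

* lateral shifts `LE = d(EP_i, P)` and `LT = d(TP_i, P)` — shortest 3D
  point-to-line distances;
* Euclidean errors `EE = |EP_p − EP_i|` and `ET = |TP_p − TP_i|`;
* signed depth error — the along-axis component of the target
  displacement (positive = implanted deeper than planned), so that
  `ET² = LT² + depth²`;
* the angle between the planned and implanted directions, plus descriptors
  (implanted length, skull thickness along the trajectory, maximum contact
  displacement from the fitted line).

Planned and implanted electrodes are paired automatically by (1) closest
entry-point distance, then (2) lowest trajectory angle. Method agreement
between estimators or entry surfaces is assessed with Bland-Altman analysis
(bias and ±1.96σ limits of agreement with confidence intervals), Wilcoxon
signed-rank, Mann-Whitney U and Pearson correlation/OLS regression.

No clinical data ship with the package: a built-in phantom generator
produces ground-truthed synthetic cohorts (ellipsoidal head, skull shells
with a thin temporal patch, controllable entry shift / tilt / depth error /
bending / contact noise) and optional rasterized CT volumes, which the
entire validation rests on.

## Worked example

```sh
seegqa phantom --out ph --seed 3 --n-cases 2 --electrodes-per-case 4 \
    --tilt 1.0 --entry-shift 1.0
seegqa compute --plans ph/plans.csv --electrodes ph/electrodes.csv \
    --scalp ph/scalp.stl --outer-skull ph/outer_skull.stl \
    --inner-skull ph/inner_skull.stl --methods A1,A4 --out run
```

`run/records.csv` then holds one row per electrode × estimator (columns
abridged):

```
electrode_id method       LE       LT       ET  depth_error  angle
  case00_E03     A1 1.001740 0.792626 0.792669    -0.008224    1.0
  case00_E03     A4 1.001740 0.792626 0.792669    -0.008224    1.0
  case01_E01     A1 1.000586 1.967757 1.967777    -0.008823    1.0
  case01_E01     A4 1.000586 1.967757 1.967777    -0.008823    1.0
```

Every electrode was generated with a 1 mm entry shift perpendicular to its
planned direction and an exact 1° tilt: the pipeline reads back the 1°
angle on every electrode and an entry lateral shift of 1.00 mm; target
lateral shifts vary per electrode because the tilt pivots at the entry, so
its effect at the target depends on trajectory length and on how the tilt
and shift directions combine. `run/summary.json` contains the per-case and
stratified (temporal / non-temporal) means and SDs — for this run the
overall row reads `LE_mean = 1.0, angle_mean = 1.0, length_mean = 59.1` —
and `run/method_agreement.csv` the pairwise A1-vs-A4 Bland-Altman and
Wilcoxon results.

The same API is available from Python:

```python
from seegqa import PhantomSpec, generate_cohort, pair_electrodes, compute_accuracy

cohort = generate_cohort(PhantomSpec(seed=1, tilt_deg=2.0))
pairs, _, _ = pair_electrodes(cohort.plans, cohort.implants,
                              surface=cohort.surfaces["scalp"])
record = compute_accuracy(pairs[0], "A4", cohort.surfaces["scalp"])
print(round(record.angle, 3))   # 2.0 — the injected tilt, recovered
```

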