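# Methods

## Data model

A **map** is one horizontal cortical section: an optional contour polyline,
four anatomical reference points p_j (j = posterior, dorsal, anterior,
ventral) placed per brain-atlas convention, and one record per labeled
neuron (id, cortical layer among II/III/IV/Va/Vb/VI, map-plane soma
position, SWC path). Maps are JSON; morphologies are standard 7-column SWC.
Only basal dendrites (SWC type 3) enter the analysis; the soma center is the
root type-1 node (centroid if the soma is traced with several type-1 nodes).
SWC coordinates are treated as soma-relative whenever a map-frame soma
position is given, because reconstruction software rarely shares the
section's coordinate frame.

Dendritic mass is discretized into sample points spaced exactly `step`
(default 0.5 µm) apart in arc length along each unbranched section, so
"total length in a sector" reduces to a point count. Arc length is measured
along the 3-D polyline and the samples are then projected onto the map
plane by dropping the sectioning axis; sections are thick (150–200 µm)
relative to the nearly planar basal arbors, and all angles are planar, so
this is the faithful default. A `planar_arclength` switch measures arc
length after projection instead, for sensitivity analysis. Branch tips with
residual length < step contribute no point (floor rule), which keeps
inter-point spacing exact; a relative guard of 1e-6 on the floor absorbs
float noise when a branch length falls exactly on a multiple of the step
(common for synthetic arbors grown in unit steps).

## Sector geometry

All angles live in (−π, π], counterclockwise positive, measured from the
posterior ray (the global reference direction, angle 0 by construction).
The signed angle from vector a to vector v is atan2(a×v, a·v), which is
quadrant-unambiguous.

The four rays soma→p_j are direction axes. In the default `bisector` mode
the circle is split at the angular bisectors between circularly adjacent
rays, so each direction's sector is the arc closest to its own ray; this
contains the ray itself and degrades gracefully when the rays are unevenly
spaced (an off-center soma). The literal alternative (`rays` mode:
boundaries at the rays, each sector spanning from its ray counterclockwise
to the next) is kept as a config option for sensitivity analysis. Sector
arcs are half-open: a point exactly on a boundary belongs to the
counterclockwise-adjacent sector, making boundary ties deterministic.
Note a geometric consequence of the bisector construction: moving the soma
*toward* one reference point rotates the two flanking rays away from it, so
that direction's sector widens rather than shrinks (for refs at unit
N/E/S/W and the soma halfway toward the anterior point, PS_anterior =
(π − arctan 2)/2π ≈ 0.324 and PS_posterior = arctan(2)/2π ≈ 0.176; the
sector-geometry tests freeze these hand-derived values).

Degenerate geometry (a reference point on the soma, coincident rays) raises
a `GeometryError`; sample points coincident with the soma have no direction
and are skipped with a warning.

## Circular statistics

* **Fisher circular median**: the *data* angle minimizing the summed
  circular distance d(a, b) = π − |π − (|a − b| mod 2π)| to all angles.
  Evaluated exactly (every data angle is a candidate), vectorized in
  512-candidate chunks so memory stays O(chunk·n). Ties — which arise for
  symmetric configurations — are broken by the candidate closest to the
  mean direction, then by the smallest angle; with the mean undefined, the
  smallest tied angle wins.
* **Mean direction**: atan2(S, C) of the resultant vector (Σ cos θ, Σ sin θ).
  When the mean resultant length R/n falls below 1e-9 the mean is undefined
  (balanced angle sets) and `UndefinedMeanError` is raised; the summary
  object then carries `mean = None`.
* **Circular quartiles** (n ≥ 4): rotate all angles so the median sits at 0,
  take linear percentiles on (−π, π], rotate back. The interpolation rule is
  configurable; the default is the (n+1)p rule (numpy `method="weibull"`,
  R type 6). Quartiles bracket the median along the circle by construction.

## Fisher-median orientation method

Per neuron, the called sector is the sector containing the median of all
sample-point angles. If the median lies exactly on a sector boundary
(within 1e-12 rad) the mean direction decides and `fallback_used` is set;
if the mean is also unusable the call is "unclear" (sector None, logged)
and excluded from map counts. Map-level tendency from per-direction counts
(fractions f_j), evaluated in precedence order:

1. some f_j > 0.8 → **oriented j**
2. a contiguous pair (A-V, A-D, D-P, P-V) with f_j1 + f_j2 = 100%, larger
   member ≥ 50%, smaller ≥ 30% → **oriented j1-j2**
3. same gate but pair sum > 80% → **partly j1-j2**
4. some f_j > 0.6 → **partly j**
5. otherwise **undetermined**

Comparisons are strict for the ">" rules and inclusive for the "at least"
50/30 gate. Full labels outrank partial ones, and pair labels outrank
single ones at equal strength — the unique ordering consistent with the
packaged 44-map audit table. At most one contiguous pair can pass the gate
(two pairs passing would require total mass > 1), so no pair tie-break is
ever exercised. The packaged audit table (`dendrorient/data/table1_counts.csv`,
44 maps, 288 neurons) reproduces 43/44 published labels with exactly seven
full "oriented" maps; the one mismatch (map 6III, counts P2 D1 A0 V3) meets
the stated partly-pair rule for P-V yet was published as Undetermined, and
is reported as a discrepancy rather than special-cased.

## DLRM

TL_j = fraction of sample points in sector j; PS_j = arc fraction of sector
j; ratio_j = TL_j / PS_j. Because Σ_j PS_j·ratio_j = Σ_j TL_j = 1
identically (asserted on every call), at most three ratios can exceed any
threshold t > 1 — the 0-to-3 preferred-direction bound is a theorem here,
not an assumption. Preferred = {j : ratio_j > t}; weak = {j : 1 < ratio_j
< t}; both rules strict, so ratio = t is not preferred and ratio = 1 is not
weak. Preferred sets are nested across thresholds by construction
(monotonicity is still tested end to end). Types: 0 → undetermined, 1 →
single, 2 → contiguous ({A,V}, {A,D}, {D,P}, {P,V}) or opposite ({A,P},
{D,V}), 3 → triple. All four possible triples are reported as explicit
classes. Group summaries are frequency tables per map/layer and threshold;
no single group label is derived from DLRM calls (that is the Fisher
method's job).

## Plots

OCH: one dot per 0.5 µm sample point, stacked per unit-degree bin, colored
by sector (orange dorsal, dark green ventral, blue posterior, purple
anterior — fixed mapping). Red arrow = median, blue arrow = mean, light
green arc with end dots = interquartile range, and each sector with
ratio > 1 is shaded over its full arc, darker for each threshold passed
(1.1 < 1.2 < 1.3). ECH: the same dots distributed over concentric rings of
25 µm planar distance bands (ring = floor(distance/25), half-open), with
the central statistics drawn from first-ring points only; a flag switches
to 3-D distance. Dot-stack geometry (radial increment per stacked dot) is
cosmetic and configurable. Every render writes a sidecar CSV (per-degree —
and per-ring for ECH — counts per sector) whose totals always equal the
cloud size, so the figures are testable without pixel comparison. With the
floor-rule sampling (points at k·step, k ≥ 1, soma not emitted) a straight
80 µm radial branch at step 0.5 yields ring counts 49/50/50/11.

## Synthetic generator

Emulates the study geometry: maps of 6 ± 2 neurons (clipped ≥ 1), reference
points ~2000 µm from the section center (optionally jittered), somata
inside a 600 µm contour. Arbors are grown, not traced: 3–8 primary branches
per neuron, lengths ~N(100, 25) µm clipped at 20 µm, each a random walk in
1 µm steps with wrapped-normal heading jitter (sd 0.06 rad/step, giving
path/chord tortuosity around 1.1, typical of basal dendrites), 0–2
daughter branches per primary sprouting at random vertices. Initial branch
bearings come from a von Mises mixture — the orientation dial: κ = 0 is
uniform (unoriented), larger κ concentrates growth toward the component
mean, which may be given as an absolute bearing or a direction name.
Every neuron's generating mixture and intended orientation label are stored
as ground truth. Generation is fully deterministic given the seed
(byte-identical SWC/JSON output).

What the generator does *not* emulate: realistic branch-order statistics,
diameter tapering, Sholl profiles, 3-D undulation out of the section plane,
or spatial interactions between neighboring neurons. Passing recovery tests
therefore show that the estimators recover *planted planar orientation
structure*, not that real P14 arbors satisfy any particular model.

## Recovery behavior and a known limitation

With concentrated bias (κ = 8, 40 × 100 µm branches) the DLRM recovers the
planted single orientation at t = 1.3 in ≥ 95% of replicates (the
acceptance script reports the measured rate). For *uniform* (κ = 0)
neurons, however, the undetermined rate at t = 1.3 is only a little above
one half, not near one. This is intrinsic to the ratio rule at finite arbor
size: the independent unit is the branch, so sd(TL_j) ≈ √(p(1−p)/n_b) ≈
0.067 at n_b = 40 and p = 1/4, and some sector exceeds TL = 0.325 (ratio
1.3) in roughly 40% of unoriented neurons — almost always producing a
spurious *single* call. Pushing this false-positive rate below ~10% would
require on the order of 125+ independent branches, beyond any realistic
basal arbor. Users should therefore read per-neuron DLRM calls on small
arbors as descriptive, and rely on group-level frequencies (or the
map-tendency rules) for inference.

## Defaults at a glance

| parameter | default | unit | rationale |
|---|---|---|---|
| sample spacing `step` | 0.5 | µm | finest practical length quantum; 360-bin angular resolution |
| thresholds | 1.1, 1.2, 1.3 | — | loose → strict preference regimes |
| boundary mode | bisector | — | each sector contains its own ray |
| arc length | 3-D, then project | — | thick sections, planar angles |
| ECH ring width | 25 | µm | distance bands around the soma |
| quartile rule | weibull ((n+1)p) | — | linear interpolation on the rotated line |
| mean-direction tolerance | 1e-9 | R/n | balanced sets have no mean |
| boundary tolerance (median fallback) | 1e-12 | rad | exact-boundary detection |
| generator: branches / neuron | 3–8 | — | basal primaries |
| generator: branch length | N(100, 25), ≥ 20 | µm | P14 basal scale |
| generator: heading jitter | 0.06 | rad/step | tortuosity ≈ 1.1 |
| generator: neurons / map | 6 ± 2 | — | section density emulated |

Validation problem sizes (1000-neuron conservation/monotonicity ensembles,
1000-instance oracle comparisons, 200-replicate recovery runs) were chosen
so the full suite and the acceptance script each complete in well under a
minute on a single CPU while keeping Monte-Carlo standard errors below a
few percent.
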