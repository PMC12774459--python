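# Methods

## Projection model

A B-scan is a cross-section along one scan line; only the detection's
extent along that line carries en face information. The linear map
`x_enface = x_bscan / W_bscan × W_enface` (768 → 496 px by default)
assumes the B-scan's lateral field of view coincides with the en face
frame — no registration beyond this rescaling is attempted.

Two choices are underdetermined by the acquisition geometry and are
fixed here as package conventions:

* **Band extent.** The device does not expose the physical thickness of
  a scan line's footprint. Each scan's projected rectangle spans the
  full inter-scan spacing, band *k* = `[floor(k·E/n), floor((k+1)·E/n))`
  with `E` the frame extent and `n` the scans per orientation, computed
  in integer arithmetic. The bands of one orientation therefore tile
  the frame exactly (no gaps, no overlaps), which makes the union area
  well defined and reproducible. Whether the device's scan lines are
  edge-aligned or centered in the frame is not documented; edge-aligned
  tiling is assumed.
* **Interval discretization.** The real-valued endpoints from the
  rescaling are discretized floor(start)/ceil(stop) into half-open
  pixel intervals, so a detection never loses sub-pixel extent
  (conservative coverage). All coordinates are 0-based, intervals
  half-open.

Detections below a confidence cutoff (default 0.25, configurable) are
dropped before projection; the detector's native output carries no
documented operating point, so the cutoff is explicit rather than
implied. Multiple boxes on one scan are all projected and unioned. The
EPI mask keeps a per-pixel count of contributing detections
(`coverage`) for provenance; all downstream quantities use only the
binary union.

**Numerical choice.** Before floor/ceil, values within 1e-6 of an
integer are snapped to it. The synthetic generator inverse-maps en face
columns to B-scan pixels (×768/496) and the projection maps them back
(×496/768); the pair of correctly-rounded float operations can land a
hair's breadth on either side of the exact integer, and the snap makes
the round trip exact. Real detector coordinates are nowhere near 1e-6
of a pixel boundary, so the snap is inert for measured data.

## Quantification

Pixel area is the square of the lateral sampling (20 μm/px → 400 μm²).
The coverage ratio divides by the full 496×496 frame, not a macular
subregion, and is **truncated**, not rounded, to two decimals: the
reference quantification table is reproduced exactly by truncation and
not by rounding (e.g. 35,352 px / 246,016 px = 14.3698% prints as
14.36). The untruncated value is carried in every JSON report.

## Thickness discretization

The 220–500 μm range is split into nine equal 280/9 ≈ 31.1 μm bands,
numbered thickest-first (class 1 = [500 − 280/9, 500]) because the
association weights must decrease with class index. Intervals are
lower-inclusive/upper-exclusive; 500 μm belongs to class 1 and 220 μm to
class 9, so an internal edge belongs to the class whose floor it is.
Pixels outside 220–500 μm (including clinically severe > 500 μm) are
left unassigned: the score is defined on that range only and no rule
for exceedances is established. Band edges come from `np.linspace(500,
220, 10)` so the endpoints are exact in floating point. Inputs are
numeric μm grids (CSV or TIFF); decoding vendor color-coded thickness
images is out of scope. NaN marks unmeasured pixels.

## Association score

`score = (1/9) Σ W_i · IoU(A_ERM, ∪_{j≤i} A_class_j)` with
`W_i = −0.01 i² − 0.07 i + 1.666`. The weights are used exactly as the
polynomial gives them. They are sometimes described as summing to 1,
but they actually sum to 8.994; renormalizing would change every
reported score, so the printed polynomial is kept and the attainable
ceiling is (1/9)·8.994 ≈ 0.99933, reached when the ERM mask coincides
with class 1 and classes 2–9 are empty. Runs log the ΣW_i actually
used. IoU of two empty sets is defined as 0 ("no association"), never
NaN; the ERM operand is the binary EPI (coverage counts are ignored —
the score treats `A_ERM` as an area). IoU is unweighted within a class;
thickness enters only through class membership.

## Observer agreement

Standard two-rater battery on 5-point Likert ratings: Pearson/Spearman
(scipy), quadratic-weighted Cohen's κ with weights `(i−j)²/(k−1)²`
(scikit-learn; defined as 1 when both raters use a single identical
category, where the generic formula is 0/0), ICC(2,1) as the two-way
random absolute-agreement single-measure coefficient with the standard
F-based 95% CI (pingouin's ICC(A,1); the CI is reported at two
decimals), and Bland–Altman with differences rater1 − rater2 (direction
stated in the output), sd with ddof=1 and LoA = mean ± 1.96·sd.

Acceptability: AAS is the mean rating; AR the percentage of ratings at
or above the accept threshold (default 4); NAS counts ratings ≥
threshold as acceptance and ≤ 2 as rejection — the Likert labels mark
1–2 as the disagree levels and 3 as neutral, which counts in neither
direction. Pooled AR is computed over all ratings (the ratings-weighted
mean of per-rater rates), which is the principled pooling for unequal
case counts and reproduces 85.0% from per-expert 83.3%/86.7% at n=30
each. Correlations and ICC on zero-variance inputs raise rather than
return silent NaN.

## Synthetic scenarios

The generator emulates the three study inputs with known ground truth:

* **Detections** — an ERM region (rectangle or ellipse) is drawn in en
  face coordinates; for every scan band intersecting it, the bounding
  interval of the intersection is inverse-mapped to B-scan pixels. This
  is a *perfect* detector: for rectangles aligned to the band grid, the
  detection→EPI→area round trip is exact, which real data cannot
  provide. It does not emulate detector misses, spurious boxes, or
  confidence spread, so passing round-trip tests validates the
  projection arithmetic, not detector robustness.
* **Thickness maps** — a radial paraboloid bump
  `bg + (peak − bg)·max(0, 1 − d²)` plus optional Gaussian noise;
  smooth and unimodal, unlike real maps with foveal pits and
  segmentation artifacts.
* **Ratings** — per-case shared latent offset ~ N(0, case_sd), plus
  per-rater mean, bias-free Gaussian noise, rounded and clipped to
  {1..5}. High case_sd with small noise yields reliable panels
  (ICC > 0.9 on average); case_sd = 0 with large noise yields
  independent raters (κ ≈ 0 on average). Defaults (means 4.5, noise
  0.4, case_sd 0.8) mimic a 30-case two-expert panel rating mostly 4–5.

One `ScenarioSpec.seed` drives independent substreams for each output;
identical specs give bit-identical scenarios. The programmed-overlap
scenario holds a band-aligned 490 μm rectangle fixed and translates an
equal-size ERM rectangle so the overlapping fraction of its area equals
the target; the association score must be non-decreasing along the
sweep.

## Problem sizes in tests and the acceptance script

Brute-force oracles (per-pixel projection membership, set-based
association) run on small frames — ≤ 32×32 with ≤ 4 scans for
projection (200 random geometries), 16×16 for association (500 random
mask sets) — where exhaustive pixel loops are exact and fast;
full-geometry (496×496, 25+25 scans) paths are exercised by the
example-based and synthetic round-trip tests. Rating simulations use
30 cases × 2 raters over 100 seeds, matching the observer-study scale.

## Known limitations

* Only the linear rescaling registers B-scan and en face frames; eye
  motion between scans is not modeled.
* The association score is global; no per-sector (ETDRS) breakdown.
* Agreement metrics are two-rater; multi-rater generalizations of κ are
  not implemented (ICC and acceptability indices accept any number of
  raters).
* Thickness > 500 μm is excluded from the score even though it is
  clinically severe; users should inspect such regions separately.
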