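# Methods

This note documents the models behind `orgstack`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic data can and
cannot tell you about real microscopy.

## Scene model

A scene is a set of spheres in a rectangular gel volume: lateral extent
`xy_extent` (default 512 × 512 µm, one camera field at 1 µm/px), axial
depth `gel_depth` (default 1100 µm, a typical Matrigel dome), centers
uniform in the volume. Organoids are modeled as spheres with a live core
and, after treatment, an annular dead-cell shell; internal lumen/crypt
morphology and individual cells are not modeled. An optional `xy_margin`
keeps centers away from the lateral field edges so footprints are not
clipped; axial placement always spans the full depth, since that is the
dimension the scan design has to cope with.

Density bookkeeping uses 1 µL = 10⁹ µm³, so a 512² × 1100 µm field is
0.29 µL; plate-level densities of 2–20 objects/µL correspond to fractions
of an object per field, and simulated experiments therefore spread a
well's objects over many independent fields.

## Optical model

The microscope abstraction has five parameters:

| parameter | default | units | meaning |
| --- | --- | --- | --- |
| `pixel_size` | 1.0 | µm/px | lateral calibration |
| `blur_coeff` (k) | 0.05 | px/µm | Gaussian defocus sigma per µm of axial distance |
| `dof_half_depth` (h) | 80 | µm | detectability half-depth (see below) |
| `noise_sd` | 0.01 | — | additive Gaussian read noise (object contrast ≈ 1) |
| `background_base` (B₀) | 0.05 | — | gel autofluorescence floor, green channel |

Per layer, every object is drawn as its **projected silhouette** — the
equatorial, maximum cross-section — blurred with sigma `k·|Δz|`. The
silhouette (rather than the geometric plane/sphere cross-section) is used
at all offsets because a sphere at small defocus still images as its full
outline, and the maximum cross-section is exactly what EDF measurement is
after; slicing the sphere would make an object nearly tangent to a plane
vanish into a sub-resolution dot, which real defocused imaging does not do.

`dof_half_depth` is a hard detectability envelope: an object whose surface
is farther than `h` from every focal plane contributes nothing. It is the
single knob that ties rendering to the closed-form capture model
`min(1, 2(r+h)/step)`, and its default of 80 µm is fixed by the assay's
design anchor — a 7-layer scan of an 1100 µm gel (step 180 µm) must
capture essentially all 20 µm spheres, i.e. `2(10+80) = 180 ≥ step`. The
envelope is deliberately binary rather than a soft falloff so that the
analytic model, the geometric Monte Carlo and the rendered pipeline agree
to within binomial error; a soft shoulder would make "captured" depend on
segmentation thresholds right at the boundary.

Brightfield is rendered as object contrast on a dark background (an
inverted-contrast convention chosen so that one segmentation recipe serves
all channels); green carries labeled live cores plus gel background; red
carries dead objects and dead-cell shells.

## Staining and background kinetics

Labeling is Bernoulli per live object with probability
`p = min(1, c·t/K)`, `K = 120 µM·min`, which places saturation exactly at
the 2 µM × 60 min working point; labeled objects get green intensity
proportional to their live fraction. The dose×time form is a stand-in —
how dye actually penetrates 3-D structures over time is not modeled — but
it reproduces the qualitative behavior that matters for assay design:
labeling rises along both axes and saturates.

Green gel background grows linearly with staining time and is quenched
multiplicatively by Cu²⁺:
`B(t) = B₀ + β·t·max(0, 1 − [Cu²⁺]/0.1 mM)`, β = 0.003/min. With these
defaults the unquenched background roughly triples between 0 and 60 min
(0.05 → 0.23) — clearly visible against read noise by 30 min yet still
well below object contrast — and the 0.1 mM working concentration quenches
the time-dependent term completely. `staining_grid` shares one set of
uniform draws across all grid cells (common random numbers), so the
observed grid is monotone in dose and time for any sample size, not just
in expectation.

## Treatment model

`TreatmentEffect(kill_fraction, shrink_factor, dead_shell_width)` kills a
binomial share of objects outright (fully red, never labeled by the live
dye) and leaves survivors with a live core shrunk by `shrink_factor`
(default 0.7) surrounded by a red shell (default 10 µm). This reproduces
the two readout-relevant facts about treated wells: live-channel footprints
are strictly smaller than brightfield footprints (core ≤ core + shell), and
brightfield counting over-measures because dead material still scatters.
Defaults are a plausible mid-range; no published values constrain them.

## Scan planning

`plan_zstack` spaces `n` planes evenly from the gel bottom and rounds the
step `z_range/(n−1)` to the nearest 10 µm, the axial increment granularity
of a plate-scanner stage; this is what maps 1100/6 = 183.3 to the
conventional 180 µm step. Rounding means the top plane can miss or slightly
overshoot the nominal range (e.g. 4 layers × 370 µm = 1110 µm); the
renderer warns and carries on, and the geometric Monte Carlo exists
precisely to expose such edge effects, which the closed form ignores
(they are below one binomial standard error everywhere in the standard
design grid). Plane anchoring at the gel bottom is a convention; pass
`round_to=0` for exact spacing.

`capture_curve(mode="empirical")` is a geometric Monte Carlo — sample
axial positions, apply the detectability envelope against the actual plane
positions — and serves as the independent oracle for the closed form.
The full imaging path (`capture_efficiency_empirical`, `capture_study`)
renders, fuses and detects; it scores a ground-truth object as captured
when a detection centroid falls inside its footprint, which stays correct
when touching objects merge into one detection or one object splits
(the raw detected/true count ratio is available as `method="count"`).

## EDF fusion

Focus is measured as the local variance of the Laplacian in a
(2·4+1)² window — small enough to localize a 10 µm object, large enough to
estimate a variance stably. The per-pixel argmax over layers forms the
layer-index map; ties break to the lowest layer (a stack of identical
layers fuses to layer 0); pixels that are perfectly flat in every layer
(zero focus — the interior of a noise-free object) inherit the nearest
structured pixel's decision; the map is median-filtered with radius 2 px
to suppress salt-and-pepper layer switching. All channels are composited
from the single reference-channel map (brightfield by default), which
keeps channels co-registered by construction. No claim of equivalence to
any particular wavelet-based EDF implementation is made; the fitness
properties (composite sharpness dominates every single layer per object;
idempotence on uniform stacks) are what the tests enforce.

## Segmentation and measurement

Detection per channel: global Otsu threshold, floored at
`median + 6·1.4826·MAD` of the image so that blank or noise-only wells
yield no foreground (Otsu alone will happily split pure noise); hole
filling; distance-transform watershed seeded from 2 px h-maxima (labeled
with 8-connectivity so a diagonal plateau pair is one seed, not two
— unseeded diagonal plateaus were the one observed source of spurious
splits); components below `min_area` dropped. `min_area` defaults to
314 µm², the area of a 20 µm circle — the smallest size class treated as a
real object; capture studies lower it to a quarter of the smallest
simulated sphere's cross-section so the floor never interacts with the
quantity being measured.

The "short diameter" is the minimum Feret diameter, computed by rotating
calipers on the convex hull of the region's pixel centers plus one pixel
for the finite pixel extent. An object counts as labeled/live when its
mean green intensity exceeds `B₀ + 3·noise_sd` (default 0.08); the
labeling rate of an empty well raises an error rather than returning 0.

Overlap rate (ground-truth mode) is the percentage of objects whose
xy-projected disks intersect at least one other object's — computed with a
KD-tree but definitionally identical to the O(n²) pairwise check, which the
tests assert exactly. Background intensity mimics the nine-diffused-points
protocol: nine locations spread by greedy farthest-point selection outside
the dilated object mask, each averaged over a 5×5 px patch.

## Assay analytics

Survival rate is `100·n(dN)/n(d0)` and the size-change ratio is
`100·A(dN)/A(d0)` (the percent-change variant `100·(A(dN)−A(d0))/A(d0)` is
available behind a flag; the ratio is primary). Both are computed from
green-channel (live) segmentation, since dead shells inflate brightfield
areas. The chemosensitivity cutoff of 36.42 % is a configured constant
taken from clinical ROC analysis; it is not re-derived here (no outcome
data). A ratio **below** the cutoff is called sensitive — the treatment
suppressed growth — and the boundary itself is conservatively assigned to
resistant; both the direction and the cutoff are arguments.

Group comparison uses unadjusted pairwise two-tailed Student's *t* tests
of each treated arm against control, reported as mean ± SD (or SEM) with
star annotations at p < 0.05 (*), p < 0.001 (***) and p < 0.0001 (****).
No multiple-testing correction is applied — a deliberate mirror of common
plate-assay practice and a documented limitation.

### Parameter recovery

`survival_recovery_experiment` closes the loop: plant organoids (40–80 µm,
8 per 512² field), image at d0, kill a binomial fraction, re-stain, image
at dN, and compare. It reports the **recovered** survival (through the
full imaging path), the **realized** survivor fraction (ground truth of
the very objects imaged) and the **nominal** `100·(1−kill_fraction)`.
Separating the two error sources matters at typical well sizes: at 200
objects the binomial SD of realized-vs-nominal is ±3.5 pp at a 0.5 kill
fraction, whereas recovered-vs-realized isolates pure
detection/segmentation error, which these conditions hold to ~1–2 pp.

## Problem sizes and determinism

Simulated experiments use 512² px fields at 1 µm/px, 2000 spheres for
capture studies (80 fields of 25), 200 objects per condition for recovery,
and n = 2000 per cell for Monte-Carlo capture grids — sizes at which
binomial error bars are a few percent and a full study runs in tens of
seconds on one CPU. Every stochastic step takes an explicit seed;
identical seeds give bit-identical scenes, stacks and CSV outputs.
Sub-seeds are drawn from a single `numpy` generator per experiment.

## What passing tests do and do not show

The simulator is the toolkit's own test bed, not a physics model. Defocus
is an isotropic Gaussian with a hard axial envelope (no real PSF, no
spherical aberration or depth-dependent attenuation); staining kinetics
are a saturating stand-in; objects are opaque spheres; stage drift,
photobleaching, uneven illumination and debris are absent. Passing the
suite shows the *pipeline logic* is correct — planning arithmetic, fusion,
segmentation, bookkeeping from counts to calls — and that the assay-design
numbers (180 µm step, ≥95 % capture, 2 µM × 60 min saturation, Cu²⁺
quench, cutoff classification) follow from the stated models. It does not
certify performance on real micrographs, where thresholds, blur and
background behave less politely.
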