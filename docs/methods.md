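# Methods

## The measurement problem

A sessile droplet on a dehydrated biofilm under a centrifugal ramp is
described here by *apparent* 2-D wetting parameters: the true three-phase
contact line is hidden inside the porous biofilm, so all angles and lengths
are read off the visible silhouette.  Two silhouettes coexist on biofilms:
the dark bulky region holding most of the liquid, and the whole droplet
including the thin translucent tail that a pinned rear edge leaves behind.
Every quantity is therefore measured twice (suffix 1 = whole droplet,
suffix 2 = bulky region), against two independent baselines in the side
view — on real images the two baselines can differ by a few degrees owing
to reflection and parallax, so they are never assumed to coincide.

## Synthetic imaging model

The renderer is the package's source of ground truth; it is a *scripted*
image model, not a physical simulation (no hydrodynamics, no imbibition
PDE).

**Side profiles.** Symmetric droplets are circular-arc caps — exact for a
spherical cap, valid for contact angles above 90° — with
`R = L / (2 sin θ)` and height `R (1 − cos θ)`.  Asymmetric (tear-shaped)
droplets use the minimal-degree polynomial satisfying the five constraints
(two endpoint positions, two endpoint slopes `tan θ_r` and `−tan θ_f`
measured through the liquid, peak height): a quartic, clipped at zero.  Of
the up to two quartics matching the height, the one with the smallest
leading free coefficient (least oscillatory) is taken.  Asymmetric shapes
with an angle ≥ 90° would be multivalued in `z(x)` and are rejected.

**Photometry.** Body gray 10, tail gray 180, background 230 by default;
rendering is hard-edged (a noiseless frame contains exactly these three
tones) with additive seeded Gaussian noise, default σ = 2 gray levels.
The tail is drawn as a thin wedge at most ~2 px tall between the pinned
rear edge and the bulky rear edge.  The tail's real thickness and gray
distribution are unknown; this model is a stand-in.

**Top views** are two nested ellipses sharing their front vertex, rotated
by `alpha_A` (the in-plane deviation of the major axis from the travel
direction), with a seeded smooth radial perturbation applied to each
boundary: a periodic Gaussian random function synthesized from Fourier
modes with a Gaussian spectral decay set by the correlation length (default
0.3 mm along the boundary), normalized to an RMS amplitude of 1% of the
minor axis by default.  The whole ellipse's semi-major axis is chosen so
its x-projection equals the side-view contact length, which makes the two
camera views mutually consistent by construction.  Tail pixels are clipped
so that none lies forward of the bulky front.

**Ramp kinematics** are piecewise linear in rotation speed: angles constant
below the leaning onset (default 30 rpm); the front angle rises linearly to
the advancing value at the front depinning onset and clamps there; the rear
angle falls linearly to the receding value at the rear onset; depinned
edges advance at `spread_rate` (default 0.1 mm/rpm, matching a few mm of
elongation over a few tens of rpm); a `"never"` rear onset keeps the rear
edge pinned for the whole ramp.  Default onset values (front 54 rpm,
advancing 67°, receding 11°) describe a clean reference substrate.

**Calibration.** Default 5 µm/px, consistent with a 7×-magnified video
camera; frames carry an independent mm/px per view.

What the renderer does *not* emulate: partial-volume (gray-ramp) edges,
illumination gradients, reflections near the contact line, evaporation and
imbibition volume loss, satellite droplets.  Passing tests therefore show
correctness of the measurement chain on well-posed silhouettes, not
robustness to every optical artifact of real videos.

## Segmentation

Pixels at or below `t_bulky` form the bulky region, at or below `t_whole`
the whole droplet; each mask is reduced to its largest connected component
(one droplet per frame; specks are noise) with holes filled, and the bulky
mask is intersected with the whole mask so inclusion holds by construction.
Contours are sub-pixel iso-contours at `t + 0.5` (linear interpolation of
the threshold crossing between pixel centers).

Manual per-frame thresholds are the faithful mode.  The automatic mode is
an exact three-class Otsu: the pair maximizing the between-class variance
over all ~32k ordered pairs, computed by cumulative moments; ties break
toward the smallest pair.  Auto mode works well when the three populations
have comparable mass (top views) but can ignore the tail on side views,
where the tail is a few hundred pixels against half a megapixel of
background — this is why the pipeline defaults to manual thresholds
mid-gap between the rendered tones (95/205) for side-view analysis.

Edge stations along the major axis (positions 1–5) combine three cues: the
axis/ellipse intersections (1, 3), the threshold crossings of the intensity
profile (2, 4) and, for the front edge (5), the station where intensity
recovers to within 5 gray levels of the background mode, refined to the
strongest Sobel-gradient peak nearby with parabolic sub-sample
interpolation.  The 5-gray band reflects "recovers to the base value"
without a stated width.  Undefined positions are reported as `None` with a
reason, never silently dropped.

## Contact angles

The contact angle is the interior-measured angle between the baseline and
the tangent of the contour at the (extrapolated) baseline crossing.  The
tangent estimator is hybrid because no single local model covers 5°–110°
on pixelated contours:

* a rough slope probe (linear fit over 10% of the contact length) selects
  the branch;
* **shallow edges (< 42°):** the window is widened to cover ~12 staircase
  periods (`px / tan θ` each) — a discretized shallow edge carries its
  slope only across many columns — the points are boxcar-averaged over one
  period to cancel the quantization sawtooth, and a parametric quadratic in
  arc length is fitted; the tangent is evaluated at the height-zero root;
* **steep edges:** an algebraic circle fit (no curvature bias on cap-like
  arcs, single-valued beyond 90°) when it indicates ≥ 88°; otherwise a
  parametric quadratic evaluated at windows `w` and `w/2` with Richardson
  extrapolation, cancelling the `O(w²)` curvature bias on non-circular
  arcs.

Auto-estimated baselines pass through the two lowest contour extremes and
are lifted by half a pixel: the iso-contour's bottom run lies between the
last liquid row and the first background row.  Stations are absolute
projections onto the baseline direction, so edge positions are comparable
across frames even when the baseline is re-estimated per frame.

Accuracy on rendered ground truth at 5 µm/px: within ±1° noiseless across
caps 45°–110° and tears with fronts 40°–67° and rears 5°–30°; within ±3°
at noise σ = 2.  Known limitation: extreme asymmetry (rear ≤ 5° combined
with front ≥ 55°, or rear ≤ 20° with front ≥ 75°) biases the rear angle by
up to ~2.5°, because the quartic's curvature varies faster than the
widened shallow-window fit can follow.  Rear angles of 2-px tail wedges
are ill-conditioned and may come back NaN (flagged by a warning).

## Lengths, areas, volume

Top lengths `L_T1/L_T2` are x-projections of the *fitted ellipses*
(`2·sqrt(a² cos² φ + b² sin² φ)`), matching the convention of reporting
ellipse-based lengths; the jagged contour's own extent is available
separately.  The ellipse fit is the direct least-squares conic fit
(scikit-image's implementation), exact on noiseless conic samples.  Side
lengths are distances between sub-pixel baseline crossings; the height is
the maximum perpendicular distance from the whole-droplet baseline.

The volume estimator revolves the height profile about the vertical axis
through its area centroid and averages the two half-solids — exact for
axisymmetric profiles, an *estimate* otherwise, validated only on synthetic
solids of revolution (hemisphere and spherical caps to within 1%).
Profiles that are multivalued above the baseline (angles beyond 90°) raise
with a suggestion to use a cap fit.

## Ramp analysis

Series are smoothed by a centered running average (default 11 frames ≈ 1 s
at 10 fps; the window shrinks symmetrically at the edges, window 1 is the
identity).  A depinning onset is the first frame whose displacement from
the initial position (mean of the first `persistence` frames) exceeds
`epsilon` and stays exceeded for `persistence` consecutive frames; defaults
`epsilon` = 0.1 mm, `persistence` = 5 frames (0.5 s at 10 fps) sit above
pixel noise and below any motion visible at figure resolution.  With the
default spread rate this detects scripted onsets with a systematic lag of
1 rpm, within the ±2 rpm acceptance band even at 0.05 mm position noise.

Regimes: *static* until the front/rear angle difference grows more than 2°
beyond its initial value; *leaning* until the front edge depins;
*spreading* while the rear stays pinned; *sliding* after the whole-droplet
rear depins; *runoff* once the front edge passes the field-of-view limit
or is lost.  The advancing/receding angles are the smoothed angle series
sampled at the detected onset frames (no extrapolation).

Forces: `F = k·γ·w·(cos θ_rec − cos θ_adv)` with `k` configurable (default
1.0; prefactors 1, π/2 and 48/π³ all circulate in the literature and none
is canonical) and `F_c = ρ·V·α_c`.  A receding angle above the advancing
angle yields a negative force plus a warning, never a silent clamp.

## Coverage

Micrographs are mean-filtered (default 5 px; the filter type is a design
choice, the smoothing is "mild"), thresholded (dark = stained is the
crystal-violet convention; polarity is a flag; auto = exact two-class
Otsu), and summarized as per-image covered percentages with sample mean and
SD (n−1 denominator; a single image reports SD = NaN rather than 0).  The
synthetic coverage fixture thresholds a smooth random blob field at the
exact target quantile, so its true fraction is known to one pixel.

## Problem sizes and numerical choices

Validation grids use 50 seeded fixtures for the jagged-vs-ellipse and
cross-view checks, images of ~0.5–1.5 Mpx at 5 µm/px, and scripted ramps
of ~1000 frames; these sizes keep every grid comfortably reproducible on a
single CPU while leaving the measured discrepancies (≤ 0.3% area, ≤ 1.6%
length, ≤ 0.6% cross-view) far from their acceptance bounds (2%, 10%, 5%).
Ties in threshold selection break toward smaller thresholds; the
between-class-variance objective has exact plateaus across empty histogram
gaps, so oracle tests compare attained scores, not indices.  All random
draws (noise, jaggedness, blob fields, fixture parameters) flow from
explicit integer seeds; repeated runs are bit-identical.
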