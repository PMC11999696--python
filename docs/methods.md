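# Methods

This note documents the models and procedures pcmorph implements, the
parameter defaults and why they hold, what the synthetic cohorts do and do
not emulate, and the numerical choices made where the design was open.

## Coordinate and unit conventions

All coordinates and radii are micrometres. The default axis mapping treats
`x` as the parasagittal axis (anterior→posterior along the PC layer), `y` as
the radial axis (soma→pia), and `z` as mediolateral; it is configurable via
`io.AxisMap`. No shrinkage factor or z-correction is applied on read; an
explicit `Arbor.scaled()` hook exists for users whose tissue processing
requires one (default: identity).

## Arbor metrics

**Cable definition.** Total dendritic length sums every inter-node edge
whose *child* is a dendrite node. The stub from the soma into the first
dendrite node therefore belongs to the trunk; soma-internal and axonal
cable is excluded. This makes segment lengths an exact partition of the
total (asserted in tests to machine precision).

**Branch decomposition.** Maximal unbranched paths between branch
points/tips; order is centrifugal with every trunk at order 1. A segment's
mean diameter is the length-weighted mean of edge-midpoint diameters; edges
entering from a non-dendrite junction (the soma) take the child's caliber,
so soma girth never inflates trunk caliber.

**Eccentricity.** Each branch trace is translated to the origin; if its
mean radial displacement is negative it is mirrored over the horizontal
axis, likewise over the vertical axis for negative mean parasagittal
displacement. The slope is the through-origin fit b = Σxy/Σx², and the
eccentricity arctan(b), clamped to [0°, 90°] (Σx² = 0 → 90°). Choices made
here: mirroring tests the *mean* displacement because "projecting
downward/leftward" is otherwise ambiguous for wiggly traces and the mean is
robust; and the regression is through-origin because the trace is
explicitly re-rooted at (0,0) — an ordinary least-squares variant with
intercept would contradict that re-rooting, but the helper accepts raw
vertex arrays so either convention can be applied upstream. Degenerate
traces (all vertices identical) return `None` and are excluded from
aggregates.

**Molecular-layer regions.** Segments are proximal / intermediate /
distal by which third of the molecular-layer thickness contains the
radial position of the segment's cable midpoint (thickness falls back to
the arbor's own radial height). Bins are closed on the left: exactly one
third ⇒ proximal. Midpoints above the thickness clamp to distal with a
warning rather than erroring, since traced arbors occasionally overshoot a
nominal thickness.

**Thin-caliber threshold.** exp(mean(ln d) + sd(ln d)) over pooled branch
*segment mean* diameters (node-wise pooling was the alternative; segment
means were chosen because the thin fraction is itself defined over
segments). The cross-species pooled default is 1.31 µm
(`arbor.THIN_CALIBER_THRESHOLD_UM`); per-arbor thresholds are computed when
none is supplied. Non-positive diameters are excluded from the log
statistics with a warning.

**Sholl.** Shells are concentric 3-D Euclidean bands of 1 µm around the
soma centroid ("centrifugal distance" read as radial shells; a
path-distance variant would be a straightforward extension but is not the
default). Each edge is split exactly where |a + t·d|² crosses a shell
boundary (quadratic roots), so conservation holds to machine precision —
the 0.5% tolerance asserted in tests is slack for the discretised
consumers, not for the computation. A branch is counted in every shell its
path intersects.

**Primary dendrite diameter.** The maximum node diameter on order-1
segments within two soma diameters of the soma centroid (Euclidean). If
that window is degenerate (e.g. zero soma radius in a synthetic file), the
thickest order-1 node anywhere is used.

## Spine metrics

Class rules: one smooth head < 0.5 µm ⇒ thin, ≥ 0.5 µm ⇒ mushroom (the
boundary itself is mushroom — "less than or greater than 500 nm" leaves
0.5 µm open, and right-closure is asserted in tests); two heads on a shared
neck ⇒ branched; a single head with ≥ 3 distinct puncta ⇒ cluster.
Head volume defaults to the sphere (π/6)·d³; measured cluster volumes can
be supplied directly. Densities are raw counts per µm with no correction
for spines hidden along the optical axis. A branched spine counts once
toward spine density; its two heads are retained in `puncta_count` for
synapse extrapolation. The spine-to-surround fraction uses the annular
cylinder between the dendrite radius r and r + p (p = mean head
protrusion); p = 0 with spines present is a degenerate shell and an error.

## Classifiers

Morphology: Poly ⇔ more than one trunk, regardless of size. Split ⇔ a
single trunk bifurcating within the proximal window — 2× the measured soma
diameter in human (somata 25–35 µm), a fixed 40 µm in mouse — either
symmetrically or with the minor daughter projecting > 200 µm (human) /
> 100 µm (mouse) parasagittally from the main compartment. Otherwise
Normative. "Symmetric" is accepted as a supplied flag; for automated
pipelines `bifurcation_symmetric_from_diameters` offers a daughter-ratio
criterion (≥ 0.75) as a documented extension. The minor-branch "distance
from the main dendritic compartment" has no unique geometric definition;
the features container expects the caller's measured parasagittal
projection, and the synthetic feature sampler interprets it as distance
from the larger daughter's subtree centroid.

Orientation (Split/Poly only; Normative raises): Horizontal when one
primary dendrite runs parallel with the PC layer > 300 µm (human) / 150 µm
(mouse), or two run in opposing directions > 150 µm / 75 µm each; parallel
means < 30° from the layer plane at the species threshold distance,
measured as the chord angle of the soma-to-threshold-point vector.

Foliar: ρ = pial length / granule-layer–white-matter border length;
Gyrus ρ > 1+τ, Sulcus ρ < 1−τ, else Bank. τ defaults to 0.05 because
"equal" outline lengths are a qualitative judgement on traced curves.

## Clustering statistics

Inter-somatic distance is the 2-D Euclidean distance between consecutive
cells in anterior→posterior order. Adjacency scores start at −1; any
neighbour within the species threshold (1000 µm human / 200 µm mouse)
raises to 0 and each matching neighbour adds +1. A run requires every
adjacent pair within threshold *and* matching; a sub-threshold gap
terminates it. "Clustered" for the excess statistic means score ≥ 1, with
denominator = cells with score ≥ 0 (whether isolated cells belong in the
denominator is ambiguous; `include_isolated=True` exposes the
alternative). Shuffles are seeded Fisher–Yates permutations of the
(morphology, orientation) pair — jointly, so the five-class label multiset
is conserved exactly, per foliar stratum in the constrained mode; 20
shuffles by default.

Population profiles tally the five-class mix within a radius of each focal
cell (focal cell excluded); the elevation is observed − shuffled-mean
match rate, in percentage points, averaged over the five classes with
equal weight (per-category weighting was chosen over per-cell weighting;
the difference only matters for very uneven demographics). Shell profiles
restrict the tally to [k·w, (k+1)·w) annuli, w = 500 µm human / 100 µm
mouse (20% of human, matching the dendritic-width ratio); cells with an
empty shell are dropped from that shell's average, and cells near slice
edges contribute one-sided tallies rather than being discarded. Since the
nonmatch rate is the complement of the match rate, per-category match and
nonmatch elevations cancel exactly — asserted as a conservation identity.

Demographics delegate the chi-squared test of independence to
scipy.stats; the inter-hemisphere comparison averages |left% − right%|
over the five classes per lobule and normalises within individual to the
reference lobule (default L6), flagging the 0/0 case instead of dividing.

## Synthetic cohorts

The generators define the study conditions; their defaults live in
`presets.py` (version 1.0) and encode the cohort means the pipeline is
expected to recover.

**Cell maps.** Positions accumulate truncated-normal spacings (human
300 ± 120 µm, mouse 35 ± 12 µm); labels follow a first-order Markov copy
process — cell *i* copies cell *i−1* with probability κ, else draws from
the five-class frequencies. κ defaults to 0.4: with copying between
in-threshold neighbours this yields mean matched runs of ~2.6–3.3 cells
over ~500–700 µm (human) and ~70–85 µm (mouse), the observed run-length
phenomenology, and it is analytically tractable (expected run length
1/(1−κ) as spacing → 0 relative to threshold). Foliar labels tile an
alternating gyrus/bank/sulcus plan by position; lobules are contiguous
blocks.

**Arbors.** Species-scaled size is a generative *target*: each cell draws
a total-length budget from the cohort distribution (human 63,645 ± 4,572
µm; mouse 6,004 ± 831 µm) and grows cable tip by tip until the budget is
spent, bifurcating with probability 0.45 at each ~23 µm (human) / ~8.5 µm
(mouse) segment end, terminating with 0.25, else elongating. Directions
are upward-biased draws from the cohort eccentricity distribution; the
vertical component reflects at the molecular-layer cap (366 / 158 µm), so
height is bounded exactly while lateral spread continues — reproducing the
wide-arbor human phenotype. A near-critical branching process without a
size budget was rejected: its total-length variance is enormous, whereas
the budgeted design gives a 30-cell cohort mean within ~1–2% of target,
and the budget is itself part of the generative model (cohort length is an
empirical input, not an emergent property we claim to predict).
Bookkeeping (cable, structural branch count) is computed from the emitted
geometry by independent arithmetic, so generator/measurement agreement is
an exact, non-trivial cross-check.

**Spiny branches.** Per-type spine counts are Poisson(density × length)
at the preset rates (human 5.37 / 0.49 / 0.42 / 0.52 per µm for
thin/mushroom/branched/cluster; mouse 4.56 / 0.13 / 0.49 / 0 — clusters
are essentially absent in mouse and modelled as a zero rate). Head
diameters are truncated normals consistent with the class boundaries;
cluster puncta are discretised normals (4.84 ± 1.75, ≥ 3) and cluster
diameter scales linearly with puncta count (slope 0.08 µm/punctum,
residual SD 0.10 µm), reflecting resizing by discrete puncta gain/loss.

**What the cohorts do not emulate.** Tortuous dendritic paths and realistic
taper statistics (segments are straight chords; taper is a fixed ratio),
tissue curvature of the PC layer, within-individual demographic gradients
along the anterior–posterior axis, truncation artefacts of real slices, and
any biophysics of dendrogenesis. Passing parameter-recovery tests therefore
shows the *measurement pipeline* is correct and calibrated on data with the
assumed statistical structure — not that the generator is a model of real
development, nor that real data would yield these effect sizes.

## Problem sizes and determinism

Default analysis sizes — 30 arbors and 50 spiny branches per species,
2,000-cell maps, 20 shuffles, 200 replicate maps for null calibration, 50
replicates per κ for the monotonicity sweep — were chosen so every cohort
statistic has standard error comfortably inside its assertion band. Every
stochastic routine takes a seed or a `numpy.random.Generator`;
identical seeds give byte-identical outputs (hashed in the pipeline
manifest and asserted in tests).

## Known limitations

- The eccentricity regression convention (through-origin) and the
  segment-mean basis of the thin-caliber threshold are interpretive
  choices; both alternatives are one flag/argument away.
- `population_match_profile` materialises an n×n distance matrix; fine to
  ~10⁴ cells, beyond which a sorted-position window would be needed.
- Orientation matching treats Normative cells (orientation "NA") as their
  own category in `orientation_only` mode.
- The shell analysis uses Euclidean annuli; for strongly folded layers a
  geodesic (along-layer) distance would differ near sulci.
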