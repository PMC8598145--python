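# Methods

## Model

An electron insert factor is treated as a smooth function of two shape
scalars: the equivalent-ellipse width `w` and the perimeter-to-area ratio
`P/A` of that ellipse. The underlying physical picture is that the output
perturbation of a cutout is dominated by (a) loss of lateral electronic
equilibrium when the field narrows toward the electron scatter range —
governed by the width of the largest circle the shape encloses — and (b)
scatter from the insert edge, which grows with boundary length per unit
area. Factors vary with machine, nominal energy, cone and SSD, so a
separate surface is fitted per (machine, energy, applicator, SSD) key; SSD
never rescales the shape, which is always expressed in cm in the
beam's-eye-view plane at 100 cm.

### Shape parameterization

* **Width** is the diameter of the largest inscribed circle, found by
  iterative interior-grid refinement (pole-of-inaccessibility search,
  `shapely.ops.polylabel`) to a default tolerance of **0.005 cm**. The
  search is robust for the concave outlines of real cutouts; multiply
  connected shapes (island blocks) are rejected.
* **Length** is defined by area equivalence, `length = 4·area/(π·width)`,
  so `π·(w/2)·(l/2) = area` holds to 1e−9 relative and `length ≥ width`
  always (the inscribed circle's area cannot exceed the shape's).
* **P/A** uses Ramanujan's first ellipse-perimeter approximation
  `P ≈ π[3(a+b) − √((3a+b)(a+3b))]`, a = l/2, b = w/2. No closed form
  exists; this choice keeps the axis a deterministic, bit-reproducible
  function of (w, l), with error far below 0.05 % at clinical aspect
  ratios.
* The model plane is (w, P/A) rather than (w, l); the two are in bijection
  at fixed area convention, and P/A is the axis that tracks edge scatter.
* Parameterization is translation- and rotation-invariant; off-center
  inserts get no centering correction (off-axis effects are a known,
  uncorrected error source of the technique).

### Spline fit

Training coordinates are standardized to unit ranges per axis (w in cm and
P/A in 1/cm differ in scale by roughly an order of magnitude), then a
tensor-product B-spline surface is fitted by least squares on the
`scipy.interpolate.BSpline` basis:

* **Degrees (2, 1)** by default — quadratic along width, where small-field
  falloff is curved; linear along P/A, where the dependence is gentle.
  Configurable. The basis then has 6 coefficients, which 8 points
  overdetermine; any polynomial surface of degree ≤ (2, 1) is reproduced
  exactly at `smoothing = 0`.
* **Eight-point floor**, enforced independently of the basis size: fewer
  measurements than eight raise an error naming the model key, whatever
  the mathematical minimum of the chosen degrees would be.
* **Knots** are clamped with no interior knots by default; optional
  interior knots go at data quantiles.
* **Smoothing** defaults to 0 (plain least squares — the inputs are few
  and low-noise); positive values add a ridge penalty of that weight on
  the coefficients.
* Records are canonically sorted by (width, P/A, shape id) before fitting,
  making the fit deterministic and permutation-invariant to ~1e−12.
  Rank-deficient designs (e.g. all shapes at one width) raise a
  degenerate-design error rather than returning a minimum-norm fit.
* FITPACK's automatic-knot scattered-data spline routines were not used:
  on 8–11 scattered points with zero smoothing their knot insertion is
  unstable and warning-prone; the fixed-knot least-squares formulation
  above is deterministic and transparent.

**Extrapolation** (query outside the convex hull of the training points,
tested via Delaunay triangulation in standardized coordinates) is allowed
but always flagged and logged, never clamped: a clinical caller must see
that a prediction leaves the measured parameter space.

### Measurement design

The recommended measurement set for a cone traces the boundary of its
reachable (w, P/A) region: `n_widths` (default 4) ellipses with length
equal to the cone's practical maximum (7, 13, 19, 21 cm for the 6, 10, 15,
20 cm cones — slightly below the geometric diagonal projected to 100 cm;
for other cone sizes the projected diagonal rounded down to 0.5 cm) and
widths spanning 2.5 cm to the cone side, plus circles over the same width
range. For the 15 and 20 cm cones, interior shapes (a mid-space ellipse
and two rectangles) are added by default, since boundary-only designs are
least accurate in the middle of the parameter space.

### Clinical operations

* `MU = dose / (calibration · isodose_fraction · cone_factor ·
  insert_factor)`; the cone factor is a measured commissioning input, not
  modeled.
* Insert factors at non-modeled SSDs come from the unique quadratic
  through the three modeled SSDs (100/105/110 cm), evaluated in Lagrange
  form so nodes are reproduced exactly. The trend is only preliminarily
  quadratic; reports label it as such, and targets outside [100, 110] cm
  are flagged as extrapolation.
* Reports print factors to 3 decimals and MU to 1 decimal using decimal
  half-up rounding on the shortest decimal representation (the convention
  of clinical calculation systems); full precision is retained internally.

### Validation statistics

Percent difference is `100·(predicted − measured)/measured`; positive
means over-prediction. Both the n−1 SD of signed differences and of their
absolute values are computed and labeled — they answer different questions
and neither bounds the other. The Gaussian summary least-squares fits
`A·exp(−(x−μ)²/2σ²)` to the histogram of signed differences (default bin
width 0.5 %), with location bounded to the data range and scale to
positive values so the fit stays identified on non-Gaussian histograms; a
single-occupied-bin histogram is a fit error. The two shipped fixture
datasets (22 patient cutouts on a Varian iX, 26 standard cutouts on a
Varian TrueBeam) store the published difference column as given: factors
printed to 3 decimals recompute to differences up to ~0.1 percentage
points away from the printed ones (one standard-insert row drifts 0.12),
so stored differences are trusted unless recomputation is requested.

## Synthetic ground truth

The generator emulates the empirical behavior the model assumes, not
electron transport:

    f(w, r) = plateau − a·exp(−w/w0) − b·(r − r0)·[r > r0]

with defaults plateau = 1.0, a = 0.25, w0 = 2.5 cm, b = 0.05 cm,
r0 = 0.6 /cm — bounded in (0.5, 1.1) over w ∈ [2, 20] cm,
r ∈ [0.2, 2.0] /cm, and reproducing the clinical ordering (narrow inserts
≈ 0.86–0.95, large inserts ≈ 1.00). Measurement noise is homoscedastic
Gaussian with SD 0.002 on the factor (the repeatability scale of averaged
100 MU chamber readings); the generator is NumPy's PCG64
(`default_rng(seed)`), fully deterministic per seed.

What passing synthetic tests show: the pipeline (parameterize → fit →
predict) recovers a smooth two-variable surface from a realistic
measurement design to well under 1 % inside the training hull, and exactly
(≤ 1e−6) when the surface lies in the spline space. What they do not show:
that real insert factors are this smooth, that noise is homoscedastic, or
that the (w, P/A) reduction captures all shape dependence (strongly
concave or off-axis cutouts can deviate); those claims rest on the shipped
clinical validation datasets.

The recovery experiment compares boundary-only vs interior-augmented
designs over paired, seeded replicates with common interior probe points
(probes are built from realistic (w, l) ellipse pairs inside the boundary
design's hull). Because a single noisy replicate can favor either design,
the "augmentation does not hurt" property is asserted on the
replicate-averaged maximum interior error (20 replicates, seed 42).

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale by design: 8–13
measurement shapes per model (the clinical regime of the technique),
50–90 interior probes, 20 recovery replicates, 50 random convex polygons
against a 0.05 cm brute-force grid oracle, 100 RT Plan round-trips. The
whole suite runs in seconds.

Degenerate inputs: polygons need ≥ 3 distinct vertices, simplicity and
nonzero area (vertex-merge tolerance 1e−9 cm); duplicate (key, shape id)
database rows, width > length, and factors outside (0.5, 1.2) are
validation errors; duplicate SSD nodes are rejected by the quadratic
interpolation.

## Known limitations

* The DICOM block-plane convention (tray-plane coordinates rescaled by the
  source-to-tray distance when present, else assumed at 100 cm) must be
  validated against a real planning-system export before clinical use.
* The spline degrees are a documented package choice; only the eight-point
  floor is inherent to the technique's published usage.
* SSD interpolation is preliminary and labeled so in reports.
* No island blocks, skin collimation, bolus, air-gap corrections, or dose
  engines; cone factors are taken as given.
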