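# Methods

This note documents the model equations, the choices made where the design
was genuinely open, the defaults and their rationale, what the synthetic
data do and do not emulate, and known limitations.

## Forcing

**Tidal datums.** MSL is the arithmetic mean of the stage record; MHHW is
the mean of higher-high waters, extracted as the maximum of each complete
24.84 h window anchored at the first timestamp. A sliding tidal-day window
is simple and reproducible and agrees with a brute-force per-tidal-day scan
to well under 0.1 cm on synthetic mixed tides; we do not perform harmonic
constituent analysis or datum-epoch adjustment. Records must span at least
one lunar month (29 d) and be uniformly sampled; a constant record has no
high waters and is rejected. The MSL–MHHW offset is held constant as sea
level rises: datums at year t are the year-0 datums plus s(t).

**Sea-level curves.** The accelerating curve is the minimal polynomial
satisfying the two stated constraints — initial slope r0 and prescribed
century total: s(t) = r0·t + b·t², b = (s100 − 100·r0)/10⁴. It is
evaluated as r0·t + (s100 − 100·r0)·(t/100)² so that s(100) equals s100
exactly in floating point. The historic hindcast uses r0 = 0.24 cm/yr with
s100 = 24 cm, hence b = 0 (constant rate). Horizons beyond 100 years (used
only for equilibrium studies) extend the curve linearly at its year-100
instantaneous rate.

**Scenarios.** The default family is the Cartesian product of century
totals {24, 52, 100, 165, 180} cm (all with r0 = 0.24 cm/yr) and suspended
sediment at 100/50/25% of the site's current concentration, ordered SLR
ascending then sediment high→low: 15 scenarios per site.

## The soil-cohort model

State is a stack of annual cohorts (mineral, labile-organic,
refractory-organic mass per unit area) above an inert substrate whose
surface is the run's starting elevation. The annual step, in order:

1. z* from the current surface and this year's datums;
2. biomass B(z*) — the unique quadratic through (z_min, 0),
   (z_peak, B_max), (z_max, 0), clamped at zero outside the window. When
   z_peak is off-centre the quadratic's vertex exceeds B_max; the curve is
   intentionally not clipped there, since all three constraints are honoured
   by interpolation;
3. mineral deposition M = C·D·n_tides·min(1, min(1, w_s/D) +
   q_trap·B/B_max) as a new surface cohort. This capture form is a
   reconstruction: it encodes the two sediment inputs (settling, biomass
   trapping) with the correct limits — zero with no flooding, saturating at
   full capture of the flood load — and both coefficients are ordinary
   configuration entries;
4. belowground production RSR·turnover·B split into refractory (f_ref) and
   labile parts, allocated over cohorts by an exponential root density with
   λ = ln(20)/D95 (95% of roots above D95); the below-column tail is
   assigned to the bottom cohort so production is conserved exactly;
5. first-order decay of every labile pool by e^(−k_decay) (fresh material
   decays in its deposition year); refractory and mineral mass are
   permanent;
6. surface = substrate + Σ cohort volumes, with cohort volume
   m_min/k_min + m_org/k_org. This is algebraically identical to dividing
   cohort mass by the ideal-mixing bulk density
   1/ρ = LOI/k_org + (1 − LOI)/k_min.

Live-root standing volume is excluded from the column; only accumulated
dead matter counts. Cohorts are never merged (a century is ≤ 100 cohorts
and the arithmetic is vectorized). Mineral mass is conserved to machine
precision and the organic budget (production − decay = storage) closes to
better than 1e-9 relative; both are asserted in the tests.

Vegetation limits are expressed in z\* so the vegetated window rides the
tidal frame upward — the mechanism behind both equilibrium tracking
(accretion converging to the SLR rate under constant forcing) and drowning
(biomass collapse once z* falls below z_min).

## Scenario engine and spatial application

Runs at 10-cm nodes over 0–380 cm NAVD88 (39 nodes) store elevations at
snapshot years {0, 20, 50, 70, 100} (calendar 2010 + t); "interpolated
evenly" between nodes is read as linear interpolation of the projected
elevation, and node values are kept bit-identical to the direct runs.
Starting elevations above the top node (DEM values up to the 390 cm cap)
clamp to the 380-node trajectory with a warning — near-upland cells accrete
negligibly. A monotonicity audit warns if projected elevation ever
decreases with starting elevation (trajectories should not cross; a
violation indicates parameter pathology rather than a numerical fault).

DEM preparation subtracts an optional vegetation-bias offset raster clamped
to 0–70 cm (a generic stand-in for survey-based LiDAR corrections), marks
cells above 390 cm as nodata, and rounds up to whole centimetres. A 0/1
channel mask removes tidal channels from all accounting. Classification
thresholds are half-open and lower-inclusive (a pixel exactly at a boundary
belongs to the upper class) — published threshold tables print touching
ranges without assigning the boundary, and a single consistent rule is
required. Percent cover is reported round-half-up to integers alongside the
exact value.

## Synthetic data

Generators are pure functions of (parameters, seed).

* **Tides**: sums of sinusoidal constituents (default one semidiurnal, one
  diurnal — a mixed, predominantly semidiurnal regime) plus optional
  Gaussian noise. No spring–neap modulation beyond what two constituents
  produce, and no storm surges.
* **DEMs**: two templates. *Island* — a mid/high platform (z* ≈ 0.8)
  ringed by a broad low-marsh fringe and mudflat rim, no upland.
  *Upland-adjacent* — a thin shore fringe, broad platform, and a linear
  upland ramp rising past the analysis cap. Jittered random-walk channels
  (lowered and masked) and centimetre-scale Gaussian roughness are added.
  The contrast mirrors the island-vs-upland landscape settings of real
  estuarine sites; no claim is made to any real site's hypsometry, so
  area figures on synthetic terrain support directional conclusions only.
* **Biomass samples**: uniform z* draws over the padded vegetated window,
  truth parabola plus zero-mean noise truncated at zero. The default site's
  truth parabola is symmetric (z_peak midway between the limits) so the
  quadratic's vertex coincides with (z_peak, B_max) and vertex-based
  recovery is well-posed.
* **Cores**: depth profiles of the model's own 100-year constant-rate
  hindcast at six elevations across the vegetated band, with the run's mean
  accretion rate embedded and optional multiplicative noise. Zero-noise
  cores are exactly self-consistent with the model — they test the
  plumbing, not the geochronology.

## Default parameterization

The default site is a brackish marsh in a frame with MSL = 100 cm,
MHHW = 180 cm NAVD88 (80 cm MSL–MHHW range). Biotic: z_min = −0.3,
z_peak = 0.5, z_max = 1.3, B_max = 2400 g/m², RSR = 1.5,
turnover = 0.5 /yr, k_decay = 0.3 /yr, f_ref = 0.15, D95 = 30 cm.
Physical: SSC = 100 mg/L, w_s = 25 cm/tide, q_trap = 0.2, 704 floods/yr,
k_org = 0.085 and k_min = 1.99 g/cm³ (the classic organic/mineral
self-packing anchors of the bulk-density mixing curve). w_s = 25 cm/tide
corresponds to fine sediment settling a few tens of centimetres over a
slack half-tide; 704 is two floods per tidal day over a year.

These values were chosen once so the default site behaves like the
historically stable marshes the model is meant for: under the 24 cm/century
hindcast it equilibrates at z* ≈ 0.99 — mid/high marsh — with accretion
0.24 cm/yr, and under 52 cm/century with high sediment the plain and
fringe converge well inside the mid/high band, while 180 cm/century with
low sediment drowns the island template. Habitat thresholds default to
−0.3 / 0.7 / 1.049 and are per-site configuration.

## Numerical choices and degenerate inputs

Time step is one year, datums updated before deposition. Zero-thickness
columns send all root allocation to the newest cohort. B_max = 0 is a
legal "unvegetated" parameterization (the trapping term is defined as zero
there). Division guards: flooding depth 0 short-circuits deposition;
classification requires MHHW > MSL. Soil-profile bins are mass-weighted
over intersecting cohorts; the last bin may be partial and reports its true
height so that Σ(ρ·h) equals total column mass exactly. The parabola fit
uses OLS on vegetated samples only (zero-biomass records would bias the
quadratic; they still bound the window implicitly), rejects non-concave
fits, and rejects roots extrapolating more than 50% of the sampled span.
The hindcast comparison is ratio-based (modeled/observed per core within
[0.5, 2], six-core mean within [0.8, 1.25]) — observational accretion
studies rarely justify tighter bands.

## Scale of the shipped analyses

Tests and examples run DEMs of 40–120 px on a side and lookup tables of 39
node runs per scenario; a full 15-scenario site completes in seconds.
These sizes give per-class area estimates stable to well under a percentage
point on the synthetic templates; production use on metre-resolution
LiDAR DEMs only changes the raster step, not the model runs.

## Limitations

The accretion model is zero-dimensional: no sediment mass balance across
the platform, no distance-to-channel deposition gradient, no wave or
channel-edge erosion, and no neighbour interactions when point results are
applied per-pixel. Suspended sediment is a fixed input per scenario rather
than a declining time series. Temperature, CO₂, salinity and nutrient
responses of productivity are not modelled. The mineral-capture formula is
a documented reconstruction, not a published equation; conclusions that
depend on its exact shape (rather than its limits and monotonicity) should
be tested against site calibration data.
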