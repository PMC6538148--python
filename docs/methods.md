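# Methods

## Problem and data model

Each case is a time-ordered series of tumor volumes (pixels³) at irregular
intervals (months from the first scan), annotated with pathology
(oligodendroglioma / astrocytoma / mixed / imaging abnormality), clinical
course group (progression / stable / imaging abnormality), resection status,
and — where a radiology report called growth — the visual-comparison (VC)
detection time. Cohort analysis assumes at least 4 scans per case. Volumes
come from binary axial masks: volume = (Σ per-slice areas) × inter-slice
distance. Pixel area and slice spacing default to 1.0, so pixels³ is the
canonical unit; physical units require the scanner geometry (read from NIfTI
headers when masks are loaded that way).

## Baseline determination

For resected tumors the baseline is the *first volume minimum after
surgery*: the earliest scan not exceeded by any earlier scan and followed by
a strict increase; a plateau at the minimum resolves to its last scan, and a
never-rising series bottoms out at its final scan. This excludes
post-surgical FLAIR change still resolving. Non-operated cases (imaging
abnormalities) use the first scan. An optional earliest-admissible baseline
time supports cases whose baseline must postdate chemotherapy. The rule is
idempotent: truncating a series at its baseline and re-searching returns
index 0.

## Change-point model

Offline, volumes x₁..xₙ (baseline through current visit) are segmented by
exactly minimizing

    Σ_segments cost(segment) + β · |changepoints|,    β = 500 / V₀

subject to ≥ `min_segment` (default 2) samples per segment. The default cost
is the length-scaled log mean square, cost(x) = n·ln(mean(x²)) — the
goodness of a single root-mean-square level for the segment. It is
scale-calibrated: rescaling all volumes shifts every segment cost by the
same total, so split *gains* are scale-invariant while the penalty falls as
1/V₀ (500 is 5% of the rounded median baseline volume of 10,000 px³, so the
median tumor pays 0.05 per change point). A within-segment sum-of-squares
(`mean_shift`) cost is available for sensitivity analysis. The optimization
is an O(n²) dynamic program, exact for the series lengths involved (tens of
scans); ties resolve toward fewer change points, so a split must strictly
beat the penalty. An exhaustive-enumeration oracle in the test suite
verifies exactness on hundreds of random series.

Online detection sweeps visits in time order, re-running the offline solver
on the past-only window; the first visit with a nonempty solution is the
alert visit. Time to growth (TTG) is measured from the baseline scan to the
*change-point scan* frozen at the alert visit (the alert itself necessarily
lags by at least `min_segment − 1` scans); full-series re-estimation is
exposed separately. The result is a pure function of past data — appending
scans after the alert never changes it.

**Known limitation.** By Jensen's inequality the rms-log split gain is
nonnegative, and at the 0.05 penalty i.i.d. per-scan noise at the ~26.5%
level found in stable clinical series almost always produces a gain above
threshold once four scans accrue. The detector is therefore deliberately
sensitive — suited to flagging scans for physician review, not to
unsupervised calling — and its false-alert rate on stationary synthetic
series at that noise level is close to 1 (tracked as a seeded regression
number). The proprietary routine this cost functional emulates evidently
weights residual improvement differently; its exact objective is not
published, so per-case agreement with the original tool's detection times is
not guaranteed.

## Bidimensional measurement

d₁ is the largest pixel-center distance in the mask (single-pixel masks have
diameter 1 by convention). d₂ is the largest perpendicular component among
pixel pairs whose connecting line is perpendicular to d₁ within 1° *or
within one pixel of shear*, whichever is looser: a pixel grid cannot resolve
1° below ~57 px chord length, and the strict cone alone makes the product
swing by up to 17% under rotation, versus ≤ ~3–5% with the shear allowance
(tested on a rasterized 60×30-px ellipse). When several pairs attain d₁ the
one admitting the larger d₂ wins; degenerate 1-px lines fall back to d₂ = 1.
The progression rule is inclusive: product increase ≥ 25% (configurable).
Candidate points are boundary pixels, reduced to the convex hull above 1,500
points.

The slice-growth profile flags *nonhomogeneous* growth when the
fastest-growing slice differs from the largest baseline slice and grows
strictly faster than it; a slice growing from zero area reports an
undefined-ratio sentinel (∞) rather than raising.

## Curve fitting and kinetics classification

Normalized curves subtract V₀ and divide by the most recent volume (so
shrinkage yields negative values and no log transform is used); times map to
[0, 1]. The linear model is ordinary least squares. The exponential model
y = a·exp(b·x) is nonlinear least squares with multi-start initialization —
(first y, slope of ln y on positive points), (max y, 1), (0.01, 3) — keeping
the best converged sse (target tolerance 1e−10; a failure from every start
raises, carrying the best candidate). The rate is bounded to |b| ≤ 50 on the
normalized domain: unbounded, curves that exp1 cannot represent drive the
optimizer toward the degenerate one-point spike a → 0, b → ∞, where the sse
plateaus but the parameters diverge. A curve is exponential when
sse_exp < 0.6·sse_lin (strict); the factor is chosen so that classified
curves fit exp1 with r² > 0.85, which the recovery experiment in the test
suite confirms. The pooled fit runs one exp1 regression over the union of
points of all supplied curves; r² uses the mean-centered total sum of
squares of the pooled y.

## Cohort statistics

Mann–Whitney–Wilcoxon two-tailed p-values use the exact null for combined
n ≤ 20 without ties (verified against full enumeration for all combined
n ≤ 10) and the tie-corrected normal approximation otherwise. Quartiles use
linear interpolation — the convention is not forced by the data, and the
reported integer-month IQRs are robust to it. Displayed p-values have a
"<0.001" floor. ΔG counts detected cases whose CAD TTG is strictly below
the VC TTG; VC times are annotations (human calls are data, not
computation), and VC ΔV is read at the scan nearest the annotated time
(ties to the earlier scan). Progression cases without a VC annotation stay
in n and the CAD columns but leave ΔG and the VC columns, with a warning.

## Synthetic data

The generator emulates the study conditions: baseline volume 10,000 px³
(the population's rounded median), visit intervals uniform on 2–6 months,
multiplicative per-scan noise (1 + ε) with ε ~ N(0.0099, 0.2654²) truncated
at −0.9 — the percent-change moments of stable clinical series; noise for
growing tumors is unreported and the same model is reused. Trends:
stationary, linear (px³/month) or exponential (1/month) growth starting at
an onset month after baseline, optionally preceded by a geometric
post-surgical decay limb (default 2 scans from 1.6×V₀) ending at the trend
baseline. Cohorts default to the study's group sizes (34/22/7) and pathology
mix; progression cases draw onset uniform on 6–24 months and rates of
0.04–0.10/month (exponential, ~14/47 of cases) or 300–1,200 px³/month
(linear). The synthetic VC annotation is a declared stand-in for human
visual comparison, not a claim about radiologists: VC "detects" at the first
visit reaching (1 + 1.74)×V₀, calibrated to the 174% median volume change at
image-based detection. Mask phantoms are rasterized ellipsoids; the
anisotropic schedule grows the through-plane axis faster, reproducing
volume growth that the in-plane bidimensional product misses.

What the generator does **not** emulate: registration and segmentation
artifacts, scanner changes mid-follow-up, intensity physics, correlated
noise, treatment effects other than the initial decay limb, or human
review. Passing tests show the pipeline's internal consistency and
calibration under these idealized conditions, not clinical performance.

## Problem sizes and numerical conventions

Tests and the acceptance script run on cohorts of tens of cases with 10–14
scans each, 500-series oracle comparisons at length ≤ 12, 100-replicate
fit-recovery experiments, and 32³–64³ phantom grids — sizes chosen so the
exact solver and brute-force oracles stay comfortable. On-disk tables are
CSV with volumes as integers and months/fractions at 2 decimals; writers
sort by case id and are byte-deterministic, so a write–read–write cycle is
idempotent (first write quantizes by ≤ 0.5 px³ / 0.005 months). The
spreadsheet import path accepts the same columns from .xlsx.
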