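# Methods

## Experimental design and data model

The package targets a completely randomized drought experiment on a pea
diversity panel: g accessions × 2 irrigation conditions (control at 70%
field capacity, drought at 30%) × r replicates, with the full-scale default
g = 180, r = 3 (1080 experimental units). Each unit carries 19 traits:
11 image-based (DB, CH, SOL, NDVI, NPCI, PSRI, GLI, TA, SA, PhE, WUE) and
8 manual (FW, DW, PH, TLA, SLA, LWR, LAR, RWC). The long-format trait
table — one row per (accession, condition, replicate, trait) — is the single
interchange object between extraction and statistics.

## Image traits

**Segmentation.** Side views are shot against a saturated blue backdrop; a
pixel is plant iff its blue excess B − max(R, G) (reflectances scaled to
0–1) is below `blue_margin` (default 0.2). Top views use excess green,
2G − R − B > 0.1. Both rules are deterministic and parameter-explicit —
a reproducible stand-in for closed vendor software. 8-connected components
smaller than `min_component_px` (default 10 px) are removed to suppress
salt noise; the default keeps 1-px-wide stems connected to their leaves
because connectivity is 8-neighbour.

**Geometry.** Projected area is the plant-pixel count. Digital biomass DB
is the arithmetic mean of the six side-view areas. Pixel height is the
inclusive row extent of the mask (no physical calibration; a scale factor
can be applied downstream). The convex hull is computed on **pixel
centers** via Andrew's monotone chain with shoelace area; masks with fewer
than three non-collinear pixels get hull area 0. The center convention was
chosen for oracle simplicity (hull area of four pixel-corner points of a
side-s square is exactly s²); its known consequence is that the hull of a
*solid* blob is slightly smaller than its pixel count, so the CH ≥ area
inequality is guaranteed only for sparse, plant-like silhouettes — which is
the regime the pipeline operates in. Per-plant solidity is DB divided by
the mean of the six per-view hull areas; per-view solidities are also
available.

**SA vs DB.** Vendor pipelines report both a "side area" and a "digital
biomass" at very different numeric scales while describing both as
six-view aggregates. Here the two are given pixel-based, unambiguous
definitions: DB is the mean and SA the sum of the six side-view projected
areas. Both are in px²; any unit mismatch with vendor output is a constant
factor that cancels in the sensitivity index and in correlations.

**Spectral indices.** NDVI = (G−R)/(G+R), NPCI = (R−B)/(R+B),
PSRI = (R−B)/G, GLI = (2G−R−B)/(2G+R+B), averaged over plant pixels.
The "NDVI" here is the green–red normalized difference (conventionally
NGRDI) as used in RGB-reflectance phenotyping rigs that lack a
near-infrared band; the label NDVI is kept for continuity with that usage.
Pixels with a zero denominator are excluded from the mean and counted,
never clipped.

**Fluorescence.** PhE = Fv/Fm = (Fm − F0)/Fm over plant pixels, the
universal definition of maximum PSII photochemical efficiency after dark
adaptation. Pixels with Fm ≤ 0 or F0 outside [0, Fm] are excluded and
counted; an all-invalid plant yields a missing value.

## Derived traits and sensitivity index

SLA = TLA/leaf_DW, LWR = leaf_DW/DW, LAR = TLA/DW,
RWC = (FW−DW)/(SFW−DW)×100, WUE = DB/water_used. Non-positive divisors
propagate to NaN with a warning, never to exceptions.

The sensitivity index is SI = (x̄_c − x̄_s)/x̄_c × 100 with x̄_c the
control mean and x̄_s the drought mean, so reductions are positive. Default
condition means pool all records per condition (pairwise-complete, with
record counts reported); a per-accession variant supports screening. The
group-reduction summary applies the same formula within each species group
and reports the unweighted grand mean across groups.

Recomputing SI from condition means printed at two decimals reproduces the
published value at two decimals only where the rounding of the means is
benign; traits like PH ((123.26 − 91.44)/123.26 × 100 = 25.816 against a
printed 25.81 computed from unrounded means) differ in the second decimal
for exactly that reason, and the acceptance layer restricts itself to the
traits where two-decimal means determine the two-decimal SI.

## Statistics

**ANOVA.** The classical balanced two-way decomposition
(SS_G, SS_C, SS_GC, SS_E) with F tests against the residual mean square.
Unbalanced layouts are rejected with a pointer to drop incomplete cells or
use a mixed-model tool — the balanced path is exactly testable and matches
the designed experiment. No multiplicity correction is applied to the
per-trait p-values.

**Variance components.** The all-random model is solved by inverting the
expected mean squares (σ²ε = MS_E; σ²GC = (MS_GC−MS_E)/r;
σ²G = (MS_G−MS_GC)/(rc); σ²C = (MS_C−MS_GC)/(rg)). For balanced data this
coincides with REML whenever the solution is interior; negative solutions
are truncated at zero and flagged, and truncation is the one case where the
two estimators can differ. Standard errors use the delta method with
Var(MS) = 2 MS²/df. Condition is treated as random here (matching the
all-random decomposition) while the ANOVA F tests use the fixed-effects
framing; both outputs are labeled.

**Heritability.** Broad-sense, plot basis by default:
h² = σ²G/(σ²G + σ²GC + σ²ε); the entry-mean basis
σ²G/(σ²G + σ²GC/c + σ²ε/(cr)) is an option. The result is clamped to
[0, 1]. Plot basis is the default because it is the natural "sample-basis"
reading for single-plot records; with c = 2 and r = 3 the entry-mean basis
is systematically higher.

**Relative contributions** are each component as a percent of the
four-component sum (genotype, condition, interaction, residual); excluding
the residual from the denominator is an option.

**Correlations and PCA.** Pearson correlations of per-plant records within
each condition; constant traits are excluded with a warning and pairs need
at least 3 complete records. The network keeps edges at |r| ≥ 0.30 and
classes them strong at |r| ≥ 0.60 — visualization conventions, overridable
in config. Nodes carry the biomass/architectural/physiological grouping.
PCA standardizes per-plant records jointly across conditions and
eigendecomposes the correlation matrix; loadings are sign-fixed so each
component's largest-magnitude loading is positive; explained proportions
are non-increasing and sum to 1 for a full-rank matrix.

## Synthetic data

**Phantoms.** Plants are 3-D stick models — a 1-px vertical stem plus
branches tilted 30° above horizontal at chosen azimuths, each ending in a
circular leaf — projected at the six turn-table angles, so projected area
varies with viewing angle as for real canopies. Ground truth is computed
from the rendered foreground pixels at render time (area = pixel count,
height = row extent, hull via `scipy.spatial.ConvexHull` — an
implementation independent of the extractor's monotone chain). Reflectance
phantoms invert the index formulas: NDVI fixes R/G, NPCI fixes B/R, and
PSRI/GLI are then determined, so a four-index target set is feasible only
when consistent — infeasible sets are rejected naming the violated
constraint. Fluorescence phantoms set F0 = (1 − target)·Fm per pixel, so
Fv/Fm is exact everywhere. Optional additive Gaussian sensor noise
(default off) supports robustness checks; real camera noise was not
characterized, so the level is a free parameter, not an instrument
estimate.

**Trait tables.** y_ijk = μ + G_i + C_j + (GC)_ij + ε_ijk with independent
zero-mean normal effects; condition can instead be a pair of fixed offsets
(the right framing for SI work). Tables are balanced and complete by
construction, and the marginal variance equals the component sum in
expectation. `simulate_study` generates all 19 traits with condition means
taken from the published panel means and variances scaled per trait via a
coefficient of variation (0.18 by default, smaller for tight traits like
PhE), with variance shares 50% genotype / 20% interaction / 30% residual
of the within-condition variance — a single fixed choice giving
genotype-dominated architectural traits and realistic heritabilities.

**What passing tests show.** Phantoms share the pixel grid with the
extractor, so exact area/height/hull recovery demonstrates internal
consistency of the geometry code, not robustness to real-world blur,
occlusion or color bleed; leaf overlap, temporal growth and photorealism
are out of scope. Traits are simulated independently of each other, so
cross-trait correlations in simulated studies arise only through the shared
condition contrast; network tests therefore check structure and thresholds,
not the published correlation values. The phantom pipeline's own SI values
reflect the stick-model geometry (e.g. its WUE rises under drought because
the modeled water saving outpaces the modeled biomass loss) and are not
calibrated to the published SI magnitudes — the trait-table simulator,
which is so calibrated, is the tool for study-scale statistical checks.

## Problem sizes and numerical choices

Parameter-recovery checks use 200 simulated experiments at g = 60, c = 2,
r = 3 — large enough that Monte-Carlo standard errors separate estimator
bias from noise while the whole battery stays interactive. Hull oracle
checks use 200 random ≤ 50-pixel masks against an exhaustive gift-wrapping
oracle. Round-trip checks use 100 random phantoms. Ties in the hull are
resolved by dropping collinear points (strictly convex turns only), which
matches the oracle's farthest-point tie-break. All randomness flows through
seeded `numpy` generators; identical seeds give byte-identical rasters and
tables, and the report bundle is deterministic for a fixed input table.
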